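"""Langevin-dynamics engine for the coarse-grained triblock model.

Implicit-solvent Langevin dynamics in a cubic periodic box, BAOAB splitting,
Verlet pair list built with a periodic k-d tree, and extended-XYZ trajectory
output.  Everything is in reduced LJ units (sigma = eps_BB = mass = 1) and
fully reproducible from a single seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .errors import GeometryError, InitializationError, InstabilityError, ParameterError
from .forcefield import (
    BEAD_B,
    ChainTopology,
    InteractionParams,
    ThermalMap,
    fene_bond,
    lj_pair,
    thermal_map,
    wca_pair,
)
from .xyz import XYZFrame, write_extxyz

__all__ = [
    "SimulationState",
    "Trajectory",
    "RunConfig",
    "minimum_image",
    "init_system",
    "neighbor_pairs",
    "compute_forces",
    "compute_forces_reference",
    "step_langevin",
    "run",
]

_BOND_LENGTH = 0.97  # initial random-walk bond length, in sigma
_OVERLAP_MIN = 0.8  # push-off target: no pair closer than this


@dataclass
class SimulationState:
    """Positions/velocities/box/time for all beads, plus the RNG stream."""

    positions: np.ndarray  # (N, 3), wrapped into [0, box_edge)
    velocities: np.ndarray  # (N, 3)
    box_edge: float
    time: float
    chain_index: np.ndarray  # (N,)
    bead_type: np.ndarray  # (N,) uint8, 0=A / 1=B
    bonds: np.ndarray  # (n_bonds, 2) global bead indices
    rng: np.random.Generator

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def copy(self) -> "SimulationState":
        return SimulationState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            box_edge=self.box_edge,
            time=self.time,
            chain_index=self.chain_index.copy(),
            bead_type=self.bead_type.copy(),
            bonds=self.bonds.copy(),
            rng=_copy_rng(self.rng),
        )

    def frame(self) -> XYZFrame:
        return XYZFrame(
            positions=self.positions.copy(),
            box_edge=self.box_edge,
            time=self.time,
            bead_type=self.bead_type.copy(),
            chain_index=self.chain_index.copy(),
        )


def _copy_rng(rng: np.random.Generator) -> np.random.Generator:
    bg = type(rng.bit_generator)()
    bg.state = rng.bit_generator.state
    return np.random.Generator(bg)


@dataclass
class Trajectory:
    """Ordered frames plus the metadata needed to replay the run exactly."""

    frames: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ParameterError("frame times must be strictly increasing")

    def write(self, path) -> None:
        write_extxyz(path, self.frames)
        manifest = Path(path).with_suffix(".manifest.json")
        manifest.write_text(json.dumps(self.metadata, indent=2, default=float))


def minimum_image(displacement, box_edge: float):
    """Wrap displacement components into the half-open box [-L/2, L/2)."""
    d = np.asarray(displacement, dtype=float)
    return d - box_edge * np.floor(d / box_edge + 0.5)


def _box_edge_for(n_beads: int, volume_fraction: float, sigma: float = 1.0) -> float:
    return (n_beads * (math.pi / 6.0) * sigma**3 / volume_fraction) ** (1.0 / 3.0)


def init_system(
    topology: ChainTopology,
    n_chains: int,
    volume_fraction: float,
    seed: int,
    temperature: float = 1.0,
    max_retries: int = 3,
) -> SimulationState:
    """Build an initial solution state at the target bead volume fraction.

    The box edge satisfies ``N (pi/6) sigma^3 / L^3 = volume_fraction``.
    Chains are placed as random walks with bond length 0.97 sigma, relaxed
    with a bounded soft-cosine push-off until no pair is closer than
    0.8 sigma, and velocities are drawn Maxwell-Boltzmann at ``temperature``
    (then shifted to zero total momentum).  Deterministic per seed.
    """
    if not 0.0 < volume_fraction < 0.5:
        raise ParameterError(f"volume_fraction={volume_fraction} outside (0, 0.5)")
    if n_chains < 0:
        raise ParameterError("n_chains must be >= 0")
    n_per = topology.n_beads
    n_total = n_chains * n_per
    box = _box_edge_for(n_total, volume_fraction)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    types = np.tile(topology.bead_types, max(n_chains, 1))[:n_total].astype(np.uint8)
    chains = np.repeat(np.arange(n_chains), n_per)
    bonds = (
        np.concatenate([topology.bonds + c * n_per for c in range(n_chains)])
        if n_chains
        else np.zeros((0, 2), dtype=np.int64)
    ).astype(np.int64)

    if n_chains == 0:
        return SimulationState(
            positions=np.zeros((0, 3)),
            velocities=np.zeros((0, 3)),
            box_edge=box,
            time=0.0,
            chain_index=chains,
            bead_type=types,
            bonds=bonds,
            rng=rng,
        )

    last_exc = None
    for _ in range(max_retries):
        pos = _random_walk_placement(rng, n_chains, n_per, box)
        try:
            pos = _push_off(pos, bonds, box)
            break
        except InitializationError as exc:  # retry with fresh placement
            last_exc = exc
    else:
        raise InitializationError(
            f"packing infeasible after {max_retries} retries: {last_exc}"
        )

    vel = rng.normal(0.0, math.sqrt(temperature), size=(n_total, 3))
    vel -= vel.mean(axis=0)
    return SimulationState(
        positions=pos % box,
        velocities=vel,
        box_edge=box,
        time=0.0,
        chain_index=chains,
        bead_type=types,
        bonds=bonds,
        rng=rng,
    )


def _random_walk_placement(rng, n_chains: int, n_per: int, box: float) -> np.ndarray:
    pos = np.empty((n_chains * n_per, 3))
    for c in range(n_chains):
        start = rng.uniform(0.0, box, size=3)
        steps = rng.normal(size=(n_per - 1, 3))
        steps *= _BOND_LENGTH / np.linalg.norm(steps, axis=1)[:, None]
        walk = np.concatenate([[start], start + np.cumsum(steps, axis=0)])
        pos[c * n_per : (c + 1) * n_per] = walk
    return pos % box


def _push_off(pos, bonds, box, max_sweeps: int = 400) -> np.ndarray:
    """Soft-potential steepest descent until no pair is below 0.8 sigma."""
    pos = pos.copy()
    bi = np.ascontiguousarray(bonds[:, 0])
    bj = np.ascontiguousarray(bonds[:, 1])
    step_cap = 0.05
    for sweep in range(max_sweeps):
        tree = cKDTree(pos % box, boxsize=box)
        close = tree.query_pairs(_OVERLAP_MIN, output_type="ndarray")
        if len(close) == 0:
            return pos % box
        pairs = tree.query_pairs(1.0, output_type="ndarray")
        forces = np.zeros_like(pos)
        amp = 5.0 + 0.5 * sweep
        _kernels.softcore_kernel(
            pos % box,
            np.ascontiguousarray(pairs[:, 0]),
            np.ascontiguousarray(pairs[:, 1]),
            box,
            amp,
            1.0,
            forces,
        )
        # harmonic tether keeps bonds near the target length during push-off
        d = minimum_image(pos[bj] - pos[bi], box)
        r = np.linalg.norm(d, axis=1)
        fb = 100.0 * (r - _BOND_LENGTH)[:, None] * d / r[:, None]
        np.add.at(forces, bi, fb)
        np.add.at(forces, bj, -fb)
        norm = np.linalg.norm(forces, axis=1, keepdims=True)
        # displacement-capped steepest descent
        disp = forces * np.minimum(0.02, step_cap / np.maximum(norm, 1e-12))
        pos = (pos + disp) % box
    raise InitializationError("push-off did not remove overlaps")


def neighbor_pairs(state: SimulationState, r_list: float) -> np.ndarray:
    """All unordered bead pairs within ``r_list`` under minimum image.

    Uses a periodic k-d tree; raises :class:`GeometryError` when ``r_list``
    exceeds half the box edge (minimum-image distances become ambiguous).
    """
    if state.n_beads < 2:
        return np.zeros((0, 2), dtype=np.int64)
    if r_list > state.box_edge / 2.0:
        raise GeometryError(
            f"r_list={r_list} exceeds box_edge/2={state.box_edge / 2.0}"
        )
    tree = cKDTree(state.positions % state.box_edge, boxsize=state.box_edge)
    pairs = tree.query_pairs(r_list, output_type="ndarray").astype(np.int64)
    return pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]


def _exclude_bonds(pairs: np.ndarray, bonds: np.ndarray, n: int) -> np.ndarray:
    if len(pairs) == 0 or len(bonds) == 0:
        return pairs
    enc = pairs[:, 0] * n + pairs[:, 1]
    b = np.sort(bonds, axis=1)
    benc = b[:, 0] * n + b[:, 1]
    return pairs[~np.isin(enc, benc)]


def compute_forces(
    state: SimulationState,
    params: InteractionParams,
    pairs: np.ndarray | None = None,
    bonds_already_excluded: bool = False,
):
    """Forces and potential energy of the full force field.

    Non-bonded terms: LJ (B-B), WCA (A-A, A-B) over all non-bonded pairs;
    bonded pairs get FENE + WCA only.  ``pairs`` may supply a precomputed
    (superset) neighbor list; otherwise one is built at the largest cutoff.
    Callers holding a pair list with bonds already filtered out can skip the
    per-call exclusion with ``bonds_already_excluded``.
    """
    n = state.n_beads
    forces = np.zeros((n, 3))
    if n == 0:
        return forces, 0.0
    if pairs is None:
        pairs = neighbor_pairs(state, params.max_cutoff)
    if not bonds_already_excluded:
        pairs = _exclude_bonds(pairs, state.bonds, n)
    pos = np.ascontiguousarray(state.positions % state.box_edge)
    energy = _kernels.nonbonded_kernel(
        pos,
        np.ascontiguousarray(pairs[:, 0]),
        np.ascontiguousarray(pairs[:, 1]),
        state.bead_type,
        state.box_edge,
        params.eps_AA,
        params.eps_AB,
        params.eps_BB,
        params.sigma,
        params.rcut_BB,
        forces,
    )
    if len(state.bonds):
        e_bond, bad = _kernels.bonded_kernel(
            pos,
            np.ascontiguousarray(state.bonds[:, 0]),
            np.ascontiguousarray(state.bonds[:, 1]),
            state.box_edge,
            params.fene_k,
            params.fene_R0,
            1.0,  # Kremer-Grest: unit-eps WCA on bonded pairs
            params.sigma,
            forces,
        )
        if bad >= 0:
            i, j = state.bonds[bad]
            from .errors import OverstretchError

            raise OverstretchError(
                f"FENE bond {bad} (beads {i}-{j}) at or beyond R0={params.fene_R0}"
            )
        energy += e_bond
    return forces, energy


def compute_forces_reference(state: SimulationState, params: InteractionParams):
    """All-pairs O(N^2) numpy oracle for :func:`compute_forces`.

    Evaluates every pair term from the closed forms in
    :mod:`triblock.forcefield`; intended for validation on small systems.
    """
    n = state.n_beads
    forces = np.zeros((n, 3))
    energy = 0.0
    if n < 2:
        return forces, energy
    pos = state.positions
    box = state.box_edge
    bond_set = {tuple(sorted(b)) for b in state.bonds.tolist()}
    for i in range(n - 1):
        for j in range(i + 1, n):
            d = minimum_image(pos[i] - pos[j], box)
            r = float(np.linalg.norm(d))
            bonded = (i, j) in bond_set
            if bonded:
                eu, fu = fene_bond(r, params.fene_k, params.fene_R0)
                ew, fw = wca_pair(r, 1.0, params.sigma)
                e, f = eu + ew, fu + fw
            else:
                tsum = int(state.bead_type[i]) + int(state.bead_type[j])
                if tsum == 2 * BEAD_B:
                    e, f = lj_pair(r, params.eps_BB, params.sigma, params.rcut_BB)
                else:
                    eps = params.eps_AA if tsum == 0 else params.eps_AB
                    e, f = wca_pair(r, eps, params.sigma)
            energy += e
            fv = f * d / r
            forces[i] += fv
            forces[j] -= fv
    return forces, energy


def step_langevin(
    state: SimulationState,
    forces: np.ndarray,
    dt: float,
    gamma: float,
    T: float,
    params: InteractionParams,
    pairs: np.ndarray | None = None,
    bonds_already_excluded: bool = False,
):
    """One BAOAB Langevin step (in place); returns (new_forces, energy).

    With ``gamma = 0`` the O-step is the identity and the scheme reduces to
    velocity Verlet.  Noise is drawn from ``state.rng`` so trajectories are
    reproducible per seed.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if gamma < 0 or T < 0:
        raise ParameterError("gamma and T must be non-negative")
    v = state.velocities
    x = state.positions
    v += 0.5 * dt * forces
    x += 0.5 * dt * v
    if gamma > 0.0:
        c1 = math.exp(-gamma * dt)
        c2 = math.sqrt(T * (1.0 - c1 * c1))
        v *= c1
        v += c2 * state.rng.standard_normal(v.shape)
    x += 0.5 * dt * v
    if not np.all(np.isfinite(x)):
        bad = int(np.argwhere(~np.isfinite(x))[0][0])
        raise InstabilityError(f"non-finite position for bead {bad} at t={state.time}")
    np.mod(x, state.box_edge, out=x)
    new_forces, energy = compute_forces(
        state, params, pairs=pairs, bonds_already_excluded=bonds_already_excluded
    )
    v += 0.5 * dt * new_forces
    state.time += dt
    return new_forces, energy


@dataclass
class RunConfig:
    """Full specification of one self-assembly run (replayable from seed)."""

    topology: ChainTopology
    n_chains: int = 100
    volume_fraction: float = 0.15
    temperature: float = 0.6
    tmap: ThermalMap = field(default_factory=ThermalMap)
    dt: float = 0.005
    gamma: float = 1.0
    n_warmup: int = 10_000  # reduced-timestep stage after the soft push-off
    n_equil: int = 10_000
    n_prod: int = 10_000
    stride: int = 2_000
    seed: int = 0
    skin: float = 0.4
    rebuild_every: int = 20
    dt_warmup: float = 0.002  # small enough to relax residual near-contacts

    def params_at_temperature(self) -> InteractionParams:
        return thermal_map(self.temperature, self.tmap)

    def to_dict(self) -> dict:
        d = {
            "n_B_per_end": self.topology.n_B_per_end,
            "n_A": self.topology.n_A,
        }
        for k in (
            "n_chains", "volume_fraction", "temperature", "dt", "gamma",
            "n_warmup", "n_equil", "n_prod", "stride", "seed", "skin",
            "rebuild_every", "dt_warmup",
        ):
            d[k] = getattr(self, k)
        d["tmap"] = {
            k: getattr(self.tmap, k)
            for k in (
                "t_min", "t_max", "eps_AA_at_tmin", "eps_AA_at_tmax",
                "eps_AB_at_tmin", "eps_AB_at_tmax", "form",
            )
        }
        return d


def run(config: RunConfig, xyz_path=None, log=None) -> Trajectory:
    """Execute push-off, equilibration and production; collect frames.

    Frames are recorded every ``stride`` production steps (plus the frame at
    the end of equilibration, so a zero-length production still yields one
    frame).  On instability the partial trajectory is attached to the raised
    :class:`InstabilityError` as ``exc.trajectory`` and, when ``xyz_path`` is
    given, persisted there.
    """
    params = config.params_at_temperature()
    state = init_system(
        config.topology,
        config.n_chains,
        config.volume_fraction,
        seed=config.seed,
        temperature=config.temperature,
    )
    r_list = params.max_cutoff + config.skin
    frames: list[XYZFrame] = []
    energies: list[tuple[float, float]] = []

    def _log(msg: str) -> None:
        if log is not None:
            log(msg)

    def _pairs() -> np.ndarray:
        if state.n_beads >= 2 and r_list <= state.box_edge / 2.0:
            pairs = neighbor_pairs(state, r_list)
        else:
            # tiny box: fall back to the exhaustive pair list
            idx = np.arange(state.n_beads)
            ii, jj = np.meshgrid(idx, idx, indexing="ij")
            m = ii < jj
            pairs = np.stack([ii[m], jj[m]], axis=1).astype(np.int64)
        return _exclude_bonds(pairs, state.bonds, state.n_beads)

    try:
        pairs = _pairs()
        forces, _ = compute_forces(state, params, pairs=pairs, bonds_already_excluded=True)
        # warmup: full potentials at a reduced timestep so residual
        # near-contacts from the push-off thermalize without bond blow-up
        for step in range(config.n_warmup):
            if step % max(config.rebuild_every // 2, 1) == 0:
                pairs = _pairs()
            forces, _ = step_langevin(
                state, forces, config.dt_warmup, config.gamma, config.temperature,
                params, pairs, bonds_already_excluded=True,
            )
        for step in range(config.n_equil):
            if step % config.rebuild_every == 0:
                pairs = _pairs()
            forces, energy = step_langevin(
                state, forces, config.dt, config.gamma, config.temperature, params,
                pairs, bonds_already_excluded=True,
            )
            if step % 1000 == 0:
                _log(f"equil step={step} T={config.temperature} U={energy:.2f}")
        frames.append(state.frame())
        for step in range(config.n_prod):
            if step % config.rebuild_every == 0:
                pairs = _pairs()
            forces, energy = step_langevin(
                state, forces, config.dt, config.gamma, config.temperature, params,
                pairs, bonds_already_excluded=True,
            )
            if (step + 1) % config.stride == 0:
                frames.append(state.frame())
                _log(f"prod step={step + 1} T={config.temperature} U={energy:.2f}")
                energies.append((state.time, energy))
    except InstabilityError as exc:
        traj = Trajectory(frames=frames, metadata=config.to_dict())
        exc.trajectory = traj
        if xyz_path is not None and frames:
            traj.write(xyz_path)
        raise

    meta = config.to_dict()
    meta["final_time"] = state.time
    meta["production_energies"] = energies
    traj = Trajectory(frames=frames, metadata=meta)
    if xyz_path is not None:
        traj.write(xyz_path)
    return traj


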