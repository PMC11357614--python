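"""Synthetic inputs for every stage of the pipeline.

Three generator families, all bit-reproducible from their seed:

* labeled micelle point clouds (uniform balls / cylinders plus Gaussian
  jitter) for exercising the shape classifier,
* planted-micelle trajectories with known ground truth for end-to-end
  morphology tests,
* Hill-structured two-drug dose-response grids with an optional localized
  synergy bump for the Bliss/IC50 statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InitializationError, ParameterError
from .forcefield import BEAD_A, BEAD_B
from .simulate import Trajectory
from .xyz import XYZFrame

__all__ = [
    "LabeledPointCloud",
    "gen_micelle_cloud",
    "gen_fixture_trajectory",
    "gen_dose_response",
]

SPHERE = "sphere"
CYLINDER = "cylinder"


@dataclass
class LabeledPointCloud:
    """Point cloud with its generative ground truth."""

    points: np.ndarray  # (n, 3)
    label: str  # "sphere" | "cylinder"
    radius: float
    length: float | None
    noise_sd: float
    seed: int


def _uniform_ball(rng, n: int, radius: float) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


def _uniform_cylinder(rng, n: int, radius: float, length: float) -> np.ndarray:
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    r = radius * np.sqrt(rng.random(n))
    z = rng.uniform(-0.5 * length, 0.5 * length, n)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _random_rotation(rng) -> np.ndarray:
    # QR of a Gaussian matrix with sign fix: Haar-uniform rotation
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def gen_micelle_cloud(
    shape: str,
    radius: float,
    length: float | None = None,
    n_points: int = 1000,
    noise_sd: float = 0.0,
    seed: int = 0,
    orient: bool = True,
) -> LabeledPointCloud:
    """Uniformly filled solid sphere or cylinder with isotropic jitter.

    ``noise_sd`` is the standard deviation of the added Gaussian
    displacement in the same length units as ``radius``.  Cylinders get a
    random (Haar-uniform) orientation unless ``orient=False``.
    """
    if radius <= 0:
        raise ParameterError("radius must be positive")
    if n_points < 10:
        raise ParameterError("n_points must be >= 10")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC10D]))
    if shape == SPHERE:
        pts = _uniform_ball(rng, n_points, radius)
    elif shape == CYLINDER:
        if length is None or length <= 0:
            raise ParameterError("cylinder requires positive length")
        pts = _uniform_cylinder(rng, n_points, radius, length)
    else:
        raise ParameterError(f"unknown shape {shape!r}")
    if orient:
        pts = pts @ _random_rotation(rng).T
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, pts.shape)
    return LabeledPointCloud(
        points=pts,
        label=shape,
        radius=radius,
        length=length if shape == CYLINDER else None,
        noise_sd=noise_sd,
        seed=seed,
    )


def gen_fixture_trajectory(
    n_micelles: int,
    shapes,
    box_edge: float,
    seed: int = 0,
    radius: float = 2.0,
    worm_radius: float | None = None,
    worm_length: float | None = None,
    points_per_volume: float = 4.0,
    corona_shell: bool = False,
    n_frames: int = 1,
) -> Trajectory:
    """Static extended-XYZ-compatible trajectory of planted micelles.

    ``shapes`` is a sequence of "sphere"/"cylinder" labels of length
    ``n_micelles``.  Micelle centers are drawn at random and rejected until
    bounding spheres do not overlap (bounded retries).  B beads fill the
    solids uniformly; an optional A corona shell is added around each core
    and excluded from core statistics downstream by construction.
    """
    shapes = list(shapes)
    if len(shapes) != n_micelles:
        raise ParameterError("len(shapes) must equal n_micelles")
    worm_radius = radius if worm_radius is None else worm_radius
    worm_length = 10.0 * worm_radius if worm_length is None else worm_length
    extents = [
        radius if s == SPHERE else 0.5 * np.hypot(worm_length, 2 * worm_radius)
        for s in shapes
    ]
    if max(extents, default=0.0) >= box_edge / 2.0:
        raise ParameterError("micelle extents do not fit the box")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF1C5]))

    centers: list[np.ndarray] = []
    for ext in extents:
        for _ in range(2000):
            c = rng.uniform(0.0, box_edge, 3)
            ok = True
            for c2, ext2 in zip(centers, extents):
                d = c - c2
                d -= box_edge * np.round(d / box_edge)
                if np.linalg.norm(d) < ext + ext2 + 1.0:
                    ok = False
                    break
            if ok:
                centers.append(c)
                break
        else:
            raise InitializationError("could not place micelles without overlap")

    pos_list, type_list, chain_list = [], [], []
    for k, (s, c) in enumerate(zip(shapes, centers)):
        if s == SPHERE:
            vol = 4.0 / 3.0 * np.pi * radius**3
            n = max(10, int(points_per_volume * vol))
            pts = _uniform_ball(rng, n, radius)
        else:
            vol = np.pi * worm_radius**2 * worm_length
            n = max(10, int(points_per_volume * vol))
            pts = _uniform_cylinder(rng, n, worm_radius, worm_length) @ _random_rotation(rng).T
        pos_list.append((pts + c) % box_edge)
        type_list.append(np.full(n, BEAD_B, dtype=np.uint8))
        chain_list.append(np.full(n, k))
        if corona_shell:
            sh = _uniform_ball(rng, n // 2, 1.0)
            sh /= np.linalg.norm(sh, axis=1, keepdims=True)
            shell_r = (radius if s == SPHERE else worm_radius) + 1.0
            pos_list.append((sh * shell_r + c) % box_edge)
            type_list.append(np.full(n // 2, BEAD_A, dtype=np.uint8))
            chain_list.append(np.full(n // 2, k))

    if pos_list:
        positions = np.concatenate(pos_list)
        types = np.concatenate(type_list)
        chains = np.concatenate(chain_list)
    else:
        positions = np.zeros((0, 3))
        types = np.zeros(0, dtype=np.uint8)
        chains = np.zeros(0, dtype=np.int64)
    frames = [
        XYZFrame(
            positions=positions.copy(),
            box_edge=box_edge,
            time=float(i),
            bead_type=types.copy(),
            chain_index=chains.copy(),
        )
        for i in range(n_frames)
    ]
    meta = {
        "generator": "gen_fixture_trajectory",
        "seed": seed,
        "shapes": shapes,
        "radius": radius,
        "worm_radius": worm_radius,
        "worm_length": worm_length,
    }
    return Trajectory(frames=frames, metadata=meta)


def _hill(dose, ic50: float, h: float, top: float = 1.0, bottom: float = 0.0):
    dose = np.asarray(dose, dtype=float)
    out = np.where(dose > 0, bottom + (top - bottom) / (1.0 + (ic50 / np.where(dose > 0, dose, 1.0)) ** h), bottom)
    return out


def gen_dose_response(
    ic50_a: float,
    hill_a: float,
    ic50_b: float,
    hill_b: float,
    doses_a,
    doses_b,
    synergy_bump: dict | None = None,
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
    multiplicative_noise: bool = False,
):
    """Bliss-independent dose-response grid with optional synergy bump.

    Single-agent inhibitions follow Hill curves (top 1, bottom 0); the
    combination equals the Bliss expectation plus any ``{(i, j): bump}``
    entries; replicates then receive additive (default) or multiplicative
    Gaussian noise and are clipped to [0, 1].  Returns a
    :class:`triblock.synergy.DoseResponseGrid`.
    """
    from .synergy import DoseResponseGrid, bliss_expectation

    if min(ic50_a, ic50_b) <= 0:
        raise ParameterError("IC50 values must be positive")
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    if np.any(doses_a < 0) or np.any(doses_b < 0):
        raise ParameterError("doses must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD05E]))
    fa = _hill(doses_a, ic50_a, hill_a)
    fb = _hill(doses_b, ic50_b, hill_b)
    clean = bliss_expectation(fa[:, None], fb[None, :])
    for (i, j), bump in (synergy_bump or {}).items():
        clean[i, j] += bump
    reps = np.repeat(clean[None, :, :], replicates, axis=0)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, reps.shape)
        reps = reps * (1.0 + noise) if multiplicative_noise else reps + noise
    reps = np.clip(reps, 0.0, 1.0)
    return DoseResponseGrid(
        doses_a=doses_a,
        doses_b=doses_b,
        inhibition=reps.mean(axis=0),
        replicates=replicates,
        replicate_stack=reps,
    )
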