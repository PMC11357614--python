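"""Temperature / block-ratio sweeps and the theory overlay.

This is the pipeline behind the composite phase diagram: run the Langevin
self-assembly model over a (T, 2 N_B/N_A) grid, call each point spherical /
coexistence / wormlike from its worm mass fraction, fit the lumped
coefficients of the closed-form scaling boundary to the observed transition
midpoints, and report how often theory and simulation agree.  A separate
helper runs replicate pairs flanking the transition at one ratio to compute
the sphere/worm core-diameter ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FitError, ParameterError, TriblockError
from .forcefield import ChainTopology, ThermalMap
from .morphology import MorphologyConfig, MorphologySummary, diameter_ratio, summarize_trajectory
from .simulate import RunConfig, run
from .theory import TheoryParams, classify_theory, fit_boundary_coefficients

__all__ = [
    "RATIO_SERIES",
    "PhasePoint",
    "PhaseDiagramResult",
    "SweepConfig",
    "AffineMap",
    "topology_for_ratio",
    "sweep",
    "fit_theory_overlay",
    "calibrate_temperature_axis",
    "flanking_diameter_ratio",
    "default_sweep_config",
    "desk_sweep_config",
]

SPHERICAL = "spherical"
COEXISTENCE = "coexistence"
WORMLIKE = "wormlike"

#: Block compositions realizing each plotted ratio 2 n_B / n_A: the PEG
#: block is held at 8 beads and the end blocks vary (total length 10-16
#: beads, so the bead concentration stays comparable across the series).
RATIO_SERIES: dict[float, tuple[int, int]] = {
    0.25: (1, 8),
    0.5: (2, 8),
    0.75: (3, 8),
    1.0: (4, 8),
}

#: Worm-mass-fraction thresholds for the three-way phase call.
WORM_FRACTION_LO = 0.2
WORM_FRACTION_HI = 0.8


def topology_for_ratio(ratio: float) -> ChainTopology:
    """Chain topology for a plotted ratio 2 n_B/n_A from the standard series."""
    try:
        n_b, n_a = RATIO_SERIES[round(float(ratio), 6)]
    except KeyError:
        raise ParameterError(
            f"no composition tabulated for ratio {ratio}; known: {sorted(RATIO_SERIES)}"
        ) from None
    return ChainTopology(n_B_per_end=n_b, n_A=n_a)


@dataclass
class PhasePoint:
    """One grid point of the simulated phase diagram."""

    temperature: float
    ratio: float  # 2 N_B / N_A
    worm_mass_fraction: float
    phase: str
    replicate_seeds: list
    summaries: list = field(default_factory=list, repr=False)
    failed: bool = False


@dataclass
class PhaseDiagramResult:
    """Grid of phase points plus the fitted theory overlay."""

    points: list
    theory: TheoryParams | None = None
    agreement_fraction: float | None = None
    diameter_ratio_mean: float | None = None
    diameter_ratio_sd: float | None = None
    master_seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temperature": [p.temperature for p in self.points],
                "ratio": [p.ratio for p in self.points],
                "worm_mass_fraction": [p.worm_mass_fraction for p in self.points],
                "phase": [p.phase for p in self.points],
                "failed": [p.failed for p in self.points],
            }
        )

    def to_json(self, path=None) -> str:
        d = {
            "master_seed": self.master_seed,
            "agreement_fraction": self.agreement_fraction,
            "diameter_ratio_mean": self.diameter_ratio_mean,
            "diameter_ratio_sd": self.diameter_ratio_sd,
            "points": self.to_frame().to_dict(orient="records"),
        }
        if self.theory is not None:
            d["theory"] = {
                "chi_G": self.theory.chi_G,
                "chi_H": self.theory.chi_H,
                "boundary_C": self.theory.boundary_C,
                "boundary_D": self.theory.boundary_D,
                "v_tilde_o": self.theory.v_tilde_o,
            }
        s = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


@dataclass
class SweepConfig:
    """Everything needed to replay a phase-diagram sweep exactly."""

    temperatures: tuple
    ratios: tuple
    replicates: int = 3
    n_chains: int = 100
    volume_fraction: float = 0.15
    tmap: ThermalMap = field(default_factory=ThermalMap)
    dt: float = 0.005
    gamma: float = 1.0
    n_warmup: int = 1_000
    n_equil: int = 40_000
    n_prod: int = 16_000
    stride: int = 1_600
    master_seed: int = 0
    morphology: MorphologyConfig = field(default_factory=MorphologyConfig)

    def run_config(self, temperature: float, ratio: float, replicate: int) -> RunConfig:
        seed = derive_seed(self.master_seed, ratio, temperature, replicate)
        return RunConfig(
            topology=topology_for_ratio(ratio),
            n_chains=self.n_chains,
            volume_fraction=self.volume_fraction,
            temperature=temperature,
            tmap=self.tmap,
            dt=self.dt,
            gamma=self.gamma,
            n_warmup=self.n_warmup,
            n_equil=self.n_equil,
            n_prod=self.n_prod,
            stride=self.stride,
            seed=seed,
        )


def derive_seed(master_seed: int, ratio: float, temperature: float, replicate: int) -> int:
    """Deterministic per-run child seed (< 2^31) from the master seed."""
    ss = np.random.SeedSequence(
        [int(master_seed), int(round(ratio * 1000)), int(round(temperature * 1000)), int(replicate)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def default_sweep_config(master_seed: int = 0) -> SweepConfig:
    """Library-default grid: 5 temperatures x 4 ratios x 3 replicates."""
    return SweepConfig(
        temperatures=tuple(np.round(np.linspace(0.5, 1.2, 5), 4)),
        ratios=tuple(sorted(RATIO_SERIES)),
        replicates=3,
        master_seed=master_seed,
    )


def desk_sweep_config(master_seed: int = 0) -> SweepConfig:
    """Desk-scale grid used by the worked examples and the validation suite.

    4 temperatures x 3 ratios x 1 replicate with 100-chain systems
    (1000-1600 beads) and 40k equilibration / 16k production steps: small
    enough for interactive use, long enough that low-temperature quench
    artifacts (elongated transients from the initial aggregation) anneal
    away.  Single-replicate calls near the boundary stay noisy; the library
    default uses 3 replicates.
    """
    return SweepConfig(
        temperatures=(0.5, 0.733, 0.967, 1.2),
        ratios=(0.5, 0.75, 1.0),
        replicates=1,
        master_seed=master_seed,
    )


def _phase_call(worm_fraction: float) -> str:
    if worm_fraction < WORM_FRACTION_LO:
        return SPHERICAL
    if worm_fraction > WORM_FRACTION_HI:
        return WORMLIKE
    return COEXISTENCE


def sweep(config: SweepConfig, log=None) -> PhaseDiagramResult:
    """Run the full (T, ratio) grid and call a phase per point.

    Individual run failures are logged and marked on the point; the sweep
    continues.  The result contains everything needed for exact replay
    (configs are derived from the master seed alone).
    """
    if not config.temperatures or not config.ratios:
        raise ParameterError("sweep grid must be non-empty")
    points: list[PhasePoint] = []
    for ratio in config.ratios:
        for T in config.temperatures:
            fracs, seeds, summaries = [], [], []
            failed = False
            for rep in range(config.replicates):
                rc = config.run_config(T, ratio, rep)
                seeds.append(rc.seed)
                try:
                    traj = run(rc, log=log)
                    summ = summarize_trajectory(traj, config.morphology)
                    summaries.append(summ)
                    fracs.append(summ.worm_mass_fraction)
                except TriblockError as exc:
                    failed = True
                    if log is not None:
                        log(f"point T={T} ratio={ratio} rep={rep} failed: {exc}")
            wf = float(np.mean(fracs)) if fracs else float("nan")
            points.append(
                PhasePoint(
                    temperature=float(T),
                    ratio=float(ratio),
                    worm_mass_fraction=wf,
                    phase=_phase_call(wf) if fracs else "failed",
                    replicate_seeds=seeds,
                    summaries=summaries,
                    failed=failed,
                )
            )
            if log is not None:
                log(f"point T={T:.3f} ratio={ratio} worm_fraction={wf:.3f}")
    return PhaseDiagramResult(points=points, master_seed=config.master_seed)


def transition_midpoints(result: PhaseDiagramResult):
    """Per-ratio transition temperature where the worm fraction crosses 1/2.

    Linear interpolation between the bracketing grid temperatures; columns
    that never cross contribute nothing.
    """
    t_mid, ratios = [], []
    df = result.to_frame()
    for ratio, col in df[~df.failed].groupby("ratio"):
        col = col.sort_values("temperature")
        wf = col.worm_mass_fraction.to_numpy()
        T = col.temperature.to_numpy()
        for i in range(len(T) - 1):
            if (wf[i] - 0.5) * (wf[i + 1] - 0.5) < 0:
                t = T[i] + (0.5 - wf[i]) / (wf[i + 1] - wf[i]) * (T[i + 1] - T[i])
                t_mid.append(float(t))
                ratios.append(float(ratio))
                break
            if wf[i] == 0.5:
                t_mid.append(float(T[i]))
                ratios.append(float(ratio))
                break
    return np.array(t_mid), np.array(ratios)


def fit_theory_overlay(
    result: PhaseDiagramResult, theory_init: TheoryParams | None = None
) -> PhaseDiagramResult:
    """Fit the lumped boundary coefficients and score the overlay.

    Least squares of the closed-form boundary through the simulated
    transition midpoints (linear in C and D; D alone when only one column
    shows a transition), then the fraction of non-coexistence grid points
    whose theory classification matches the simulation call.
    """
    params = theory_init or TheoryParams()
    df = result.to_frame()
    calls = set(df[~df.failed].phase)
    if SPHERICAL not in calls or WORMLIKE not in calls:
        raise FitError("degenerate sweep: need both spherical and wormlike points to fit")
    t_mid, ratios = transition_midpoints(result)
    if len(t_mid) >= 2:
        fitted = fit_boundary_coefficients(t_mid, ratios, params)
    elif len(t_mid) == 1:
        # one column: keep C, solve D exactly from the single midpoint
        from .theory import boundary_rhs

        q = boundary_rhs(float(ratios[0]), params) / params.v_tilde_o
        D = (params.boundary_C - q) * float(t_mid[0])
        fitted = replace(params, chi_H=D / 2.0)
    else:
        raise FitError("no transition midpoint found on the grid")
    keep = df[(~df.failed) & (df.phase != COEXISTENCE)]
    match = [
        classify_theory(row.temperature, row.ratio, fitted) == row.phase
        for row in keep.itertuples()
    ]
    agreement = float(np.mean(match)) if match else float("nan")
    return replace(result, theory=fitted, agreement_fraction=agreement)


@dataclass(frozen=True)
class AffineMap:
    """Affine calibration between reduced temperature and degrees Celsius."""

    slope: float  # degC per reduced unit
    intercept: float  # degC at reduced T = 0

    def to_celsius(self, t_reduced):
        return self.slope * np.asarray(t_reduced, dtype=float) + self.intercept

    def to_reduced(self, t_celsius):
        return (np.asarray(t_celsius, dtype=float) - self.intercept) / self.slope


def calibrate_temperature_axis(
    anchors=None,
    *,
    t_star_reduced: float | None = None,
    t_below: float | None = None,
    t_above: float | None = None,
    celsius_low: float = 25.0,
    celsius_high: float = 37.0,
) -> AffineMap:
    """Affine map from reduced temperature to degrees Celsius.

    Two modes:

    * ``anchors``: two or more ``(t_reduced, t_celsius)`` pairs; the map is
      the least-squares affine fit and must reproduce every anchor to 1e-9
      (inconsistent anchors raise).
    * phase anchors: the copolymer is observed liquid (spherical micelles)
      at ``celsius_low`` and gel (wormlike) at ``celsius_high``.  Given the
      reduced boundary temperature ``t_star_reduced`` at the experimental
      block ratio and the reduced grid temperatures ``t_below``/``t_above``
      flanking it, the map sends the boundary to the Celsius midpoint with
      slope ``(celsius_high - celsius_low) / (t_above - t_below)``, so the
      low observation lands on the spherical side and the high one on the
      wormlike side.
    """
    if anchors is not None:
        anchors = np.asarray(anchors, dtype=float)
        if len(anchors) < 2:
            raise ParameterError("need at least two anchors")
        A = np.stack([anchors[:, 0], np.ones(len(anchors))], axis=1)
        coeff, *_ = np.linalg.lstsq(A, anchors[:, 1], rcond=None)
        resid = A @ coeff - anchors[:, 1]
        if np.max(np.abs(resid)) > 1e-9:
            raise ParameterError(f"inconsistent anchors (max residual {np.max(np.abs(resid)):.3g})")
        if coeff[0] == 0:
            raise ParameterError("anchors give a degenerate (zero-slope) map")
        return AffineMap(slope=float(coeff[0]), intercept=float(coeff[1]))
    if t_star_reduced is None or t_below is None or t_above is None:
        raise ParameterError("provide either anchors or all three reduced temperatures")
    if not t_below < t_star_reduced < t_above:
        raise ParameterError("require t_below < t_star_reduced < t_above")
    if celsius_high <= celsius_low:
        raise ParameterError("require celsius_high > celsius_low")
    slope = (celsius_high - celsius_low) / (t_above - t_below)
    mid_c = 0.5 * (celsius_low + celsius_high)
    return AffineMap(slope=slope, intercept=mid_c - slope * t_star_reduced)


def experimental_block_ratio(
    mn_b_block: float = 1570.0,
    mn_a_block: float = 1500.0,
    monomer_mass_a: float = 44.05,
    monomer_mass_b: float = 86.09,
) -> float:
    """Plotted ratio 2 N_B/N_A of the synthesized polymer from block masses.

    Defaults: PEG repeat 44.05 g/mol; hydrophobe repeat averaged over an
    equimolar delta-valerolactone (100.12) / lactyl unit (72.06) composition.
    """
    n_b = mn_b_block / monomer_mass_b
    n_a = mn_a_block / monomer_mass_a
    return 2.0 * n_b / n_a


def flanking_diameter_ratio(
    ratio: float = 0.75,
    t_sphere: float = 0.6,
    t_worm: float = 1.05,
    replicates: int = 3,
    base: SweepConfig | None = None,
    master_seed: int = 0,
    log=None,
):
    """Sphere/worm core-diameter ratio from replicate runs flanking the transition.

    Runs ``replicates`` seeded pairs (one run just below, one just above the
    transition) at the given block ratio, classifies micelles with the
    gyration-tensor pipeline and returns ``(mean, sd, per-replicate ratios)``.
    """
    cfg = base or desk_sweep_config(master_seed)
    cfg = replace(cfg, master_seed=master_seed)
    per_replicate: list[list[MorphologySummary]] = []
    for rep in range(replicates):
        summaries = []
        for T in (t_sphere, t_worm):
            rc = cfg.run_config(T, ratio, rep)
            traj = run(rc, log=log)
            summaries.append(summarize_trajectory(traj, cfg.morphology))
        per_replicate.append(summaries)
    mean, sd = diameter_ratio(per_replicate)
    return mean, sd, per_replicate
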