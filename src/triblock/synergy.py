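"""Two-drug combination statistics: Bliss independence and Hill IC50 fits.

Inhibition throughout is the fractional growth inhibition relative to an
untreated control, ``inhibition = 1 - viability``; values live in [0, 1].
The Bliss expectation for two independently acting agents is
``E = fa + fb - fa*fb``; the delta-Bliss reported here is
``observed - E`` so that POSITIVE values mean synergy (killing in excess of
independent action) — the convention is embedded in output metadata.

Dose-response curves are fit with the four-parameter Hill (log-logistic)
model ``inhibition = bottom + (top - bottom) / (1 + (IC50/dose)^h)`` by
bounded deterministic least squares on the log-dose scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError, ParameterError

__all__ = [
    "DoseResponseGrid",
    "HillFit",
    "DELTA_BLISS_CONVENTION",
    "bliss_expectation",
    "delta_bliss",
    "synergy_matrix",
    "hill_fit",
    "read_grid_csv",
    "write_synergy_csv",
]

DELTA_BLISS_CONVENTION = "observed_minus_expectation (positive = synergy)"


@dataclass
class DoseResponseGrid:
    """Fractional-inhibition matrix over a two-agent dose grid.

    ``doses_a`` indexes rows, ``doses_b`` columns; a zero dose of the
    partner agent (index 0 by convention) provides the monotherapy data the
    Bliss calculation needs.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    inhibition: np.ndarray  # (len_a, len_b) in [0, 1]
    replicates: int = 1
    replicate_stack: np.ndarray | None = None  # (replicates, len_a, len_b)

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.inhibition = np.asarray(self.inhibition, dtype=float)
        if self.inhibition.shape != (len(self.doses_a), len(self.doses_b)):
            raise ParameterError("inhibition matrix shape must match dose vectors")
        for d in (self.doses_a, self.doses_b):
            if np.any(np.diff(d) <= 0):
                raise ParameterError("dose levels must be strictly increasing")
        if np.any(self.inhibition < 0) or np.any(self.inhibition > 1):
            raise ParameterError("inhibition values must lie in [0, 1]")


@dataclass
class HillFit:
    """Four-parameter Hill fit result."""

    ic50: float
    hill: float
    top: float
    bottom: float
    residual_norm: float
    converged: bool
    convention: str = "inhibition = bottom + (top-bottom)/(1+(IC50/dose)^h)"

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ParameterError("IC50 must be positive")
        if self.bottom > self.top:
            raise ParameterError("bottom plateau must not exceed top")


def _check_fraction(name, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ParameterError(f"{name} must lie in [0, 1]")
    return x


def bliss_expectation(fa, fb):
    """Independent-action expectation ``fa + fb - fa*fb`` (symmetric)."""
    fa = _check_fraction("fa", fa)
    fb = _check_fraction("fb", fb)
    out = fa + fb - fa * fb
    return float(out) if np.ndim(out) == 0 else out


def delta_bliss(observed, fa, fb):
    """Observed minus Bliss expectation; positive = synergy."""
    observed = _check_fraction("observed", observed)
    out = observed - bliss_expectation(fa, fb)
    return float(out) if np.ndim(out) == 0 else out


def synergy_matrix(grid: DoseResponseGrid) -> np.ndarray:
    """Delta-Bliss matrix aligned to the dose grid.

    The monotherapy inhibitions are taken from the zero-dose row/column of
    the partner agent, which must be present.
    """
    if grid.doses_a[0] != 0.0:
        raise ParameterError(
            f"missing agent-B monotherapy data: first agent-A dose is "
            f"{grid.doses_a[0]}, expected 0"
        )
    if grid.doses_b[0] != 0.0:
        raise ParameterError(
            f"missing agent-A monotherapy data: first agent-B dose is "
            f"{grid.doses_b[0]}, expected 0"
        )
    fa = grid.inhibition[:, 0]  # agent A alone (B dose = 0)
    fb = grid.inhibition[0, :]  # agent B alone
    expectation = bliss_expectation(fa[:, None], fb[None, :])
    return grid.inhibition - expectation


def _hill_model(log_dose, log_ic50, h, top, bottom):
    return bottom + (top - bottom) / (1.0 + np.exp(-h * (log_dose - log_ic50)))


def hill_fit(doses, inhibitions, require_span: bool = True) -> HillFit:
    """Fit the four-parameter Hill model; deterministic given the data.

    Requires >= 4 distinct positive dose levels whose responses straddle
    the half-way point between the observed extremes (the inflection must
    be spanned, otherwise the IC50 would be an extrapolation and an error
    is raised instead).
    """
    doses = np.asarray(doses, dtype=float)
    y = _check_fraction("inhibitions", inhibitions)
    keep = doses > 0
    doses, y = doses[keep], y[keep]
    if len(np.unique(doses)) < 4:
        raise ParameterError("need at least 4 distinct positive dose levels")
    order = np.argsort(doses)
    doses, y = doses[order], y[order]
    ymin, ymax = float(y.min()), float(y.max())
    if require_span:
        mid = 0.5 * (ymin + ymax)
        if ymax - ymin < 0.05 or not (y[0] < mid and y[-1] > mid or y[0] > mid and y[-1] < mid):
            raise FitError(
                "dose range does not span the response inflection; refusing "
                "to extrapolate an IC50"
            )
    x = np.log(doses)
    # initialization from the data midpoint
    mid = 0.5 * (ymin + ymax)
    i_mid = int(np.argmin(np.abs(y - mid)))
    p0 = (x[i_mid], 1.0, min(ymax + 0.05, 1.0), max(ymin - 0.05, 0.0))
    span = x.max() - x.min()
    bounds = (
        [x.min() - 2 * span - 1.0, 0.05, 0.0, 0.0],
        [x.max() + 2 * span + 1.0, 20.0, 1.0, 1.0],
    )
    p0 = tuple(np.clip(p0, bounds[0], bounds[1]))
    try:
        popt, _ = curve_fit(
            _hill_model, x, y, p0=p0, bounds=bounds, method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"Hill fit did not converge: {exc}") from exc
    log_ic50, h, top, bottom = popt
    resid = y - _hill_model(x, *popt)
    if bottom > top:  # reparametrize the (rare) inverted solution
        top, bottom, h = bottom, top, -h
    return HillFit(
        ic50=float(np.exp(log_ic50)),
        hill=float(h),
        top=float(top),
        bottom=float(bottom),
        residual_norm=float(np.linalg.norm(resid)),
        converged=True,
    )


def read_grid_csv(path) -> DoseResponseGrid:
    """Read a dose-response grid from CSV.

    Two layouts are accepted:

    * long: columns ``dose_a, dose_b, inhibition`` (replicate rows averaged),
    * matrix: first column agent-A doses, header row agent-B doses.
    """
    df = pd.read_csv(path)
    cols = {c.lower() for c in df.columns}
    if {"dose_a", "dose_b", "inhibition"} <= cols:
        df.columns = [c.lower() for c in df.columns]
        piv = df.pivot_table(index="dose_a", columns="dose_b", values="inhibition")
        return DoseResponseGrid(
            doses_a=piv.index.to_numpy(),
            doses_b=piv.columns.to_numpy(dtype=float),
            inhibition=piv.to_numpy(),
        )
    doses_a = df.iloc[:, 0].to_numpy(dtype=float)
    doses_b = np.array([float(c) for c in df.columns[1:]])
    return DoseResponseGrid(
        doses_a=doses_a, doses_b=doses_b, inhibition=df.iloc[:, 1:].to_numpy(dtype=float)
    )


def write_synergy_csv(grid: DoseResponseGrid, delta: np.ndarray, path) -> None:
    """Write the delta-Bliss matrix (and convention metadata) next to CSV."""
    df = pd.DataFrame(delta, index=grid.doses_a, columns=grid.doses_b)
    df.index.name = "dose_a"
    df.to_csv(path)
    meta = {"delta_bliss_convention": DELTA_BLISS_CONVENTION}
    Path(path).with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))
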