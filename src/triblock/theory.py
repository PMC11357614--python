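"""Flory-type scaling theory for the spherical-to-wormlike micelle transition.

The physical picture: a dense spherical core of radius ``R_B`` formed by the
hydrophobic B blocks, decorated by a grafted corona of hydrophilic A blocks
of size ``R_A``.  With unit prefactors (every relation is a scaling law):

* corona:           R_A = f^(1/5) v_A^(1/5) b_A N_A^(3/5)
* core:             R_B = N_B^(1/3) b_B u^(-1/3),   u = v_B phi_B^(5/2) / b_B^3
* aggregation no.:  f   = N_B^(5/3) N_A^(-3) (b_B/b_A)^5 u^(-5/3) v_A^s
* Flory energies:   F   = R^2/(N b^2) + v f N^2 / R^3 evaluated per block

``s`` (``closure_va_exponent``) is +1 by default; substituting f back into
the corona law then gives R_A(f) = R_B v_A^(2/5), i.e. the closure equates
corona and core sizes up to a power of the corona excluded volume (exact for
v_A = 1).  ``s = -1`` gives the strictly geometric closure R_A(f) = R_B.

Equating F_A ~ F_B and writing the dimensionless core excluded volume as
``v~_B = v~_o (1 - 2 chi)`` with ``chi = G + H/T`` yields the closed-form
phase boundary (with b_A = b_B)::

    v~_o (C - D/T*) = (r v_A^(4/5) - 1) / (r^3 v_A),   r = N_B / N_A

with lumped coefficients ``C = 1 - 2G``, ``D = 2H``.  For ratios where the
right-hand side never meets the left for positive T the copolymer is
spherical at all temperatures; the infimum of ratios with a solution is the
asymptote of the phase diagram.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ParameterError

__all__ = [
    "TheoryParams",
    "PhaseBoundary",
    "corona_size",
    "core_size",
    "aggregation_number",
    "free_energies",
    "chi_of_T",
    "boundary_rhs",
    "phase_boundary",
    "classify_theory",
    "predict_diameter_ratio",
]

SPHERICAL = "spherical"
WORMLIKE = "wormlike"

#: Densest sphere packing (FCC/HCP), pi / sqrt(18).
DENSEST_PACKING = np.pi / np.sqrt(18.0)
#: Random close packing of equal spheres.
RANDOM_CLOSE_PACKING = 0.64


@dataclass(frozen=True)
class TheoryParams:
    """All symbols of the scaling theory, with unit-prefactor defaults.

    ``chi_G`` / ``chi_H`` are the empirical Flory-Huggins coefficients
    (``chi = G + H/T``); they are lumped fit parameters calibrated against
    the simulated transition, not microscopic constants.  The defaults place
    the boundary inside the default simulation window (reduced T in
    [0.5, 1.0]) with the asymptote near a plotted ratio 2 N_B/N_A of 0.4.
    """

    N_A: float = 16.0
    N_B: float = 6.0
    b_A: float = 1.0
    b_B: float = 1.0
    v_A: float = 1.0
    v_B: float = 1.0
    phi_B: float = 1.0
    v_tilde_o: float = 1.0
    chi_G: float = 60.5
    chi_H: float = -43.0
    prefactor_corona: float = 1.0
    prefactor_core: float = 1.0
    prefactor_f: float = 1.0
    closure_va_exponent: float = 1.0  # +1 = as-derived chain; -1 = geometric R_A(f)=R_B
    t_bracket: tuple = (1e-3, 1e3)  # temperature interval searched for T*

    def __post_init__(self) -> None:
        for name in ("N_A", "N_B", "b_A", "b_B", "v_A", "v_B", "v_tilde_o"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if not 0.0 < self.phi_B <= 1.0:
            raise ParameterError("phi_B must lie in (0, 1]")

    @property
    def boundary_C(self) -> float:
        return 1.0 - 2.0 * self.chi_G

    @property
    def boundary_D(self) -> float:
        return 2.0 * self.chi_H

    @property
    def u(self) -> float:
        """Effective dimensionless core excluded volume v_B phi_B^(5/2)/b_B^3."""
        return self.v_B * self.phi_B ** 2.5 / self.b_B**3


@dataclass
class PhaseBoundary:
    """Boundary temperatures T*(ratio) over a grid of 2 N_B/N_A values."""

    ratios: np.ndarray  # plotted abscissa, 2 N_B / N_A
    t_star: np.ndarray  # NaN where no positive solution exists
    asymptote_ratio: float | None  # infimum abscissa admitting a boundary
    converged: np.ndarray  # per-point root-finder success

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ratio_2NB_over_NA": self.ratios,
                "t_star": self.t_star,
                "has_transition": np.isfinite(self.t_star),
            }
        )


def corona_size(params: TheoryParams, f: float) -> float:
    """Corona extent R_A of f good-solvent chains grafted to the core."""
    if f < 1:
        raise ParameterError("aggregation number f must be >= 1")
    p = params
    return p.prefactor_corona * f**0.2 * p.v_A**0.2 * p.b_A * p.N_A**0.6


def core_size(params: TheoryParams) -> float:
    """Core radius R_B of the collapsed B block at core concentration phi_B."""
    p = params
    return p.prefactor_core * p.N_B ** (1.0 / 3.0) * p.b_B * p.u ** (-1.0 / 3.0)


def aggregation_number(params: TheoryParams) -> float:
    """Chains per micelle from the corona/core closure (see module docs)."""
    p = params
    f = (
        p.prefactor_f
        * p.N_B ** (5.0 / 3.0)
        * p.N_A**-3.0
        * (p.b_B / p.b_A) ** 5
        * p.u ** (-5.0 / 3.0)
        * p.v_A**p.closure_va_exponent
    )
    if f <= 0 or not np.isfinite(f):
        raise ParameterError(f"aggregation number {f} outside physical regime")
    return float(f)


def free_energies(params: TheoryParams, T: float | None = None) -> tuple[float, float]:
    """Per-chain Flory energies (F_A, F_B) of corona and core blocks.

    With ``T`` given, the dimensionless core excluded volume is evaluated
    from the empirical chi(T) law, ``v~_B(T) = v~_o (1 - 2 chi(T))``,
    instead of the static ``v_B/b_B^3``; this is the route through which
    the free-energy crossover reproduces the closed-form phase boundary.
    The common positive prefactor ``N_B^(-1/3) |u|^(-2/3)`` uses the
    magnitude of the effective excluded volume: in the collapsed (wormlike)
    regime v~_B is negative and the fractional power would otherwise be
    complex; the F_A = F_B crossing locus is unaffected.
    """
    p = params
    vtb = float(v_tilde_B(T, p)) if T is not None else p.v_B / p.b_B**3
    u = vtb * p.phi_B ** 2.5
    if u == 0.0:
        raise ParameterError("vanishing core excluded volume: core size diverges")
    pref = p.N_B ** (-1.0 / 3.0) * abs(u) ** (-2.0 / 3.0)
    r = p.N_B / p.N_A
    bracket_B = 1.0 + r**3 * (p.b_B / p.b_A) ** 5 * vtb * p.v_A**p.closure_va_exponent
    bracket_A = r * (p.b_B / p.b_A) ** 2 * p.v_A ** (0.4 * (1.0 + p.closure_va_exponent))
    return pref * bracket_A, pref * bracket_B


def chi_of_T(T: float, G: float, H: float) -> float:
    """Empirical Flory-Huggins parameter ``chi = G + H/T``."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ParameterError("temperature must be positive")
    out = G + H / T
    return float(out) if out.ndim == 0 else out


def v_tilde_B(T, params: TheoryParams):
    """Dimensionless core excluded volume v~_o (1 - 2 chi(T)) = v~_o (C - D/T)."""
    return params.v_tilde_o * (params.boundary_C - params.boundary_D / np.asarray(T, dtype=float))


def boundary_rhs(ratio_2: float, params: TheoryParams) -> float:
    """Right-hand side Q(r) of the closed-form boundary, r = ratio_2 / 2.

    Assumes b_A = b_B (the simplification used to reach the closed form);
    written for the configured closure exponent, which reproduces the
    printed ``(r v_A^(4/5) - 1) / (r^3 v_A)`` at the default ``s = +1``.
    """
    if ratio_2 <= 0:
        raise ParameterError("ratio must be positive")
    r = ratio_2 / 2.0
    s = params.closure_va_exponent
    return (r * params.v_A ** (0.4 * (1.0 + s)) - 1.0) / (r**3 * params.v_A**s)


def _t_star(ratio_2: float, params: TheoryParams):
    """Solve v~_o (C - D/T) = Q(r) for T by bracketed root finding."""
    q = boundary_rhs(ratio_2, params)
    lo, hi = params.t_bracket

    def g(T):
        return float(v_tilde_B(T, params)) - q

    glo, ghi = g(lo), g(hi)
    if glo == 0.0:
        return lo, True
    if ghi == 0.0:
        return hi, True
    if glo * ghi > 0:
        return np.nan, True  # no sign change: no transition in the bracket
    try:
        return brentq(g, lo, hi, xtol=1e-10, rtol=8.9e-16), True
    except RuntimeError:
        return np.nan, False


def phase_boundary(params: TheoryParams, ratio_grid) -> PhaseBoundary:
    """Boundary temperature T* for each plotted ratio 2 N_B/N_A in the grid.

    Ratios without a positive solution are marked NaN ("spherical for all
    T"); the asymptote is refined by bisection on the ratio axis between the
    last no-transition and first with-transition grid ratios (or below the
    whole grid when every point has a boundary).
    """
    ratios = np.asarray(ratio_grid, dtype=float)
    if ratios.size == 0 or np.any(ratios <= 0):
        raise ParameterError("ratio grid must be non-empty and positive")
    t_star = np.full(ratios.shape, np.nan)
    converged = np.ones(ratios.shape, dtype=bool)
    for i, r2 in enumerate(ratios):
        t_star[i], converged[i] = _t_star(float(r2), params)
    has = np.isfinite(t_star)
    asymptote = None
    if has.any():
        lo_grid = 1e-6 if has.all() else float(ratios[~has].max())
        hi_grid = float(ratios[has].min())

        def exists(r2: float) -> bool:
            t, _ = _t_star(r2, params)
            return np.isfinite(t)

        lo, hi = lo_grid, hi_grid
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if exists(mid):
                hi = mid
            else:
                lo = mid
        asymptote = 0.5 * (lo + hi)
    return PhaseBoundary(ratios=ratios, t_star=t_star, asymptote_ratio=asymptote, converged=converged)


def classify_theory(T: float, ratio_2: float, params: TheoryParams) -> str:
    """Which side of the boundary a (temperature, ratio) point falls on.

    Wormlike when the core excluded volume has collapsed past the threshold,
    ``v~_B(T) <= Q(r)``; the boundary itself is wormlike (closed-boundary
    convention, applied with a 1e-9 relative tolerance so a root-found T*
    classifies consistently).
    """
    q = boundary_rhs(ratio_2, params)
    tol = 1e-9 * (1.0 + abs(q))
    return WORMLIKE if float(v_tilde_B(T, params)) <= q + tol else SPHERICAL


def predict_diameter_ratio(
    packing_sphere: float = RANDOM_CLOSE_PACKING,
    packing_worm: float = DENSEST_PACKING,
    geometry_rule: str | float = "core-collapse",
) -> float:
    """Sphere-to-worm diameter ratio from the two core packing fractions.

    The transverse size of a core packing N Kuhn monomers at packing
    fraction eta scales as eta^(-p); the ratio is then
    ``(packing_worm / packing_sphere)^p``.  Rules:

    * ``"core-collapse"`` (default): p = 5/6, the exponent of the theory's
      own core-size law R_B ~ phi^(-5/6).
    * ``"volume"``: p = 1/3, plain volume conservation of a fixed monomer
      count.
    * a float: use that exponent directly.

    With the defaults (random close packing 0.64 for spheres, densest
    packing pi/sqrt(18) for worms) the rules give 1.13 and 1.05
    respectively.
    """
    for eta in (packing_sphere, packing_worm):
        if not 0.0 < eta <= DENSEST_PACKING + 1e-12:
            raise ParameterError(f"packing fraction {eta} outside (0, {DENSEST_PACKING:.4f}]")
    if isinstance(geometry_rule, str):
        try:
            p = {"core-collapse": 5.0 / 6.0, "volume": 1.0 / 3.0}[geometry_rule]
        except KeyError:
            raise ParameterError(f"unknown geometry rule {geometry_rule!r}") from None
    else:
        p = float(geometry_rule)
    return float((packing_worm / packing_sphere) ** p)


def fit_boundary_coefficients(t_mid, ratio_2, params: TheoryParams) -> TheoryParams:
    """Least-squares (C, D) from observed transition midpoints.

    The boundary temperature is ``T*(r) = D / (C - Q(r)/v~_o)``; the lumped
    coefficients are fit by least squares on the *temperature* residuals
    ``T*(r_i) - T_i``, restricted to the heating-induced branch (``D < 0``
    and ``C`` below every ``Q(r_i)``, so each observed column has a
    boundary: the thermal map is monotone, so the model gels on heating by
    construction).  A fit on the excluded-volume residuals is linear but
    can select the inverted (cooling-induced) branch when the midpoints
    are noisy, which a temperature overlay must not do.  Returns params
    with chi_G/chi_H back-substituted (C = 1 - 2G, D = 2H).
    """
    from scipy.optimize import least_squares

    t_mid = np.asarray(t_mid, dtype=float)
    ratio_2 = np.asarray(ratio_2, dtype=float)
    if t_mid.size < 2:
        raise ParameterError("need at least two transition midpoints to fit (C, D)")
    q = np.array([boundary_rhs(r, params) for r in ratio_2]) / params.v_tilde_o
    c_cap = float(q.min())

    def residuals(x):
        C, D = x
        t_star = D / (C - q)
        return t_star - t_mid

    # deterministic initialization on the admissible branch
    C0 = c_cap - max(1.0, float(q.max() - q.min()))
    D0 = float(np.mean(t_mid)) * (C0 - float(np.mean(q)))
    sol = least_squares(
        residuals,
        x0=(C0, min(D0, -1e-6)),
        bounds=((-np.inf, -np.inf), (c_cap - 1e-9, -1e-9)),
        method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    C, D = sol.x
    return replace(params, chi_G=(1.0 - C) / 2.0, chi_H=D / 2.0)
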