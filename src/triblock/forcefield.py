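"""Coarse-grained force field for BAB (hydrophobe-PEG-hydrophobe) bead-spring chains.

The model follows standard Kremer-Grest practice in reduced Lennard-Jones
units (sigma = 1, eps_BB = 1, bead mass = 1):

* B-B (hydrophobe-hydrophobe): attractive Lennard-Jones, truncated and
  energy-shifted at ``rcut`` — the effective hydrophobic attraction of the
  implicit solvent.
* A-A (PEG-PEG) and A-B: purely repulsive Weeks-Chandler-Andersen (WCA)
  potentials whose strengths depend on temperature.  PEG dehydrates on
  heating, so the A-A repulsion (hydration-shell swelling) *decreases* with
  temperature while the A-B repulsion (block segregation) *increases*.
* Bonds: FENE springs combined with WCA excluded volume on the bonded pair.

All pair functions are vectorised over ``r`` and return
``(energy, force_magnitude)`` where the force magnitude is ``-dU/dr``
(positive = repulsive).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import OverstretchError, ParameterError

__all__ = [
    "BEAD_A",
    "BEAD_B",
    "WCA_CUT",
    "ChainTopology",
    "InteractionParams",
    "ThermalMap",
    "lj_pair",
    "wca_pair",
    "fene_bond",
    "thermal_map",
]

#: Integer bead-type codes used throughout the package.
BEAD_A = 0  # hydrophilic middle block (PEG)
BEAD_B = 1  # hydrophobic end blocks (PVLA)

#: WCA cutoff in units of sigma: the LJ minimum, 2^(1/6).
WCA_CUT = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class ChainTopology:
    """Bead types and bond graph of one linear B...B A...A B...B chain.

    Parameters
    ----------
    n_B_per_end:
        Number of hydrophobic (B) beads in *each* terminal block.
    n_A:
        Number of hydrophilic (A) beads in the middle block.
    """

    n_B_per_end: int
    n_A: int

    def __post_init__(self) -> None:
        if self.n_B_per_end < 1 or self.n_A < 1:
            raise ParameterError(
                f"block sizes must be >= 1 bead, got "
                f"n_B_per_end={self.n_B_per_end}, n_A={self.n_A}"
            )

    @property
    def n_beads(self) -> int:
        return 2 * self.n_B_per_end + self.n_A

    @property
    def block_ratio(self) -> float:
        """Phase-diagram abscissa 2*N_B / N_A (total hydrophobe over PEG)."""
        return 2.0 * self.n_B_per_end / self.n_A

    @property
    def bead_types(self) -> np.ndarray:
        """Ordered type codes along the chain (B...B A...A B...B)."""
        t = np.full(self.n_beads, BEAD_A, dtype=np.uint8)
        t[: self.n_B_per_end] = BEAD_B
        t[self.n_B_per_end + self.n_A :] = BEAD_B
        return t

    @property
    def bonds(self) -> np.ndarray:
        """(n_beads - 1, 2) array of consecutive-bead bond index pairs."""
        i = np.arange(self.n_beads - 1)
        return np.stack([i, i + 1], axis=1)


@dataclass(frozen=True)
class InteractionParams:
    """All pair-interaction parameters at one temperature, in reduced units."""

    eps_BB: float = 1.0
    sigma: float = 1.0
    rcut_BB: float = 2.5
    eps_AA: float = 1.0
    eps_AB: float = 0.5
    fene_k: float = 30.0
    fene_R0: float = 1.5

    def __post_init__(self) -> None:
        for name in ("eps_BB", "sigma", "rcut_BB", "eps_AA", "eps_AB", "fene_k", "fene_R0"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.rcut_BB <= WCA_CUT * self.sigma:
            raise ParameterError(
                f"rcut_BB={self.rcut_BB} must exceed the LJ minimum "
                f"2^(1/6)*sigma={WCA_CUT * self.sigma:.6f}"
            )

    @property
    def max_cutoff(self) -> float:
        """Largest non-bonded interaction range (for neighbor searching)."""
        return max(self.rcut_BB, WCA_CUT * self.sigma)


@dataclass(frozen=True)
class ThermalMap:
    """Phenomenological temperature dependence of the repulsive strengths.

    PEG dehydration on heating is encoded as a monotone interpolation of the
    A-A and A-B WCA strengths between their values at ``t_min`` and ``t_max``:
    eps_AA non-increasing, eps_AB non-decreasing.  Only the linear form is
    implemented; the field exists so configs are explicit about the choice.
    """

    t_min: float = 0.5
    t_max: float = 1.2
    eps_AA_at_tmin: float = 1.0
    eps_AA_at_tmax: float = 0.25
    eps_AB_at_tmin: float = 0.5
    eps_AB_at_tmax: float = 2.0
    form: str = "linear"
    base: InteractionParams = field(default_factory=InteractionParams)

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ParameterError("require t_min < t_max")
        if self.eps_AA_at_tmin < self.eps_AA_at_tmax:
            raise ParameterError("eps_AA must be non-increasing in T")
        if self.eps_AB_at_tmin > self.eps_AB_at_tmax:
            raise ParameterError("eps_AB must be non-decreasing in T")
        if min(self.eps_AA_at_tmax, self.eps_AB_at_tmin) <= 0:
            raise ParameterError("epsilon endpoints must be strictly positive")
        if self.form != "linear":
            raise ParameterError(f"unknown interpolation form {self.form!r}")


def _as_positive(name: str, value: float) -> None:
    if np.any(np.asarray(value) <= 0):
        raise ParameterError(f"{name} must be strictly positive")


def lj_pair(r, eps: float, sigma: float, rcut: float):
    """Truncated and energy-shifted Lennard-Jones pair interaction.

    ``U(r) = 4 eps [(sigma/r)^12 - (sigma/r)^6] - U(rcut)`` for ``r < rcut``,
    zero beyond.  The force is ``-dU/dr`` of the unshifted form (the shift is
    a constant), zero at and beyond the cutoff.
    """
    r = np.asarray(r, dtype=float)
    _as_positive("r", r)
    _as_positive("eps", eps)
    _as_positive("sigma", sigma)
    if rcut <= sigma:
        raise ParameterError(f"rcut={rcut} must exceed sigma={sigma}")
    inside = r < rcut
    sr6 = np.where(inside, (sigma / np.where(inside, r, 1.0)) ** 6, 0.0)
    sr6c = (sigma / rcut) ** 6
    u_cut = 4.0 * eps * (sr6c * sr6c - sr6c)
    energy = np.where(inside, 4.0 * eps * (sr6 * sr6 - sr6) - u_cut, 0.0)
    force = np.where(inside, 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / np.where(inside, r, 1.0), 0.0)
    if energy.ndim == 0:
        return float(energy), float(force)
    return energy, force


def wca_pair(r, eps: float, sigma: float):
    """Weeks-Chandler-Andersen pair interaction.

    LJ truncated at its minimum ``2^(1/6) sigma`` and shifted up by ``eps``:
    continuous, purely repulsive, zero beyond the cutoff.
    """
    r = np.asarray(r, dtype=float)
    _as_positive("r", r)
    _as_positive("eps", eps)
    _as_positive("sigma", sigma)
    rc = WCA_CUT * sigma
    inside = r < rc
    sr6 = np.where(inside, (sigma / np.where(inside, r, 1.0)) ** 6, 0.0)
    energy = np.where(inside, 4.0 * eps * (sr6 * sr6 - sr6) + eps, 0.0)
    force = np.where(inside, 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / np.where(inside, r, 1.0), 0.0)
    if energy.ndim == 0:
        return float(energy), float(force)
    return energy, force


def fene_bond(r, k: float, R0: float):
    """FENE bond potential ``U(r) = -k R0^2/2 ln(1 - (r/R0)^2)``.

    Diverges at the maximum extension ``R0``; reaching it signals an
    unstable timestep and raises :class:`OverstretchError`.
    """
    r = np.asarray(r, dtype=float)
    _as_positive("r", r)
    _as_positive("k", k)
    _as_positive("R0", R0)
    if np.any(r >= R0):
        worst = float(np.max(r))
        raise OverstretchError(
            f"FENE bond overstretched: r={worst:.6g} >= R0={R0} "
            "(unstable timestep or corrupted configuration)"
        )
    x2 = (r / R0) ** 2
    energy = -0.5 * k * R0 * R0 * np.log1p(-x2)
    force = -k * r / (1.0 - x2)  # -dU/dr, attractive (negative) for r > 0
    if energy.ndim == 0:
        return float(energy), float(force)
    return energy, force


def thermal_map(T: float, tmap: ThermalMap) -> InteractionParams:
    """Interaction parameters at reduced temperature ``T``.

    Linear interpolation of eps_AA (decreasing) and eps_AB (increasing)
    between the configured endpoints; eps_BB and all other parameters are
    temperature-independent.
    """
    if not (tmap.t_min <= T <= tmap.t_max):
        raise ParameterError(
            f"T={T} outside thermal map range [{tmap.t_min}, {tmap.t_max}]"
        )
    x = (T - tmap.t_min) / (tmap.t_max - tmap.t_min)
    eps_AA = tmap.eps_AA_at_tmin + x * (tmap.eps_AA_at_tmax - tmap.eps_AA_at_tmin)
    eps_AB = tmap.eps_AB_at_tmin + x * (tmap.eps_AB_at_tmax - tmap.eps_AB_at_tmin)
    return replace(tmap.base, eps_AA=float(eps_AA), eps_AB=float(eps_AB))
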