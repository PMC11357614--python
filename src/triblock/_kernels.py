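"""Numba-jitted inner loops for pair and bond forces.

These kernels iterate over an explicit pair list (minimum-image convention,
cubic periodic box) and accumulate forces in place.  They are the production
path; the vectorised all-pairs reference in :mod:`triblock.simulate` is the
test oracle.
"""

from __future__ import annotations

import numpy as np
from numba import njit

WCA_CUT2 = 2.0 ** (1.0 / 3.0)  # (2^(1/6))^2


@njit(cache=True)
def nonbonded_kernel(
    pos, pairs_i, pairs_j, types, box,
    eps_AA, eps_AB, eps_BB, sigma, rcut_BB,
    forces,
):
    """Accumulate non-bonded pair forces; return total potential energy.

    B-B pairs: truncated+shifted LJ at ``rcut_BB``; A-A and A-B pairs: WCA.
    ``types`` holds 0 (A) / 1 (B).  Overstretch/instability is not checked
    here; callers validate coordinates.
    """
    energy = 0.0
    half = 0.5 * box
    sig2 = sigma * sigma
    rc2_bb = rcut_BB * rcut_BB
    rc2_wca = WCA_CUT2 * sig2
    src6 = (sig2 / rc2_bb) ** 3
    u_shift_bb = 4.0 * (src6 * src6 - src6)  # in units of eps_BB
    for k in range(pairs_i.shape[0]):
        i = pairs_i[k]
        j = pairs_j[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx >= half:
            dx -= box
        elif dx < -half:
            dx += box
        if dy >= half:
            dy -= box
        elif dy < -half:
            dy += box
        if dz >= half:
            dz -= box
        elif dz < -half:
            dz += box
        r2 = dx * dx + dy * dy + dz * dz
        tsum = types[i] + types[j]
        if tsum == 2:  # B-B: LJ
            if r2 >= rc2_bb:
                continue
            eps = eps_BB
            sr6 = (sig2 / r2) ** 3
            energy += 4.0 * eps * (sr6 * sr6 - sr6) - eps * u_shift_bb
            fr = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2  # F/r
        else:  # A-A or A-B: WCA
            if r2 >= rc2_wca:
                continue
            eps = eps_AA if tsum == 0 else eps_AB
            sr6 = (sig2 / r2) ** 3
            energy += 4.0 * eps * (sr6 * sr6 - sr6) + eps
            fr = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz
    return energy


@njit(cache=True)
def bonded_kernel(pos, bonds_i, bonds_j, box, fene_k, fene_R0, eps_wca, sigma, forces):
    """FENE + WCA on bonded pairs.  Returns (energy, overstretched_index).

    ``overstretched_index`` is -1 when all bonds are within R0, otherwise the
    index of the first offending bond (energy is then meaningless).
    """
    energy = 0.0
    half = 0.5 * box
    sig2 = sigma * sigma
    rc2_wca = WCA_CUT2 * sig2
    R02 = fene_R0 * fene_R0
    for k in range(bonds_i.shape[0]):
        i = bonds_i[k]
        j = bonds_j[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx >= half:
            dx -= box
        elif dx < -half:
            dx += box
        if dy >= half:
            dy -= box
        elif dy < -half:
            dy += box
        if dz >= half:
            dz -= box
        elif dz < -half:
            dz += box
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= R02:
            return 0.0, k
        x2 = r2 / R02
        energy += -0.5 * fene_k * R02 * np.log(1.0 - x2)
        fr = -fene_k / (1.0 - x2)  # F/r (attractive)
        if r2 < rc2_wca and r2 > 0.0:
            sr6 = (sig2 / r2) ** 3
            energy += 4.0 * eps_wca * (sr6 * sr6 - sr6) + eps_wca
            fr += 24.0 * eps_wca * (2.0 * sr6 * sr6 - sr6) / r2
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz
    return energy, -1


@njit(cache=True)
def softcore_kernel(pos, pairs_i, pairs_j, box, amplitude, rc, forces):
    """Soft cosine push-off ``U = A (1 + cos(pi r / rc))`` for r < rc.

    Bounded at r = 0, so overlapping random-walk initial states relax
    without blowing up.  Returns total energy.
    """
    energy = 0.0
    half = 0.5 * box
    for k in range(pairs_i.shape[0]):
        i = pairs_i[k]
        j = pairs_j[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx >= half:
            dx -= box
        elif dx < -half:
            dx += box
        if dy >= half:
            dy -= box
        elif dy < -half:
            dy += box
        if dz >= half:
            dz -= box
        elif dz < -half:
            dz += box
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc * rc or r2 == 0.0:
            continue
        r = np.sqrt(r2)
        energy += amplitude * (1.0 + np.cos(np.pi * r / rc))
        fmag = amplitude * np.pi / rc * np.sin(np.pi * r / rc)  # -dU/dr
        fr = fmag / r
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz
    return energy
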