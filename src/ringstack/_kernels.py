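"""Hot inner loops for the integrator.

A single O(n^2) pass accumulates WCA plus the short-range electrostatic
contribution (Ewald real-space erfc term or Yukawa).  Compiled with numba
when available; a vectorised numpy fallback keeps the package functional
without it.  Energies elsewhere in the package deliberately do not use
these kernels, so force/energy consistency tests exercise two routes.
"""

from __future__ import annotations

import math

import numpy as np

COULOMB_NONE = 0
COULOMB_EWALD_REAL = 1
COULOMB_YUKAWA = 2

_SQRT_PI = math.sqrt(math.pi)
_WCA_CUT2 = 2.0 ** (1.0 / 3.0)  # (2^(1/6))^2


def _nonbonded_forces_py(pos, radii, charges, L, eps, bjerrum,
                         coulomb_mode, alpha, screening, rcut):
    """Numpy fallback: full-matrix evaluation (memory-heavy but correct)."""
    d = pos[:, None, :] - pos[None, :, :]
    d -= L * np.round(d / L)
    r2 = (d * d).sum(axis=-1)
    np.fill_diagonal(r2, np.inf)
    sig = 0.5 * (radii[:, None] + radii[None, :])
    mask = r2 < _WCA_CUT2 * sig * sig
    inv_r2 = np.where(mask, 1.0 / r2, 0.0)
    sr2 = sig * sig * inv_r2
    sr6 = sr2 * sr2 * sr2
    g = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) * inv_r2
    if coulomb_mode != COULOMB_NONE:
        from scipy.special import erfc
        qq = charges[:, None] * charges[None, :]
        r = np.sqrt(r2)
        cmask = r < rcut
        with np.errstate(over="ignore", invalid="ignore"):
            if coulomb_mode == COULOMB_EWALD_REAL:
                ar = alpha * r
                gc = np.where(cmask, bjerrum * qq * (
                    erfc(ar) / r + 2.0 * alpha / _SQRT_PI * np.exp(-ar * ar))
                    / r2, 0.0)
            else:
                gc = np.where(cmask, bjerrum * qq * np.exp(-r / screening)
                              * (1.0 / r + 1.0 / screening) / r2, 0.0)
        g = g + gc
    return (g[:, :, None] * d).sum(axis=1)


def _nonbonded_forces_loop(pos, radii, charges, L, eps, bjerrum,
                           coulomb_mode, alpha, screening, rcut):
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    rcut2 = rcut * rcut
    two_alpha_over_sqrt_pi = 2.0 * alpha / _SQRT_PI
    for i in range(n - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for j in range(i + 1, n):
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            dx -= L * math.floor(dx / L + 0.5)
            dy -= L * math.floor(dy / L + 0.5)
            dz -= L * math.floor(dz / L + 0.5)
            r2 = dx * dx + dy * dy + dz * dz
            g = 0.0
            sig = 0.5 * (radii[i] + radii[j])
            if r2 < _WCA_CUT2 * sig * sig:
                sr2 = sig * sig / r2
                sr6 = sr2 * sr2 * sr2
                g += 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
            if coulomb_mode != COULOMB_NONE and r2 < rcut2:
                qq = charges[i] * charges[j]
                if qq != 0.0:
                    r = math.sqrt(r2)
                    if coulomb_mode == COULOMB_EWALD_REAL:
                        ar = alpha * r
                        g += bjerrum * qq * (
                            math.erfc(ar) / r
                            + two_alpha_over_sqrt_pi * math.exp(-ar * ar)) / r2
                    else:
                        g += bjerrum * qq * math.exp(-r / screening) * (
                            1.0 / r + 1.0 / screening) / r2
            if g != 0.0:
                fx = g * dx
                fy = g * dy
                fz = g * dz
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[i, 2] += fz
                forces[j, 0] -= fx
                forces[j, 1] -= fy
                forces[j, 2] -= fz
    return forces


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    nonbonded_forces = njit(cache=True, fastmath=True)(_nonbonded_forces_loop)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    nonbonded_forces = _nonbonded_forces_py
    HAVE_NUMBA = False
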