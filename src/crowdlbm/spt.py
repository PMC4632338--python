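"""Scaled Particle Theory (SPT) for 2D hard-disk mixtures.

SPT approximates the reversible work of inserting a hard disk of radius ``r``
into a mixture of hard disks, which yields the activity coefficient
``gamma >= 1`` and the insertion probability ``P = 1/gamma`` — the chance
that a molecule trying to enter a voxel finds enough free space.

The mixture enters through the per-voxel moments of the radius distribution

    S_x = (pi / dx**2) * sum_i rho_i * r_i**x,      x = 0, 1, 2

where ``rho_i`` is the molecule count of species ``i`` in the voxel.  ``S_2``
is the area fraction covered by disks; ``S_2 >= 1`` means the voxel is
(over)full and admits no entrant (``P = 0``).

For the square lattice-packing model (non-rotating squares of area ``A`` on a
uniform packing grid) the work term reduces to the free-area fraction alone:
``ln gamma = -ln(1 - S2)`` with ``S2 = (1/dx**2) * sum_i rho_i * A_i``, the
same for every species.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np

__all__ = [
    "moments",
    "ln_gamma_disks",
    "ln_gamma_lattice",
    "probability",
    "lattice_area_fraction",
]

logger = logging.getLogger(__name__)

#: insertion probabilities outside [0, 1] by more than this indicate a bug
_P_DRIFT_TOL = 1e-9


def moments(
    densities: np.ndarray, radii: Sequence[float], dx: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel moments ``(S0, S1, S2)`` of a hard-disk mixture.

    Parameters
    ----------
    densities : array, shape ``(n_species, ...)``
        Molecule counts per voxel for every species present (the inserted
        species' own density is included: self-crowding is physical).
    radii : sequence of float, one per species (nm).
    dx : float
        Voxel side (nm).
    """
    rho = np.asarray(densities, dtype=float)
    r = np.asarray(radii, dtype=float)
    if np.any(r < 0):
        raise ValueError("negative radius")
    if rho.shape[0] != r.shape[0]:
        raise ValueError("need one radius per species")
    pref = math.pi / (dx * dx)
    rx = r[(slice(None),) + (None,) * (rho.ndim - 1)]
    S0 = pref * rho.sum(axis=0)
    S1 = pref * (rho * rx).sum(axis=0)
    S2 = pref * (rho * rx * rx).sum(axis=0)
    return S0, S1, S2


def ln_gamma_disks(S0, S1, S2, r_sp: float) -> np.ndarray:
    """SPT log activity coefficient of a disk of radius ``r_sp`` in a mixture.

    ``ln gamma = -ln(1-S2) + [2 S1/(1-S2)] r + [S0/(1-S2) + S1^2/(1-S2)^2] r^2``

    Voxels with ``S2 >= 1`` diverge and must be masked by the caller (their
    insertion probability is forced to zero); here they evaluate to ``+inf``.
    """
    if r_sp < 0:
        raise ValueError("negative radius")
    S0, S1, S2 = (np.asarray(s, dtype=float) for s in (S0, S1, S2))
    with np.errstate(divide="ignore", invalid="ignore"):
        one_m = 1.0 - S2
        lg = (
            -np.log(one_m)
            + (2.0 * S1 / one_m) * r_sp
            + (S0 / one_m + (S1 / one_m) ** 2) * r_sp**2
        )
    return np.where(S2 >= 1.0, np.inf, lg)


def lattice_area_fraction(
    densities: np.ndarray, areas: Sequence[float], dx: float
) -> np.ndarray:
    """Occupied-area fraction ``S2 = (1/dx**2) * sum_i rho_i * A_i`` per voxel."""
    rho = np.asarray(densities, dtype=float)
    A = np.asarray(areas, dtype=float)
    if np.any(A < 0):
        raise ValueError("negative area")
    ax = A[(slice(None),) + (None,) * (rho.ndim - 1)]
    return (rho * ax).sum(axis=0) / (dx * dx)


def ln_gamma_lattice(
    densities: np.ndarray, areas: Sequence[float], dx: float
) -> np.ndarray:
    """Lattice-packing-model log activity coefficient (species independent).

    ``ln gamma = -ln(1 - S2)``; full voxels (``S2 >= 1``) evaluate to ``+inf``
    so that the insertion probability becomes zero.
    """
    A = np.asarray(areas, dtype=float)
    if np.any(A < 0):
        raise ValueError("negative area")
    S2 = lattice_area_fraction(densities, A, dx)
    with np.errstate(divide="ignore", invalid="ignore"):
        lg = -np.log(1.0 - S2)
    return np.where(S2 >= 1.0, np.inf, lg)


def probability(ln_gamma: np.ndarray) -> np.ndarray:
    """Insertion probability ``P = 1/gamma = exp(-ln gamma)``, clamped to [0, 1].

    Flagged voxels (``ln gamma = +inf``, i.e. ``S2 >= 1``) map to 0.  Values
    outside [0, 1] by more than floating-point drift indicate a bug (SPT gives
    ``gamma >= 1`` analytically) and raise.
    """
    lg = np.asarray(ln_gamma, dtype=float)
    with np.errstate(over="ignore"):
        P = np.exp(-lg)
    low, high = P.min(initial=0.0), P.max(initial=1.0)
    if low < -_P_DRIFT_TOL or high > 1.0 + _P_DRIFT_TOL:
        raise FloatingPointError(
            f"insertion probability outside [0,1] beyond drift: [{low}, {high}]"
        )
    return np.clip(P, 0.0, 1.0)


def activity(ln_gamma: np.ndarray, concentration: np.ndarray) -> np.ndarray:
    """Thermodynamic activity ``a = gamma * C / C_st``.

    The standard concentration is fixed at 1 molecule per voxel, so the
    activity is simply ``gamma * C``; it is derived on demand and never
    enters the engine numerics directly.
    """
    return np.exp(np.asarray(ln_gamma, dtype=float)) * np.asarray(concentration)
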