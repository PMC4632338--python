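"""Classical D2Q5 lattice-Boltzmann diffusion engine: BGK collision + streaming.

For a solute advected by a fluid at rest the equilibrium populations carry no
momentum: ``F_eq[d] = (rho/m) * w_d`` with ``w_0 = 0`` and mover weights 1/4.
A single-relaxation-time (BGK) collision drives the populations toward this
equilibrium at dimensionless rate ``omega``; streaming then shifts each mover
population to its neighbour voxel with periodic wraparound.

At ``omega = 1`` one full collide+stream cycle is algebraically identical to
the finite-difference diffusion stencil at its stability limit: the new
density of every voxel is the average of its four neighbours' densities.
"""

from __future__ import annotations

import warnings

import numpy as np

from .lattice import N_DIR, SHIFTS, WEIGHTS, DistributionField

__all__ = [
    "compute_omega",
    "RelaxationParams",
    "equilibrium",
    "collide",
    "stream",
    "stream_inplace",
]


def compute_omega(D0: float, dt: float, dx: float) -> float:
    """Relaxation parameter for a given dilute diffusion coefficient.

    ``omega = 2 / (1 + 4 * D0 * dt / dx**2)`` (Enskog–Chapman result for the
    D2Q5 stencil).  ``omega = 1`` corresponds to ``dt = dx**2 / (4 * D0)``,
    the finite-difference stability limit, which is also the most accurate
    operating point of the crowding-corrected scheme.
    """
    if dx <= 0 or dt <= 0:
        raise ValueError("dx and dt must be positive")
    if D0 < 0:
        raise ValueError("D0 must be >= 0")
    return 2.0 / (1.0 + 4.0 * D0 * dt / (dx * dx))


class RelaxationParams:
    """Per-species relaxation parameters with range validation.

    By default ``0 < omega <= 1`` is enforced: over-relaxation (``omega > 1``)
    can drive populations negative under BGK, which breaks the crowding
    correction's requirement that insertion probabilities act on non-negative
    populations.  Values up to (but below) 2 can be allowed explicitly, with a
    warning.
    """

    def __init__(self, omega, allow_over_relaxation: bool = False):
        om = np.atleast_1d(np.asarray(omega, dtype=float))
        if np.any(om <= 0):
            raise ValueError("omega must be > 0")
        limit = 2.0 if allow_over_relaxation else 1.0
        if np.any(om > limit) or (allow_over_relaxation and np.any(om >= 2.0)):
            raise ValueError(
                "omega must be <= 1 (or < 2 with allow_over_relaxation=True)"
            )
        if allow_over_relaxation and np.any(om > 1.0):
            warnings.warn(
                "omega > 1: BGK may produce negative populations", stacklevel=2
            )
        self.omega = om

    def __len__(self) -> int:
        return len(self.omega)


def equilibrium(rho: np.ndarray, mass: float = 1.0) -> np.ndarray:
    """Equilibrium populations ``F_eq[d] = (rho/m) * w_d`` for one species.

    Returns an array of shape ``(5,) + rho.shape``; the rest weight is zero so
    ``F_eq[0]`` vanishes, while the direction sum over all d equals ``rho/m``.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("negative density")
    return WEIGHTS[(slice(None),) + (None,) * rho.ndim] * (rho / mass)


def collide(field: DistributionField, omega, allow_over_relaxation: bool = False) -> np.ndarray:
    """BGK collision: ``F_LB = F + omega * (F_eq - F)`` for every species.

    ``omega`` is scalar or one value per species.  Returns the post-collision
    populations ``F_LB`` (same shape as ``field.F``) without modifying the
    input.  Collision conserves the per-voxel direction sum because the
    equilibrium has the same density.
    """
    params = RelaxationParams(omega, allow_over_relaxation)
    om = params.omega
    if len(om) == 1:
        om = np.repeat(om, len(field.species))
    if len(om) != len(field.species):
        raise ValueError("need one omega per species")
    F = field.F
    F_lb = np.empty_like(F)
    for k, sp in enumerate(field.species):
        rho = sp.mass * F[k].sum(axis=0)
        F_eq = equilibrium(rho, sp.mass)
        F_lb[k] = F[k] + om[k] * (F_eq - F[k])
    return F_lb


def stream(F: np.ndarray) -> np.ndarray:
    """Streaming with periodic wrap; returns a new population array.

    ``F`` may be ``(5, n, n)`` (one species) or ``(n_species, 5, n, n)``.
    Mover populations shift by their stencil displacement; the rest
    population is untouched.  A pure permutation of voxel contents, so the
    grid total of every (species, direction) slice is exactly conserved.
    """
    out = np.empty_like(F)
    out[..., 0, :, :] = F[..., 0, :, :]
    for d in range(1, N_DIR):
        di, dj = SHIFTS[d]
        out[..., d, :, :] = np.roll(F[..., d, :, :], shift=(di, dj), axis=(-2, -1))
    return out


def stream_inplace(field: DistributionField) -> None:
    """Stream a :class:`DistributionField` in place."""
    field.F = stream(field.F)
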