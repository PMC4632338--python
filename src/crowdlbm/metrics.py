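"""Comparison metrics: relative distribution error and tracer MSD.

The distribution error between a reference density grid (usually the kMC
ensemble mean) and a test grid (LBM or cLBM) is the Frobenius norm of their
difference divided by the reference's total molecule count, in percent::

    error = 100 * ||rho_ref - rho_test||_F / sum_ij rho_ref(i, j)

An error of 0.93 % for 100 simulated molecules means that the two methods
disagree on the voxel assignment of 0.93 molecules.

A mesoscopic density field has no per-molecule trajectories, so the tracer
MSD is estimated from origin-labelled subpopulations: each initially occupied
tracer voxel is simulated as a distinct species with identical physical
parameters (the nonlinear crowding coupling only sees the summed density, so
the split is exact), and the MSD is the density-weighted mean of squared
voxel-centre distances from each subpopulation's origin, with the
minimum-image convention on the periodic box.  The estimate resolves
displacement at the voxel scale only — molecules rattling inside one voxel
contribute nothing — and is flagged invalid once the spread reaches half the
box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crowding import Simulation, SimulationResult
from .scenarios import Scenario

__all__ = [
    "distribution_error",
    "msd_from_density",
    "msd_error",
    "MSDSeries",
    "label_tracer_origins",
    "simulate_tracer_msd",
]


def distribution_error(rho_ref: np.ndarray, rho_test: np.ndarray) -> float:
    """Relative distribution error in percent.

    Note the asymmetry: the Frobenius norm is symmetric in its arguments but
    the normalisation uses the *reference* total, so swapping the arguments
    changes only the denominator.
    """
    rho_ref = np.asarray(rho_ref, dtype=float)
    rho_test = np.asarray(rho_test, dtype=float)
    if rho_ref.shape != rho_test.shape:
        raise ValueError(f"shape mismatch: {rho_ref.shape} vs {rho_test.shape}")
    total = rho_ref.sum()
    if total <= 0:
        raise ValueError("reference grid has no molecules")
    return 100.0 * float(np.linalg.norm(rho_ref - rho_test)) / float(total)


@dataclass
class MSDSeries:
    """Mean squared displacement vs time, with a per-time validity flag."""

    times: np.ndarray        # ms
    msd: np.ndarray          # nm^2
    species: str
    provenance: str          # "lbm" | "clbm" | "kmc"
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones_like(self.msd, dtype=bool)
        if self.msd[0] != 0.0 and self.times[0] == 0.0:
            raise ValueError("MSD(0) must be 0")
        if np.any(self.msd < 0):
            raise ValueError("MSD must be non-negative")


def _min_image_sq_distances(n: int, dx: float, origins: np.ndarray) -> np.ndarray:
    """Squared voxel-centre distances (nm^2) from each origin to every voxel."""
    idx = np.arange(n)
    d_i = idx[None, :] - origins[:, 0][:, None]
    d_j = idx[None, :] - origins[:, 1][:, None]
    half = n / 2.0
    d_i = (d_i + half) % n - half
    d_j = (d_j + half) % n - half
    return (dx * d_i[:, :, None]) ** 2 + (dx * d_j[:, None, :]) ** 2


def msd_from_density(histories: np.ndarray, origins: np.ndarray, dx: float,
                     times: np.ndarray, species: str = "tracer",
                     provenance: str = "clbm") -> MSDSeries:
    """Tracer MSD from origin-labelled density histories.

    Parameters
    ----------
    histories : array ``(n_times, n_origins, n, n)``
        Density grid of each origin-labelled subpopulation at each time.
    origins : array ``(n_origins, 2)``
        Voxel index of each subpopulation's origin.
    dx : float
        Voxel side, nm.
    times : array of recording times, ms.
    """
    h = np.asarray(histories, dtype=float)
    origins = np.asarray(origins)
    if h.ndim != 4 or h.shape[1] != len(origins):
        raise ValueError("need one labelled density history per origin")
    n = h.shape[-1]
    d2 = _min_image_sq_distances(n, dx, origins)          # (n_origins, n, n)
    num = np.einsum("toij,oij->t", h, d2)
    den = h.sum(axis=(1, 2, 3))
    msd = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    L = n * dx
    valid = np.sqrt(msd) < L / 2.0
    return MSDSeries(times=np.asarray(times, dtype=float), msd=msd,
                     species=species, provenance=provenance, valid=valid)


def msd_error(msd_ref: np.ndarray, msd_test: np.ndarray,
              times: np.ndarray | None = None) -> np.ndarray:
    """Pointwise relative MSD error, percent: ``100 |ref - test| / ref``.

    ``t = 0`` (reference MSD of zero) must be excluded by the caller.
    """
    ref = np.asarray(msd_ref, dtype=float)
    test = np.asarray(msd_test, dtype=float)
    if ref.shape != test.shape:
        raise ValueError("series length mismatch")
    if np.any(ref <= 0):
        raise ValueError("reference MSD must be positive (exclude t = 0)")
    return 100.0 * np.abs(ref - test) / ref


# --------------------------------------------------------------------- #
# origin-labelled engine runs
# --------------------------------------------------------------------- #


def label_tracer_origins(scenario: Scenario, tracer: str = "tracer"):
    """Split a scenario's tracer counts into one subpopulation per origin voxel.

    Returns ``(species, counts, origins, tracer_slice)`` ready for
    :class:`~crowdlbm.crowding.Simulation`: the tracer species is replaced by
    one identical species per initially occupied voxel, all other species kept.
    """
    base_counts = scenario.initial_counts()
    k_tr = scenario.species_index(tracer)
    sp_tr = scenario.species[k_tr]
    origins = np.argwhere(base_counts[k_tr] > 0)
    if not len(origins):
        raise ValueError(f"species {tracer!r} has no molecules to label")
    n = scenario.lattice.n
    species, counts = [], []
    for o, (vi, vj) in enumerate(origins):
        grid = np.zeros((n, n))
        grid[vi, vj] = base_counts[k_tr, vi, vj]
        from dataclasses import replace
        species.append(replace(sp_tr, name=f"{tracer}@{vi},{vj}"))
        counts.append(grid)
    for k, sp in enumerate(scenario.species):
        if k != k_tr:
            species.append(sp)
            counts.append(base_counts[k])
    return species, np.array(counts), origins, slice(0, len(origins))


def simulate_tracer_msd(scenario: Scenario, engine: str = "clbm",
                        tracer: str = "tracer",
                        t_end: float | None = None,
                        record_every: int | None = None,
                        ) -> tuple[MSDSeries, SimulationResult]:
    """Run an engine with origin-labelled tracers and return the tracer MSD."""
    species, counts, origins, tr = label_tracer_origins(scenario, tracer)
    sim = Simulation(scenario, engine=engine, counts=counts, species=species)
    res = sim.run(t_end=t_end, record_every=record_every)
    series = msd_from_density(res.data[:, tr], origins, scenario.lattice.dx,
                              res.times, species=tracer, provenance=engine)
    return series, res
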