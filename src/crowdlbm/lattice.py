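"""Grid geometry, D2Q5 stencil constants, species descriptions and state containers.

The simulation domain is a square, periodic lattice of side ``L`` nanometres
divided into ``n = L/dx`` voxels per side.  Every voxel is assumed internally
well mixed and holds real-valued (mesoscopic) molecule counts.  Positions are
indexed ``(i, j)`` = (row, column), 0-based; ``i`` increases downward and
``j`` increases rightward.

The D2Q5 stencil has five directions ``d = 0..4``: ``d = 0`` is the rest
population and ``d = 1..4`` carry molecules to the four von Neumann
neighbours.  The direction/shift assignment is::

    d = 1 : (i, j) -> (i, j+1)
    d = 2 : (i, j) -> (i-1, j)
    d = 3 : (i, j) -> (i, j-1)
    d = 4 : (i, j) -> (i+1, j)

with weights ``w = (0, 1/4, 1/4, 1/4, 1/4)``.  Boundaries are periodic and
not configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "N_DIR",
    "WEIGHTS",
    "SHIFTS",
    "SpeciesSpec",
    "LatticeConfig",
    "DistributionField",
    "density",
    "voxel_capacity",
]

#: number of stencil directions (rest + 4 neighbours)
N_DIR = 5

#: stencil weights w_d; w_0 = 0 and the four mover weights sum to 1
WEIGHTS = np.array([0.0, 0.25, 0.25, 0.25, 0.25])

#: unit displacement (di, dj) of each direction
SHIFTS = ((0, 0), (0, 1), (-1, 0), (0, -1), (1, 0))

#: opposite direction of each d (0 is self-opposite)
OPPOSITE = (0, 3, 4, 1, 2)


@dataclass(frozen=True)
class SpeciesSpec:
    """Physical description of one molecular species.

    Parameters
    ----------
    name : str
        Species label.
    D0 : float
        Diffusion coefficient in dilute solution, nm^2/ms.
    radius : float
        Hard-disk radius in nm (used by the hard-disk crowding model).
    area : float
        Molecule area in nm^2.  For disks this should equal ``pi * radius**2``;
        for the square lattice-packing model it is the square's area and the
        radius is unused.
    mass : float
        Mass per molecule in g/molecule.  Defaults to 1 so densities equal
        molecule counts.
    mobile : bool
        Immobile species act as fixed crowders: they contribute to the
        excluded area but never move.
    """

    name: str
    D0: float
    radius: float = 0.0
    area: float = 0.0
    mass: float = 1.0
    mobile: bool = True

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError(f"species {self.name!r}: radius must be >= 0")
        if self.area < 0:
            raise ValueError(f"species {self.name!r}: area must be >= 0")
        if self.D0 < 0:
            raise ValueError(f"species {self.name!r}: D0 must be >= 0")
        if self.mass <= 0:
            raise ValueError(f"species {self.name!r}: mass must be > 0")

    @classmethod
    def disk(cls, name: str, D0: float, radius: float, **kw) -> "SpeciesSpec":
        """A hard-disk species; the area is derived from the radius."""
        return cls(name=name, D0=D0, radius=radius, area=math.pi * radius**2, **kw)


@dataclass(frozen=True)
class LatticeConfig:
    """Square periodic lattice geometry and time step.

    Parameters
    ----------
    L : float
        System side length, nm.
    dx : float
        Voxel side, nm.  ``L/dx`` must be an exact integer.
    dt : float
        Time step, ms.
    """

    L: float
    dx: float
    dt: float

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dt <= 0 or self.L <= 0:
            raise ValueError("L, dx and dt must all be positive")
        n = self.L / self.dx
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"L/dx = {n} is not an integer")

    @property
    def n(self) -> int:
        """Voxels per side."""
        return round(self.L / self.dx)


def voxel_capacity(dx: float, area: float) -> int:
    """Maximum number of same-size square molecules that fit in one voxel.

    Assumes square uniform packing, i.e. ``floor(dx**2 / area)``.  Used to
    audit initial conditions of the lattice-packing model.
    """
    if area <= 0:
        raise ValueError("point-like species (area = 0) have no capacity bound")
    return math.floor(dx * dx / area)


@dataclass
class DistributionField:
    """Per-species, per-direction population counts on the voxel grid.

    ``F[s, d, i, j]`` is the (real-valued, non-negative) number of molecules
    of species ``s`` in voxel ``(i, j)`` committed to direction ``d``.  The
    macroscopic density recovers as ``rho_s = m_s * sum_d F[s, d]``.
    """

    config: LatticeConfig
    species: list[SpeciesSpec]
    F: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.config.n
        if self.F is None:
            self.F = np.zeros((len(self.species), N_DIR, n, n))
        expected = (len(self.species), N_DIR, n, n)
        if self.F.shape != expected:
            raise ValueError(f"F has shape {self.F.shape}, expected {expected}")

    def species_index(self, name: str) -> int:
        for k, sp in enumerate(self.species):
            if sp.name == name:
                return k
        raise KeyError(f"unknown species label {name!r}")

    def density(self, name: str) -> np.ndarray:
        """Macroscopic density grid ``rho = m * sum_d F`` for one species."""
        k = self.species_index(name)
        return self.species[k].mass * self.F[k].sum(axis=0)

    def densities(self) -> np.ndarray:
        """Density grids for all species, shape ``(n_species, n, n)``."""
        masses = np.array([sp.mass for sp in self.species])
        return masses[:, None, None] * self.F.sum(axis=1)

    def total_mass(self, name: str) -> float:
        return float(self.density(name).sum())

    @classmethod
    def at_rest(
        cls, config: LatticeConfig, species: list[SpeciesSpec], counts: np.ndarray
    ) -> "DistributionField":
        """Build a field with all molecules in the rest population.

        ``counts[s]`` is the initial molecule-count grid of species ``s``;
        ``F[s, 0] = counts[s] / m_s`` and the mover populations start empty.
        """
        fld = cls(config, list(species))
        for k, sp in enumerate(species):
            if np.any(counts[k] < 0):
                raise ValueError(f"negative initial count for species {sp.name!r}")
            fld.F[k, 0] = counts[k] / sp.mass
        return fld


def density(field: DistributionField, name: str) -> np.ndarray:
    """Functional alias of :meth:`DistributionField.density`."""
    return field.density(name)
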