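"""Ready-made diffusion scenarios and their structured-text configuration.

All scenarios live on a (1000 nm)^2 periodic square lattice with every
molecule's mass set to 1 g, so densities equal molecule counts.  The five
catalogue examples:

1.  Two square species (10 nm side, D = 500 nm^2/ms) on a 10x10 voxel grid
    (dx = 100 nm, dt = 5 ms); the first voxel column is filled to capacity
    (100 molecules per voxel), one voxel holding the 100 tracer A molecules
    and the other nine holding the 900 B molecules.
2.  Three square species A/B/C (D = 1000/1050/1100) on a 20x20 grid
    (dx = 50 nm, dt = 0.625 ms); three adjacent two-column bands are filled
    at 25 molecules per voxel (capacity).
3.  100 square tracer molecules among 0..4000 square crowders (all
    D = 1000), uniformly placed at random — crowder area fractions 0..40 %.
4.  Hard-disk mixture: a tracer of radius 2/1.5/1/0 nm (796 molecules) in a
    4-species crowder background jointly covering 30 % of the lattice.
5.  Hard-disk tracer (r = 1.5 nm, 1414 molecules) among one crowder species
    of radius 2/1.5/1 nm at fixed 30 % covered area (23 873 / 42 441 /
    95 493 molecules).

Scenarios serialise losslessly to YAML; regenerating a scenario with the
same seed reproduces the random placement bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import yaml

from .lattice import LatticeConfig, SpeciesSpec, voxel_capacity

__all__ = [
    "Scenario",
    "example1",
    "example2",
    "example3",
    "example4",
    "example5",
    "EXAMPLE3_CROWDER_COUNTS",
    "EXAMPLE4_TRACER_RADII",
    "EXAMPLE5_CROWDER_COUNTS",
]

EXAMPLE3_CROWDER_COUNTS = (0, 1000, 2000, 3000, 4000)
EXAMPLE4_TRACER_RADII = (2.0, 1.5, 1.0, 0.0)
EXAMPLE5_CROWDER_COUNTS = {2.0: 23873, 1.5: 42441, 1.0: 95493}


@dataclass
class Scenario:
    """A complete simulation configuration.

    ``placements`` maps species name to either
    ``{"kind": "region", "cols": [...], "rows": [...] | None, "per_voxel": int}``
    (every voxel in the column/row intersection gets ``per_voxel`` molecules)
    or ``{"kind": "random", "count": int}`` (uniform random placement, seeded).

    ``mode`` selects the crowding model: ``"lattice"`` (square uniform
    packing, species-independent free-area probability) or ``"disks"``
    (hard-disk SPT with per-species radii).
    """

    name: str
    lattice: LatticeConfig
    species: list[SpeciesSpec]
    placements: dict[str, dict[str, Any]]
    mode: str = "lattice"
    seed: int = 0
    t_end: float = 30.0
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("lattice", "disks"):
            raise ValueError(f"unknown mode {self.mode!r}")
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        for nm in self.placements:
            if nm not in names:
                raise ValueError(f"placement for unknown species {nm!r}")

    # ------------------------------------------------------------------ #
    # placement
    # ------------------------------------------------------------------ #

    def species_index(self, name: str) -> int:
        return [sp.name for sp in self.species].index(name)

    def molecule_side(self) -> float:
        """Side length (nm) of the square molecules in lattice mode."""
        if self.mode != "lattice":
            raise ValueError("molecule_side is defined for lattice mode only")
        areas = {sp.area for sp in self.species if sp.area > 0}
        if len(areas) > 1:
            raise ValueError("lattice mode with mixed molecule sizes")
        return math.sqrt(areas.pop()) if areas else 0.0

    def _region_voxels(self, plc: dict[str, Any]) -> list[tuple[int, int]]:
        n = self.lattice.n
        rows = plc.get("rows")
        rows = range(n) if rows is None else rows
        return [(i, j) for j in plc["cols"] for i in rows]

    def initial_counts(self) -> np.ndarray:
        """Initial per-voxel molecule counts, shape ``(n_species, n, n)``.

        Random placements are drawn with ``default_rng(seed)``; the result is
        identical to coarse-graining :meth:`site_placement` in lattice mode.
        """
        if self.mode == "lattice" and self.molecule_side() > 0:
            positions = self.site_placement()
            n, v = self.lattice.n, round(self.lattice.dx / self.molecule_side())
            counts = np.zeros((len(self.species), n, n))
            for k, pos in enumerate(positions):
                if len(pos):
                    vi, vj = pos[:, 0] // v, pos[:, 1] // v
                    np.add.at(counts[k], (vi, vj), 1.0)
            return counts
        return self._voxel_counts_disks()

    def site_placement(self) -> list[np.ndarray]:
        """Site-level placement for the kMC reference (lattice mode).

        Returns one ``(count, 2)`` integer array of site coordinates per
        species, on the ``L/a`` site lattice (``a`` = molecule side).  Region
        placements fill (or sub-sample) sites voxel by voxel; all random
        placements are drawn jointly, uniformly without replacement over the
        remaining free sites.
        """
        a = self.molecule_side()
        if a <= 0:
            raise ValueError("site placement needs a finite molecule size")
        S = round(self.lattice.L / a)
        v = round(self.lattice.dx / a)
        cap = v * v
        rng = np.random.default_rng(self.seed)
        occupied = np.zeros((S, S), dtype=bool)
        out: list[np.ndarray] = [np.empty((0, 2), dtype=np.int64)] * len(self.species)

        random_names: list[str] = []
        for k, sp in enumerate(self.species):
            plc = self.placements.get(sp.name)
            if plc is None:
                continue
            if plc["kind"] == "random":
                random_names.append(sp.name)
                continue
            per = int(plc["per_voxel"])
            if per > cap:
                raise ValueError(f"{sp.name}: {per} molecules exceed voxel capacity {cap}")
            sites = []
            for (vi, vj) in self._region_voxels(plc):
                ii, jj = np.meshgrid(
                    np.arange(vi * v, (vi + 1) * v),
                    np.arange(vj * v, (vj + 1) * v),
                    indexing="ij",
                )
                cell = np.column_stack([ii.ravel(), jj.ravel()])
                free = cell[~occupied[cell[:, 0], cell[:, 1]]]
                if len(free) < per:
                    raise ValueError(f"{sp.name}: voxel ({vi},{vj}) cannot hold {per}")
                pick = free if per == len(free) else free[
                    rng.choice(len(free), size=per, replace=False)
                ]
                occupied[pick[:, 0], pick[:, 1]] = True
                sites.append(pick)
            out[k] = np.concatenate(sites) if sites else out[k]

        if random_names:
            counts = [int(self.placements[nm]["count"]) for nm in random_names]
            total = sum(counts)
            free_flat = np.flatnonzero(~occupied.ravel())
            if total > len(free_flat):
                raise ValueError("more molecules than free sites")
            chosen = rng.choice(free_flat, size=total, replace=False)
            start = 0
            for nm, cnt in zip(random_names, counts):
                sl = chosen[start : start + cnt]
                start += cnt
                pos = np.column_stack([sl // S, sl % S])
                occupied[pos[:, 0], pos[:, 1]] = True
                out[self.species_index(nm)] = pos
        return out

    def _voxel_counts_disks(self) -> np.ndarray:
        """Voxel-level random placement for disk mode (no site lattice).

        Molecules are assigned to uniformly random voxels; any voxel whose
        covered-area fraction would reach 1 has its excess reassigned (never
        triggered at the catalogue's <= 40 % fractions, kept as a guard).
        """
        n = self.lattice.n
        dx2 = self.lattice.dx**2
        rng = np.random.default_rng(self.seed)
        counts = np.zeros((len(self.species), n, n))
        areas = np.array(
            [sp.area if self.mode == "lattice" else math.pi * sp.radius**2
             for sp in self.species]
        )
        for k, sp in enumerate(self.species):
            plc = self.placements.get(sp.name)
            if plc is None:
                continue
            if plc["kind"] != "random":
                for (vi, vj) in self._region_voxels(plc):
                    counts[k, vi, vj] += plc["per_voxel"]
                continue
            vox = rng.integers(0, n * n, size=int(plc["count"]))
            counts[k] += np.bincount(vox, minlength=n * n).reshape(n, n)
        # guard: push excess out of (over)full voxels
        for _ in range(1000):
            S2 = (counts * areas[:, None, None]).sum(axis=0) / dx2
            over = np.argwhere(S2 >= 1.0)
            if not len(over):
                break
            for vi, vj in over:
                k = int(np.argmax(counts[:, vi, vj] * areas))
                counts[k, vi, vj] -= 1
                free = np.argwhere(S2 < 0.95)
                ti, tj = free[rng.integers(0, len(free))]
                counts[k, ti, tj] += 1
        else:
            raise RuntimeError("could not place molecules below full packing")
        return counts

    # ------------------------------------------------------------------ #
    # audits
    # ------------------------------------------------------------------ #

    def total_area_fraction(self) -> float:
        """Lattice-area fraction covered by all molecules initially."""
        counts = self.initial_counts()
        frac = 0.0
        for k, sp in enumerate(self.species):
            area = sp.area if self.mode == "lattice" else math.pi * sp.radius**2
            frac += counts[k].sum() * area
        return frac / self.lattice.L**2

    def validate(self) -> None:
        """Audit the initial condition against the packing constraints."""
        if self.total_area_fraction() >= 1.0:
            raise ValueError("total occupied area fraction must be < 1")
        counts = self.initial_counts()
        if self.mode == "lattice":
            for k, sp in enumerate(self.species):
                if sp.area > 0:
                    cap = voxel_capacity(self.lattice.dx, sp.area)
                    if counts[k].max() > cap:
                        raise ValueError(f"{sp.name}: voxel count exceeds capacity {cap}")

    # ------------------------------------------------------------------ #
    # serialisation
    # ------------------------------------------------------------------ #

    def to_dict(self) -> dict[str, Any]:
        d = {
            "name": self.name,
            "lattice": {"L_nm": self.lattice.L, "dx_nm": self.lattice.dx,
                        "dt_ms": self.lattice.dt},
            "species": [asdict(sp) for sp in self.species],
            "placements": self.placements,
            "mode": self.mode,
            "run": {"t_end_ms": self.t_end, "record_every_steps": self.record_every,
                    "seed": self.seed},
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Scenario":
        lat = d["lattice"]
        run = d.get("run", {})
        plc = {
            nm: {k: (list(v) if isinstance(v, tuple) else v) for k, v in p.items()}
            for nm, p in d["placements"].items()
        }
        return cls(
            name=d["name"],
            lattice=LatticeConfig(L=lat["L_nm"], dx=lat["dx_nm"], dt=lat["dt_ms"]),
            species=[SpeciesSpec(**sp) for sp in d["species"]],
            placements=plc,
            mode=d.get("mode", "lattice"),
            seed=int(run.get("seed", 0)),
            t_end=float(run.get("t_end_ms", 30.0)),
            record_every=int(run.get("record_every_steps", 1)),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "Scenario":
        if hasattr(source, "read"):
            return cls.from_dict(yaml.safe_load(source))
        try:
            import os
            if os.path.exists(str(source)):
                with open(source) as fh:
                    return cls.from_dict(yaml.safe_load(fh))
        except OSError:
            pass
        return cls.from_dict(yaml.safe_load(source))


# ---------------------------------------------------------------------- #
# catalogue
# ---------------------------------------------------------------------- #


def example1(a_row: int = 5, seed: int = 0, t_end: float = 50.0) -> Scenario:
    """Two square species; first voxel column filled to capacity.

    The tracer voxel row (``a_row``) is configurable; the diffusion profiles
    are translation invariant under the periodic boundaries, so any row gives
    the same physics.  Default: middle row (5 of 0..9).
    """
    lat = LatticeConfig(L=1000.0, dx=100.0, dt=5.0)
    sp = [
        SpeciesSpec("A", D0=500.0, area=100.0, radius=math.sqrt(100.0 / math.pi)),
        SpeciesSpec("B", D0=500.0, area=100.0, radius=math.sqrt(100.0 / math.pi)),
    ]
    rows_b = [r for r in range(lat.n) if r != a_row]
    plc = {
        "A": {"kind": "region", "cols": [0], "rows": [a_row], "per_voxel": 100},
        "B": {"kind": "region", "cols": [0], "rows": rows_b, "per_voxel": 100},
    }
    return Scenario("example1", lat, sp, plc, mode="lattice", seed=seed,
                    t_end=t_end, record_every=1)


def example2(seed: int = 0, t_end: float = 50.0) -> Scenario:
    """Three square species in adjacent two-column bands at capacity.

    The lattice's ten two-column bands are numbered 1..10 left to right;
    bands 3, 4 and 5 (columns 4-5, 6-7, 8-9, 0-based) hold species A, B, C.
    """
    lat = LatticeConfig(L=1000.0, dx=50.0, dt=0.625)
    r = math.sqrt(100.0 / math.pi)
    sp = [
        SpeciesSpec("A", D0=1000.0, area=100.0, radius=r),
        SpeciesSpec("B", D0=1050.0, area=100.0, radius=r),
        SpeciesSpec("C", D0=1100.0, area=100.0, radius=r),
    ]
    plc = {
        "A": {"kind": "region", "cols": [4, 5], "rows": None, "per_voxel": 25},
        "B": {"kind": "region", "cols": [6, 7], "rows": None, "per_voxel": 25},
        "C": {"kind": "region", "cols": [8, 9], "rows": None, "per_voxel": 25},
    }
    return Scenario("example2", lat, sp, plc, mode="lattice", seed=seed,
                    t_end=t_end, record_every=8)


def example3(crowder_count: int, seed: int = 0, t_end: float = 30.0,
             record_every: int = 8) -> Scenario:
    """Square tracer (1 % of lattice area) among 0..40 % square crowders."""
    if crowder_count not in EXAMPLE3_CROWDER_COUNTS:
        raise ValueError(f"crowder_count must be one of {EXAMPLE3_CROWDER_COUNTS}")
    lat = LatticeConfig(L=1000.0, dx=50.0, dt=0.625)
    r = math.sqrt(100.0 / math.pi)
    sp = [SpeciesSpec("tracer", D0=1000.0, area=100.0, radius=r)]
    plc: dict[str, dict[str, Any]] = {"tracer": {"kind": "random", "count": 100}}
    if crowder_count:
        sp.append(SpeciesSpec("crowder", D0=1000.0, area=100.0, radius=r))
        plc["crowder"] = {"kind": "random", "count": int(crowder_count)}
    return Scenario("example3", lat, sp, plc, mode="lattice", seed=seed,
                    t_end=t_end, record_every=record_every)


_EX4_CROWDERS = [
    ("crowder1", 1050.0, 1.9, 6172),
    ("crowder2", 1100.0, 1.8, 9824),
    ("crowder3", 1200.0, 1.6, 6217),
    ("crowder4", 1250.0, 1.5, 11318),
]


def example4(tracer_radius: float, seed: int = 0, t_end: float = 30.0,
             record_every: int = 8) -> Scenario:
    """Hard-disk tracer of selectable radius in a 30 %-covered 4-crowder mix."""
    if tracer_radius not in EXAMPLE4_TRACER_RADII:
        raise ValueError(f"tracer_radius must be one of {EXAMPLE4_TRACER_RADII}")
    lat = LatticeConfig(L=1000.0, dx=50.0, dt=0.625)
    sp = [SpeciesSpec.disk("tracer", D0=1000.0, radius=float(tracer_radius))]
    plc: dict[str, dict[str, Any]] = {"tracer": {"kind": "random", "count": 796}}
    for nm, D0, r, cnt in _EX4_CROWDERS:
        sp.append(SpeciesSpec.disk(nm, D0=D0, radius=r))
        plc[nm] = {"kind": "random", "count": cnt}
    return Scenario("example4", lat, sp, plc, mode="disks", seed=seed,
                    t_end=t_end, record_every=record_every)


def example5(crowder_radius: float, seed: int = 0, t_end: float = 30.0,
             record_every: int = 8) -> Scenario:
    """Hard-disk tracer among one crowder species at fixed 30 % covered area."""
    if crowder_radius not in EXAMPLE5_CROWDER_COUNTS:
        raise ValueError(
            f"crowder_radius must be one of {sorted(EXAMPLE5_CROWDER_COUNTS)}"
        )
    lat = LatticeConfig(L=1000.0, dx=50.0, dt=0.625)
    sp = [
        SpeciesSpec.disk("tracer", D0=1000.0, radius=1.5),
        SpeciesSpec.disk("crowder", D0=1000.0, radius=float(crowder_radius)),
    ]
    plc = {
        "tracer": {"kind": "random", "count": 1414},
        "crowder": {"kind": "random", "count": EXAMPLE5_CROWDER_COUNTS[crowder_radius]},
    }
    return Scenario("example5", lat, sp, plc, mode="disks", seed=seed,
                    t_end=t_end, record_every=record_every)


def example1_omega_variant(omega: float, seed: int = 0, t_end: float = 50.0) -> Scenario:
    """Accuracy-sweep variant of the column-release scenario at ``dx = 50 nm``.

    The time step is set from the requested relaxation parameter,
    ``dt = (2/omega - 1) * dx**2 / (4 D0)`` — the sweep that shows
    ``omega = 1`` to be the most accurate operating point (omega in (0, 1]).
    The first voxel column is filled to capacity (25 per voxel); the 100
    tracer molecules occupy the four middle voxels of the column.
    """
    if not 0.0 < omega <= 1.0:
        raise ValueError("omega must be in (0, 1]")
    D0, dx = 500.0, 50.0
    dt = (2.0 / omega - 1.0) * dx * dx / (4.0 * D0)
    lat = LatticeConfig(L=1000.0, dx=dx, dt=dt)
    r = math.sqrt(100.0 / math.pi)
    sp = [
        SpeciesSpec("A", D0=D0, area=100.0, radius=r),
        SpeciesSpec("B", D0=D0, area=100.0, radius=r),
    ]
    a_rows = [8, 9, 10, 11]
    plc = {
        "A": {"kind": "region", "cols": [0], "rows": a_rows, "per_voxel": 25},
        "B": {"kind": "region", "cols": [0],
              "rows": [i for i in range(lat.n) if i not in a_rows],
              "per_voxel": 25},
    }
    return Scenario("example1_omega", lat, sp, plc, mode="lattice", seed=seed,
                    t_end=t_end, record_every=8)
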