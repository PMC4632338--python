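"""On-lattice kinetic Monte Carlo reference simulator.

Single molecules of side ``a`` (10 nm in the catalogue scenarios) live on an
``L/a`` site lattice with periodic boundaries; each site holds at most one
molecule and a molecule hops only into an empty von Neumann neighbour.  Every
(molecule, free neighbour) pair is an event of rate ``D_sp / a**2`` — the
choice that makes a free walker's MSD equal ``4 D t`` — and the clock
advances by exponential increments ``dt = -ln(u) / R`` where ``R`` is the
cumulative rate.

Two interchangeable samplers are provided:

* a rejection-free reference (:func:`enumerate_events` +
  :func:`select_and_advance`) that re-enumerates the event list at every
  step — the correctness baseline, used on small systems;
* a null-event kernel (numba) for production ensembles: attempts are drawn at
  the constant total rate ``R0 = sum_sp 4 N_sp D_sp / a**2`` and blocked
  attempts advance the clock only.  The compound waiting time to the next
  *accepted* hop is exponential with the exact instantaneous rate, so the two
  samplers generate identical trajectory distributions.

Ensembles are averaged over repetitions of the dynamics from a fixed, seeded
initial placement; occupancies are snapshotted at the recording times using
the state at the last event time <= t_k (previous-state sampling) and coarse
grained to the voxel grid for comparison with the LBM engines.  (The kernel
draws the attempt count of each recording window from the Poisson law of the
constant-rate attempt process — uniformization — which is the same sampler
without per-attempt clock draws.)

Two MSD estimators are recorded per species:

* ``msd`` — exact tagged-particle MSD from unwrapped per-molecule
  displacements.  In a crowded exclusion gas this carries the vacancy
  back-correlation factor (consecutive hops of a tagged molecule are
  anti-correlated because the vacancy it just left is the most likely place
  it returns to).
* ``jump_msd`` — the independent-jump estimator ``a**2 *`` (mean number of
  executed hops), i.e. the displacement accumulated as if successive hops
  were uncorrelated; its slope is ``4 D (1 - phi)`` at site occupancy
  ``phi``.  This is the microscopic quantity comparable with the mesoscopic
  engines, which only resolve effective voxel-to-voxel transits and carry no
  inter-hop memory.  For a free walker the two estimators coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .scenarios import Scenario

__all__ = [
    "KMCState",
    "JammedError",
    "enumerate_events",
    "select_and_advance",
    "run_ensemble",
    "KMCEnsembleResult",
]


class JammedError(RuntimeError):
    """All molecules are fully blocked: the clock advance is undefined."""


# --------------------------------------------------------------------- #
# reference sampler
# --------------------------------------------------------------------- #

#: site-lattice hop displacements, same (i, j) convention as the engines
_HOPS = np.array([(0, 1), (-1, 0), (0, -1), (1, 0)], dtype=np.int64)


@dataclass
class KMCState:
    """Single-molecule occupancy lattice plus per-molecule bookkeeping.

    Molecules are stored contiguously per species: molecule ``m`` belongs to
    species ``s`` iff ``offsets[s] <= m < offsets[s+1]``.  ``disp`` holds
    unwrapped site displacements for MSD computation.
    """

    side: int
    a: float
    occ: np.ndarray          # (side, side) int64, -1 = empty, else molecule id
    pos: np.ndarray          # (N, 2) int64 site coordinates
    offsets: np.ndarray      # (n_species+1,) int64
    hop_rates: np.ndarray    # (n_species,) float64, D_sp / a**2 per direction
    disp: np.ndarray = field(default=None)  # type: ignore[assignment]
    t: float = 0.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def __post_init__(self) -> None:
        if self.disp is None:
            self.disp = np.zeros_like(self.pos)

    @property
    def n_molecules(self) -> int:
        return len(self.pos)

    def species_of(self, m: int) -> int:
        return int(np.searchsorted(self.offsets, m, side="right") - 1)

    @classmethod
    def from_scenario(cls, scenario: Scenario,
                      rng: np.random.Generator | None = None) -> "KMCState":
        """Build the site lattice from a lattice-mode scenario's placement."""
        if scenario.mode != "lattice":
            raise ValueError("the kMC reference supports lattice-mode scenarios only")
        a = scenario.molecule_side()
        if a <= 0:
            raise ValueError("kMC needs finite-size molecules")
        side = round(scenario.lattice.L / a)
        positions = scenario.site_placement()
        counts = [len(p) for p in positions]
        offsets = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        pos = (np.concatenate([p for p in positions if len(p)])
               if offsets[-1] else np.empty((0, 2), dtype=np.int64))
        occ = np.full((side, side), -1, dtype=np.int64)
        occ[pos[:, 0], pos[:, 1]] = np.arange(len(pos))
        rates = np.array([
            (sp.D0 / a**2) if sp.mobile else 0.0 for sp in scenario.species
        ])
        return cls(side=side, a=a, occ=occ, pos=pos.astype(np.int64),
                   offsets=offsets, hop_rates=rates,
                   rng=rng if rng is not None else np.random.default_rng())


def enumerate_events(state: KMCState):
    """List every (molecule, direction) hop into a free site, with rates.

    Returns ``(mols, dirs, rates, R)`` where ``R`` is the cumulative rate.
    """
    mols, dirs, rates = [], [], []
    side = state.side
    for m in range(state.n_molecules):
        r = state.hop_rates[state.species_of(m)]
        if r <= 0:
            continue
        i, j = state.pos[m]
        for d in range(4):
            ni = (i + _HOPS[d, 0]) % side
            nj = (j + _HOPS[d, 1]) % side
            if state.occ[ni, nj] < 0:
                mols.append(m)
                dirs.append(d)
                rates.append(r)
    rates = np.asarray(rates, dtype=float)
    return np.asarray(mols), np.asarray(dirs), rates, float(rates.sum())


def select_and_advance(state: KMCState, events=None) -> float:
    """Execute one event chosen proportionally to its rate; advance the clock.

    Returns the waiting time ``dt = -ln(u)/R`` that was added to the clock.
    Raises :class:`JammedError` when no event is possible.
    """
    if events is None:
        events = enumerate_events(state)
    mols, dirs, rates, R = events
    if R <= 0:
        raise JammedError("no possible events: system is jammed")
    cum = np.cumsum(rates)
    k = int(np.searchsorted(cum, state.rng.random() * R, side="right"))
    m, d = int(mols[k]), int(dirs[k])
    i, j = state.pos[m]
    step = _HOPS[d]
    ni, nj = (i + step[0]) % state.side, (j + step[1]) % state.side
    state.occ[i, j] = -1
    state.occ[ni, nj] = m
    state.pos[m] = (ni, nj)
    state.disp[m] += step
    dt = -math.log(1.0 - state.rng.random()) / R
    state.t += dt
    return dt


# --------------------------------------------------------------------- #
# production kernel (null-event sampling)
# --------------------------------------------------------------------- #


@njit(cache=False)
def _null_event_rep(occ, pos, disp, nhop, offsets, hop_rates, side, vox_sites,
                    record_times, counts_out, msd_out, hops_out, seed):  # pragma: no cover
    np.random.seed(seed)
    n_sp = len(hop_rates)
    n_rec = len(record_times)
    # constant attempt rate: every molecule proposes 4 directions
    cum_w = np.empty(n_sp)
    R0 = 0.0
    for s in range(n_sp):
        R0 += 4.0 * hop_rates[s] * (offsets[s + 1] - offsets[s])
        cum_w[s] = R0
    n_mol = pos.shape[0]
    t_prev = 0.0
    for rec in range(n_rec):
        # uniformization: the attempt process is Poisson at constant rate R0,
        # so the attempt count in each recording window is Poisson(R0 * dt)
        lam = R0 * (record_times[rec] - t_prev)
        t_prev = record_times[rec]
        n_att = np.random.poisson(lam) if lam > 0.0 else 0
        for _ in range(n_att):
            u = np.random.random() * R0
            s = 0
            while u > cum_w[s]:
                s += 1
            n_s = offsets[s + 1] - offsets[s]
            if n_s <= 0:  # float boundary hit on an empty species: null attempt
                continue
            m = offsets[s] + min(int(np.random.random() * n_s), n_s - 1)
            d = min(int(np.random.random() * 4), 3)
            di = 0
            dj = 0
            if d == 0:
                dj = 1
            elif d == 1:
                di = -1
            elif d == 2:
                dj = -1
            else:
                di = 1
            ni = pos[m, 0] + di
            nj = pos[m, 1] + dj
            if ni == side:
                ni = 0
            elif ni == -1:
                ni = side - 1
            if nj == side:
                nj = 0
            elif nj == -1:
                nj = side - 1
            if occ[ni, nj] < 0:
                occ[pos[m, 0], pos[m, 1]] = -1
                occ[ni, nj] = m
                pos[m, 0] = ni
                pos[m, 1] = nj
                disp[m, 0] += di
                disp[m, 1] += dj
                nhop[m] += 1
        for m in range(n_mol):
            s = 0
            while offsets[s + 1] <= m:
                s += 1
            counts_out[rec, s, pos[m, 0] // vox_sites, pos[m, 1] // vox_sites] += 1.0
            msd_out[rec, s] += disp[m, 0] ** 2 + disp[m, 1] ** 2
            hops_out[rec, s] += nhop[m]


@dataclass
class KMCEnsembleResult:
    """Coarse-grained ensemble mean occupancies and tracer MSD.

    ``counts[k, s]`` is the mean molecule count of species ``s`` per voxel at
    ``times[k]``; ``msd[k, s]`` the mean squared displacement (nm^2) averaged
    over the species' molecules and all repetitions.
    """

    times: np.ndarray
    species: list[str]
    counts: np.ndarray
    msd: np.ndarray
    jump_msd: np.ndarray
    n_reps: int
    n_molecules: np.ndarray

    def density(self, name: str, t: float) -> np.ndarray:
        k = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[k] - t) > 1e-9:
            raise KeyError(f"time {t} ms was not recorded")
        return self.counts[k, self.species.index(name)]

    def msd_series(self, names=None, estimator: str = "jump") -> np.ndarray:
        """MSD averaged over the given species, weighted by molecule count.

        ``estimator="jump"`` (default) is the independent-jump estimator used
        for comparison with the mesoscopic engines; ``"tagged"`` is the exact
        unwrapped-displacement MSD.  All species pooled must share identical
        physical parameters for the pooled estimate to be meaningful (e.g.
        tracer and same-size, same-``D`` crowders).
        """
        if names is None:
            names = self.species
        idx = [self.species.index(nm) for nm in names]
        w = self.n_molecules[idx].astype(float)
        src = {"jump": self.jump_msd, "tagged": self.msd}[estimator]
        return (src[:, idx] * w).sum(axis=1) / w.sum()


def run_ensemble(scenario: Scenario, n_reps: int, seed: int,
                 t_end: float | None = None, record_every: int | None = None,
                 method: str = "fast") -> KMCEnsembleResult:
    """Repeat the kMC dynamics ``n_reps`` times and average.

    The initial placement is fixed by ``scenario.seed`` (it matches the LBM
    engines' initial densities exactly); repetition ``r`` uses an independent
    dynamics seed spawned from ``seed``.  ``method="reference"`` uses the
    rejection-free Python sampler (small systems only).
    """
    t_end = scenario.t_end if t_end is None else t_end
    every = scenario.record_every if record_every is None else record_every
    dt = scenario.lattice.dt
    n_steps = int(round(t_end / dt))
    rec_steps = sorted(set(list(range(0, n_steps + 1, every)) + [n_steps]))
    record_times = np.array([k * dt for k in rec_steps])

    proto = KMCState.from_scenario(scenario)
    vox_sites = round(scenario.lattice.dx / proto.a)
    n = scenario.lattice.n
    n_sp = len(scenario.species)
    counts_acc = np.zeros((len(record_times), n_sp, n, n))
    msd_acc = np.zeros((len(record_times), n_sp))
    hops_acc = np.zeros((len(record_times), n_sp))

    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31 - 1)
    for r in range(n_reps):
        occ = proto.occ.copy()
        pos = proto.pos.copy()
        disp = np.zeros_like(pos)
        nhop = np.zeros(len(pos), dtype=np.int64)
        if method == "fast":
            _null_event_rep(occ, pos, disp, nhop, proto.offsets, proto.hop_rates,
                            proto.side, vox_sites, record_times,
                            counts_acc, msd_acc, hops_acc, int(seeds[r]))
        elif method == "reference":
            _reference_rep(proto, occ, pos, disp, nhop, vox_sites, record_times,
                           counts_acc, msd_acc, hops_acc, int(seeds[r]))
        else:
            raise ValueError(f"unknown method {method!r}")

    n_mol = np.diff(proto.offsets)
    counts = counts_acc / n_reps
    norm = proto.a**2 / np.maximum(n_mol, 1)[None, :] / n_reps
    return KMCEnsembleResult(
        times=record_times, species=[sp.name for sp in scenario.species],
        counts=counts, msd=msd_acc * norm, jump_msd=hops_acc * norm,
        n_reps=n_reps, n_molecules=n_mol,
    )


def _reference_rep(proto: KMCState, occ, pos, disp, nhop, vox_sites, record_times,
                   counts_acc, msd_acc, hops_acc, seed: int) -> None:
    """One repetition with the rejection-free sampler (previous-state snapshots)."""
    state = KMCState(side=proto.side, a=proto.a, occ=occ, pos=pos,
                     offsets=proto.offsets, hop_rates=proto.hop_rates,
                     disp=disp, rng=np.random.default_rng(seed))
    rec = 0
    n_rec = len(record_times)
    while rec < n_rec:
        events = enumerate_events(state)
        R = events[3]
        dt = np.inf if R <= 0 else None
        if dt is None:
            # peek the waiting time without committing the move yet
            u_evt = state.rng.random()
            u_dt = state.rng.random()
            dt = -math.log(1.0 - u_dt) / R
        while rec < n_rec and state.t + dt >= record_times[rec]:
            _snapshot(state, nhop, vox_sites, counts_acc, msd_acc, hops_acc, rec)
            rec += 1
        if rec >= n_rec:
            break
        # commit the move using the already-drawn random numbers
        mols, dirs, rates, R = events
        cum = np.cumsum(rates)
        k = int(np.searchsorted(cum, u_evt * R, side="right"))
        m, d = int(mols[k]), int(dirs[k])
        i, j = state.pos[m]
        step = _HOPS[d]
        ni, nj = (i + step[0]) % state.side, (j + step[1]) % state.side
        state.occ[i, j] = -1
        state.occ[ni, nj] = m
        state.pos[m] = (ni, nj)
        state.disp[m] += step
        nhop[m] += 1
        state.t += dt


def _snapshot(state: KMCState, nhop, vox_sites, counts_acc, msd_acc, hops_acc,
              rec: int) -> None:
    n_sp = len(state.hop_rates)
    for s in range(n_sp):
        lo, hi = state.offsets[s], state.offsets[s + 1]
        if hi == lo:
            continue
        p = state.pos[lo:hi]
        np.add.at(counts_acc[rec, s], (p[:, 0] // vox_sites, p[:, 1] // vox_sites), 1.0)
        d = state.disp[lo:hi]
        msd_acc[rec, s] += float((d[:, 0] ** 2 + d[:, 1] ** 2).sum())
        hops_acc[rec, s] += float(nhop[lo:hi].sum())
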