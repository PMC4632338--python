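import numpy as np
import pytest
from scipy import stats

from crowdlbm import kmc
from crowdlbm.lattice import SpeciesSpec
from tests.conftest import make_scenario


def two_species_scenario(seed=5):
    return make_scenario(
        L=100.0, dx=50.0, dt=0.5,
        species=[SpeciesSpec("A", D0=500.0, area=100.0),
                 SpeciesSpec("B", D0=1000.0, area=100.0)],
        placements={"A": {"kind": "random", "count": 8},
                    "B": {"kind": "random", "count": 6}},
        seed=seed)


class TestEventCatalogue:
    def test_free_molecule_has_four_hops(self, single_walker_scenario):
        state = kmc.KMCState.from_scenario(single_walker_scenario)
        mols, dirs, rates, R = kmc.enumerate_events(state)
        assert len(mols) == 4
        assert np.all(rates == 5.0)          # D/a^2 = 500/100
        assert R == 20.0

    def test_fully_blocked_molecule_contributes_nothing(self):
        sc = make_scenario(
            L=100.0, dx=50.0, dt=0.5,
            species=[SpeciesSpec("A", D0=500.0, area=100.0)],
            placements={"A": {"kind": "region", "cols": [0, 1],
                              "rows": None, "per_voxel": 25}})
        state = kmc.KMCState.from_scenario(sc)   # every site occupied
        *_, R = kmc.enumerate_events(state)
        assert R == 0.0
        with pytest.raises(kmc.JammedError):
            kmc.select_and_advance(state)

    def test_occupancy_stays_one_per_site(self, rng):
        sc = two_species_scenario()
        state = kmc.KMCState.from_scenario(sc, rng=rng)
        for _ in range(500):
            kmc.select_and_advance(state)
            ids = state.occ[state.occ >= 0]
            assert len(ids) == len(np.unique(ids)) == state.n_molecules
            assert np.all(state.occ[state.pos[:, 0], state.pos[:, 1]]
                          == np.arange(state.n_molecules))


class TestClockAndSelection:
    def test_waiting_times_are_exponential_mean_one_over_R(self, single_walker_scenario):
        state = kmc.KMCState.from_scenario(
            single_walker_scenario, rng=np.random.default_rng(3))
        R = 20.0
        dts = np.array([kmc.select_and_advance(state) for _ in range(4000)])
        assert dts.mean() == pytest.approx(1.0 / R, rel=0.05)
        assert dts.std() == pytest.approx(1.0 / R, rel=0.08)
        # one-sided KS against the exponential law
        assert stats.kstest(dts, "expon", args=(0, 1.0 / R)).pvalue > 0.01

    def test_equal_rate_events_chosen_uniformly(self, single_walker_scenario):
        state = kmc.KMCState.from_scenario(
            single_walker_scenario, rng=np.random.default_rng(4))
        picks = np.zeros(4)
        for _ in range(2000):
            before = state.pos[0].copy()
            kmc.select_and_advance(state)
            step = state.pos[0] - before
            step = (step + state.side // 2) % state.side - state.side // 2
            d = [(0, 1), (-1, 0), (0, -1), (1, 0)].index(tuple(step))
            picks[d] += 1
        assert stats.chisquare(picks).pvalue > 0.01


class TestEnsemble:
    def test_free_walker_msd_slope_4D(self, single_walker_scenario):
        ens = kmc.run_ensemble(single_walker_scenario, n_reps=600, seed=9,
                               t_end=40.0, record_every=8)
        t = ens.times[1:]
        for estimator in ("tagged", "jump"):
            msd = ens.msd_series(["w"], estimator=estimator)[1:]
            slope = np.polyfit(t, msd, 1)[0]
            assert slope == pytest.approx(4.0 * 500.0, rel=0.08)

    def test_single_molecule_visits_sites_uniformly(self):
        sc = make_scenario(L=50.0, dx=10.0, dt=1.0,
                           species=[SpeciesSpec("w", D0=500.0, area=100.0)],
                           placements={"w": {"kind": "random", "count": 1}},
                           seed=1)
        # dx = a: voxels are sites, so occupancy snapshots are site counts
        ens = kmc.run_ensemble(sc, n_reps=40, seed=12, t_end=100.0,
                               record_every=1)
        counts = ens.counts[1:, 0].sum(axis=0) * ens.n_reps
        assert stats.chisquare(counts.ravel()).pvalue > 0.01

    def test_null_event_kernel_matches_reference_sampler(self):
        """A/B: the production kernel and the rejection-free enumeration
        sampler must agree in distribution (same scenario, disjoint seeds)."""
        sc = two_species_scenario()
        ens_fast = kmc.run_ensemble(sc, n_reps=120, seed=21, t_end=1.5,
                                    record_every=3, method="fast")
        ens_ref = kmc.run_ensemble(sc, n_reps=120, seed=22, t_end=1.5,
                                   record_every=3, method="reference")
        # per-voxel mean occupancies agree within Monte-Carlo noise
        for s, n_mol in enumerate(ens_fast.n_molecules):
            a = ens_fast.counts[-1, s].ravel()
            b = ens_ref.counts[-1, s].ravel()
            sd = np.sqrt(n_mol) / np.sqrt(120)   # generous binomial bound
            assert np.all(np.abs(a - b) < 4 * sd)
        # and so do the MSD estimators
        assert np.allclose(ens_fast.msd[-1], ens_ref.msd[-1],
                           rtol=0.35, atol=20.0)

    def test_ensemble_mean_is_seed_stable(self):
        sc = two_species_scenario()
        e1 = kmc.run_ensemble(sc, n_reps=100, seed=31, t_end=1.0, record_every=2)
        e2 = kmc.run_ensemble(sc, n_reps=100, seed=32, t_end=1.0, record_every=2)
        sd = np.sqrt(ens_total := e1.n_molecules.sum()) / np.sqrt(100)
        assert np.all(np.abs(e1.counts[-1] - e2.counts[-1]) < 4 * sd)

    def test_dilute_kmc_converges_to_lbm_density(self):
        """Both methods solve the same diffusion equation in the dilute limit."""
        from crowdlbm.crowding import Simulation
        from crowdlbm.metrics import distribution_error

        sc = make_scenario(
            L=500.0, dx=50.0, dt=1.25,
            species=[SpeciesSpec("A", D0=500.0, area=100.0)],
            placements={"A": {"kind": "region", "cols": [5], "rows": None,
                              "per_voxel": 2}},
            seed=2)
        ens = kmc.run_ensemble(sc, n_reps=600, seed=41, t_end=10.0,
                               record_every=8)
        res = Simulation(sc, engine="lbm").run(t_end=10.0, record_every=8)
        err = distribution_error(ens.density("A", 10.0), res.density("A", 10.0))
        assert err < 8.0     # sampling error of 600 reps dominates

    def test_placement_infeasible_raises(self):
        sc = make_scenario(
            L=100.0, dx=50.0, dt=0.5,
            species=[SpeciesSpec("A", D0=500.0, area=100.0)],
            placements={"A": {"kind": "random", "count": 101}})
        with pytest.raises(ValueError):
            kmc.KMCState.from_scenario(sc)
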