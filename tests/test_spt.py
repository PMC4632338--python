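import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crowdlbm import spt


class TestMoments:
    def test_empty_voxel(self):
        S0, S1, S2 = spt.moments(np.zeros((1, 2, 2)), [2.0], 50.0)
        assert not S0.any() and not S1.any() and not S2.any()

    def test_thirty_percent_area_fraction(self):
        # uniform crowder density of catalogue example 5 (r = 2 nm)
        rho = np.full((1, 1, 1), 23873.0 / 400.0)
        _, _, S2 = spt.moments(rho, [2.0], 50.0)
        assert S2[0, 0] == pytest.approx(0.30, abs=1e-4)

    def test_point_species_only_counts(self):
        S0, S1, S2 = spt.moments(np.full((1, 1, 1), 7.0), [0.0], 50.0)
        assert S0[0, 0] > 0 and S1[0, 0] == 0 and S2[0, 0] == 0

    def test_radius_per_species_required(self):
        with pytest.raises(ValueError):
            spt.moments(np.zeros((2, 1, 1)), [1.0], 50.0)


class TestLnGamma:
    def test_point_tracer_sees_free_area(self):
        # r = 0: ln gamma = -ln(1 - S2), so P = 1 - S2
        S = (np.full((1, 1), 0.1), np.full((1, 1), 0.2), np.full((1, 1), 0.3))
        lg = spt.ln_gamma_disks(*S, 0.0)
        assert lg[0, 0] == pytest.approx(-math.log(0.7), rel=1e-12)
        assert spt.probability(lg)[0, 0] == pytest.approx(0.7, rel=1e-12)

    def test_uncrowded_gives_unity(self):
        z = np.zeros((2, 2))
        lg = spt.ln_gamma_disks(z, z, z, 1.5)
        assert np.all(lg == 0.0)
        assert np.all(spt.probability(lg) == 1.0)

    def test_disk_mixture_oracle_value(self):
        # independent term-by-term evaluation of the insertion work
        S0, S1, S2, r = 0.075, 0.15, 0.30, 1.5
        expected = (-math.log(1 - S2) + 2 * S1 / (1 - S2) * r
                    + (S0 / (1 - S2) + S1**2 / (1 - S2) ** 2) * r**2)
        assert expected == pytest.approx(1.3439, abs=2e-4)
        lg = spt.ln_gamma_disks(*(np.full((1, 1), s) for s in (S0, S1, S2)), r)
        assert lg[0, 0] == pytest.approx(expected, rel=1e-12)
        assert spt.probability(lg)[0, 0] == pytest.approx(0.2608, abs=2e-4)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            spt.ln_gamma_disks(np.zeros(1), np.zeros(1), np.zeros(1), -1.0)


class TestLatticeModel:
    def test_full_voxel_blocks_entry(self):
        rho = np.full((1, 1, 1), 25.0)  # 25 squares of 100 nm^2 in (50 nm)^2
        lg = spt.ln_gamma_lattice(rho, [100.0], 50.0)
        assert np.isinf(lg[0, 0])
        assert spt.probability(lg)[0, 0] == 0.0

    def test_half_full_voxel(self):
        rho = np.full((1, 1, 1), 12.5)
        P = spt.probability(spt.ln_gamma_lattice(rho, [100.0], 50.0))
        assert P[0, 0] == pytest.approx(0.5, rel=1e-12)

    def test_empty_voxel(self):
        P = spt.probability(spt.ln_gamma_lattice(np.zeros((1, 1, 1)), [100.0], 50.0))
        assert np.all(P == 1.0)

    def test_matches_disk_model_for_point_tracer(self):
        rho = np.array([[[3.0, 7.0], [0.0, 12.0]]])
        area = 100.0
        P_lat = spt.probability(spt.ln_gamma_lattice(rho, [area], 50.0))
        # a disk mixture with the same S2 seen by a point tracer
        r_eq = math.sqrt(area / math.pi)
        S0, S1, S2 = spt.moments(rho, [r_eq], 50.0)
        P_disk = spt.probability(spt.ln_gamma_disks(S0, S1, S2, 0.0))
        assert np.allclose(P_lat, P_disk, rtol=1e-12)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    S0=st.floats(0.0, 0.3), S1=st.floats(0.0, 0.4), S2=st.floats(0.0, 0.9),
    r=st.floats(0.0, 3.0),
    dS=st.floats(1e-6, 0.05), dr=st.floats(1e-6, 0.5),
)
def test_insertion_probability_monotonicity(S0, S1, S2, r, dS, dr):
    """P never increases when any moment or the tracer radius grows."""
    def P(s0, s1, s2, rr):
        arr = spt.ln_gamma_disks(np.array([s0]), np.array([s1]),
                                 np.array([min(s2, 0.999)]), rr)
        return spt.probability(arr)[0]

    base = P(S0, S1, S2, r)
    assert P(S0 + dS, S1, S2, r) <= base + 1e-12
    assert P(S0, S1 + dS, S2, r) <= base + 1e-12
    assert P(S0, S1, S2 + dS, r) <= base + 1e-12
    assert P(S0, S1, S2, r + dr) <= base + 1e-12


class TestInsertionOracle:
    def test_against_hard_disk_monte_carlo(self):
        """SPT insertion probability vs brute-force trial insertion.

        An equilibrated periodic hard-disk fluid at 15 % area fraction is
        sampled with Metropolis displacement moves; P is estimated as the
        acceptance fraction of random tracer insertions.  SPT is accurate at
        low-to-moderate coverage: agreement within 5 % relative is expected.
        (Characterisation of SPT accuracy, not of the engine.)
        """
        rng = np.random.default_rng(7)
        r_c, r_t, n_disks, phi = 1.0, 1.0, 30, 0.15
        box = math.sqrt(n_disks * math.pi * r_c**2 / phi)

        def overlaps(pts, p, skip=-1):
            d = np.abs(pts - p)
            d = np.minimum(d, box - d)
            dist2 = (d**2).sum(axis=1)
            if skip >= 0:
                dist2[skip] = np.inf
            return np.any(dist2 < (2 * r_c) ** 2)

        # random sequential start, then Metropolis equilibration
        pts = []
        while len(pts) < n_disks:
            p = rng.random(2) * box
            if not pts or not overlaps(np.array(pts), p):
                pts.append(p)
        pts = np.array(pts)
        for _ in range(400 * n_disks):
            k = rng.integers(n_disks)
            trial = (pts[k] + rng.uniform(-1.0, 1.0, 2)) % box
            if not overlaps(pts, trial, skip=k):
                pts[k] = trial

        trials = rng.random((40_000, 2)) * box
        hits = 0
        rr = (r_c + r_t) ** 2
        for p in trials:
            d = np.abs(pts - p)
            d = np.minimum(d, box - d)
            if np.all((d**2).sum(axis=1) >= rr):
                hits += 1
        P_mc = hits / len(trials)

        S0, S1, S2 = spt.moments(np.full((1, 1, 1), float(n_disks)), [r_c], box)
        P_spt = spt.probability(spt.ln_gamma_disks(S0, S1, S2, r_t))[0, 0]
        assert P_mc == pytest.approx(P_spt, rel=0.05)
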