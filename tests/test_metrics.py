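"""Clustering, backbone extraction, profiles, periodograms, similarity."""

import numpy as np
import pytest

import colribbon as cb
from colribbon import metrics
from colribbon.forces import Box
from colribbon.metrics import (MassProfile, NotElongatedError, dominant_period,
                               mass_profile, periodogram, profile_similarity,
                               similarity_null)


def brute_union_find_labels(state, cutoff):
    """Pure-Python union-find over all rod pairs (oracle)."""
    rods = list(np.unique(state.rod_index))
    parent = {r: r for r in rods}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        parent[find(a)] = find(b)

    p = state.positions
    for ri in rods:
        for rj in rods:
            if rj <= ri:
                continue
            pi = p[state.rod_index == ri]
            pj = p[state.rod_index == rj]
            d = pi[:, None, :] - pj[None, :, :]
            d[..., 0] -= state.box.lx * np.round(d[..., 0] / state.box.lx)
            d[..., 1] -= state.box.ly * np.round(d[..., 1] / state.box.ly)
            if np.sqrt((d ** 2).sum(-1)).min() < cutoff:
                union(ri, rj)
    return {r: find(r) for r in rods}


def cosine_profile(period, n_bins, bin_width=1.0, amp=1.0, phase=0.0):
    x = (np.arange(n_bins) + 0.5) * bin_width
    return MassProfile(bin_centers=x,
                       mass=amp * np.cos(2 * np.pi * x / period + phase) + 2 * amp,
                       bin_width=bin_width)


class TestClustering:
    def test_isolated_rods_are_singletons(self, small_rod):
        st = cb.build_ribbon_state(1, 1, 3.0, small_rod,
                                   box=Box(300, 300, 5))
        rods = []
        for k in range(4):
            s = cb.build_ribbon_state(1, 1, 3.0, small_rod,
                                      box=Box(300, 300, 5))
            s.positions[:, 1] += 40.0 * k
            rods.append(s)
        merged = cb.SystemState(
            np.vstack([s.positions for s in rods]),
            np.concatenate([s.rod_index + k for k, s in enumerate(rods)]),
            np.concatenate([s.charges for s in rods]), st.box, st.template)
        cs = cb.find_clusters(merged)
        assert cs.n_clusters == 4

    def test_built_fibril_is_one_cluster(self, small_rod):
        st = cb.build_ribbon_state(1, 5, 3.0, small_rod)
        cs = cb.find_clusters(st, 1.2 * small_rod.bead_diameter)
        assert cs.n_clusters == 1
        assert cs.masses.sum() == st.n_beads

    def test_random_rods_match_union_find_oracle(self, rng):
        rod = cb.ChargedRod(n_beads=4, bead_spacing=1.0, bead_diameter=1.0)
        box = Box(40.0, 40.0, 8.0)
        n_rods = 20
        positions, rid = [], []
        for r in range(n_rods):
            start = rng.uniform([0, 0, 1], [36, 36, 5])
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            positions.append(start + np.arange(4)[:, None] * direction)
            rid.append(np.full(4, r))
        st = cb.SystemState(np.vstack(positions), np.concatenate(rid),
                            np.zeros(4 * n_rods), box, rod)
        cutoff = 2.0
        cs = cb.find_clusters(st, cutoff)
        oracle = brute_union_find_labels(st, cutoff)
        rods = np.unique(st.rod_index)
        for a in range(n_rods):
            for b in range(a + 1, n_rods):
                same_oracle = oracle[rods[a]] == oracle[rods[b]]
                same_fast = cs.labels[a] == cs.labels[b]
                assert same_oracle == same_fast

    def test_labels_invariant_under_rigid_translation(self, small_rod):
        st = cb.build_ribbon_state(2, 4, 3.0, small_rod)
        cs0 = cb.find_clusters(st)
        moved = st.copy()
        moved.positions[:, 0] = (moved.positions[:, 0] + 13.7) % st.box.lx
        moved.positions[:, 1] = (moved.positions[:, 1] + 5.1) % st.box.ly
        cs1 = cb.find_clusters(moved)
        assert np.array_equal(np.sort(cs0.masses), np.sort(cs1.masses))


class TestBackbone:
    def test_straight_line_recovered(self):
        t = np.linspace(0, 30, 40)
        beads = np.column_stack([t, np.full_like(t, 2.0), np.full_like(t, 1.0)])
        curve = cb.backbone_spline(beads)
        assert curve.arclength == pytest.approx(30.0, rel=1e-6)

    def test_quarter_circle_arclength(self):
        R = 40.0
        theta = np.linspace(0, np.pi / 2, 200)
        beads = np.column_stack([R * np.cos(theta), R * np.sin(theta),
                                 np.ones_like(theta)])
        curve = cb.backbone_spline(beads, smoothing=1e-6)
        assert curve.arclength == pytest.approx(np.pi * R / 2, rel=0.02)

    def test_built_ribbon_arclength_near_nominal(self, small_rod):
        st = cb.build_ribbon_state(1, 10, 3.5, small_rod)
        nominal = 9 * 3.5 + small_rod.length
        curve = cb.backbone_spline(st.positions)
        assert curve.arclength == pytest.approx(nominal, rel=0.05)

    def test_isotropic_cloud_rejected(self, rng):
        beads = rng.normal(size=(100, 3))
        with pytest.raises(NotElongatedError, match="principal axis"):
            cb.backbone_spline(beads)
        curve = cb.principal_axis_curve(beads)  # fallback works
        assert curve.arclength > 0


class TestMassProfile:
    def test_uniform_rod_flat_interior(self):
        t = np.arange(0, 60, 1.0)
        beads = np.column_stack([t, np.zeros_like(t), np.ones_like(t)])
        curve = cb.principal_axis_curve(beads)
        prof = mass_profile(beads, curve, bin_width=5.0)
        interior = prof.mass[1:-1]
        assert np.all(interior == interior[0])

    def test_mass_conserved(self, small_rod, rng):
        st = cb.build_ribbon_state(1, 7, 3.0, small_rod)
        beads = st.positions + rng.normal(0, 0.1, st.positions.shape)
        curve = cb.backbone_spline(beads)
        prof = mass_profile(beads, curve, bin_width=2.0)
        assert prof.mass.sum() == len(beads)

    def test_staggered_toy_overlap_gap_pattern(self):
        """Hand-enumerated 20-bead toy: two 10-bead rods, the second offset
        by 5 spacings, gives occupancy 1/2/1 along the axis."""
        xs1 = np.arange(10) * 1.0
        xs2 = xs1 + 5.0
        beads = np.vstack([
            np.column_stack([xs1, np.zeros(10), np.ones(10)]),
            np.column_stack([xs2, np.full(10, 0.5), np.ones(10)])])
        axis_x = np.linspace(0.0, 15.0, 301)
        curve = metrics.BackboneCurve(
            control_points=np.column_stack([
                axis_x, np.full_like(axis_x, 0.25), np.ones_like(axis_x)]),
            arclength=15.0)
        prof = mass_profile(beads, curve, bin_width=1.0)
        # hand enumeration: positions 0-4 have 1 bead, 5-9 have 2, 10-14 have 1
        expected = np.array([1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 1, 1, 1, 1, 1])
        assert prof.mass.sum() == 20
        assert np.array_equal(prof.mass[:15], expected)


class TestPeriodogram:
    def test_pure_cosine_peak_within_one_bin(self):
        prof = cosine_profile(period=20.0, n_bins=400)
        pg = periodogram(prof)
        peak_f = pg.spatial_frequencies[np.argmax(pg.power[1:]) + 1]
        df = pg.spatial_frequencies[1]
        assert abs(peak_f - 1 / 20.0) <= df

    def test_constant_profile_no_ac_power(self):
        prof = MassProfile(np.arange(64) + 0.5, np.full(64, 3.0), 1.0)
        pg = periodogram(prof)
        assert np.all(pg.power == 0.0)

    def test_white_noise_parseval(self, rng):
        x = rng.normal(size=512)
        prof = MassProfile(np.arange(512) + 0.5, x, 1.0)
        pg = periodogram(prof)
        xd = x - x.mean()
        assert pg.power.sum() == pytest.approx((xd ** 2).sum(), abs=1e-9)

    def test_too_few_bins_rejected(self):
        prof = MassProfile(np.arange(4) + 0.5, np.arange(4.0), 1.0)
        with pytest.raises(ValueError):
            periodogram(prof)


class TestDominantPeriod:
    def test_cosine_period_50(self):
        prof = cosine_profile(period=50.0, n_bins=1000)
        pg = periodogram(prof)
        assert dominant_period(pg, (30, 150)) == pytest.approx(50.0, abs=0.5)

    def test_stronger_of_two_cosines_wins(self):
        x = (np.arange(900) + 0.5)
        mass = 3.0 * np.cos(2 * np.pi * x / 60.0) + 1.0 * np.cos(2 * np.pi * x / 45.0)
        prof = MassProfile(x, mass, 1.0)
        pg = periodogram(prof)
        assert dominant_period(pg, (30, 150)) == pytest.approx(60.0, abs=1.0)

    def test_builder_dband_parameter_recovery(self):
        """build -> backbone -> profile -> FFT recovers planted staggers."""
        for D in (50.0, 67.0, 80.0):
            n_beads = int(round(4.48 * D / 2.0)) + 1
            rod = cb.ChargedRod(n_beads=n_beads, bead_spacing=2.0,
                                bead_diameter=1.5)
            st = cb.build_ribbon_state(1, 40, D, rod)
            curve = cb.backbone_spline(st.positions)
            prof = mass_profile(st.positions, curve, bin_width=2.0)
            pg = periodogram(prof)
            est = dominant_period(pg, (30, 150))
            one_bin = est ** 2 / (len(prof.mass) * prof.bin_width)
            assert abs(est - D) <= one_bin

    def test_empty_band_rejected(self):
        prof = cosine_profile(period=20.0, n_bins=128)
        pg = periodogram(prof)
        with pytest.raises(ValueError, match="band"):
            dominant_period(pg, (0.1, 0.2))


class TestSimilarity:
    def test_identical_profiles_score_one(self, rng):
        x = rng.normal(size=128)
        p = MassProfile(np.arange(128) + 0.5, x, 1.0)
        assert profile_similarity(p, p) == pytest.approx(1.0, abs=1e-9)

    def test_circular_shift_invariance(self, rng):
        x = rng.normal(size=128)
        p1 = MassProfile(np.arange(128) + 0.5, x, 1.0)
        p2 = MassProfile(np.arange(128) + 0.5, np.roll(x, 37), 1.0)
        assert profile_similarity(p1, p2) == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_and_bounded(self, rng):
        a = MassProfile(np.arange(100) + 0.5, rng.normal(size=100), 1.0)
        b = MassProfile(np.arange(100) + 0.5, rng.normal(size=100), 1.0)
        sab = profile_similarity(a, b)
        assert sab == pytest.approx(profile_similarity(b, a), abs=1e-12)
        assert sab <= 1.0 + 1e-12

    def test_constant_profile_rejected(self):
        p1 = MassProfile(np.arange(16) + 0.5, np.ones(16), 1.0)
        p2 = MassProfile(np.arange(16) + 0.5, np.arange(16.0), 1.0)
        with pytest.raises(ValueError, match="constant"):
            profile_similarity(p1, p2)

    def test_white_noise_null_distribution(self, rng):
        """Independent white-noise profiles score like their own permutation
        null: the observed score should not be an outlier of the null."""
        a = MassProfile(np.arange(256) + 0.5, rng.normal(size=256), 1.0)
        b = MassProfile(np.arange(256) + 0.5, rng.normal(size=256), 1.0)
        obs, null, p = similarity_null(a, b, n_perm=1000, rng=rng)
        # permuting white noise preserves its distribution: obs is a typical
        # draw, so the p-value must not be extreme
        assert 0.001 < p
        assert null.min() < obs < null.max() or p > 0.5

    def test_mismatched_bin_width_rejected(self):
        p1 = MassProfile(np.arange(16) + 0.5, np.random.rand(16), 1.0)
        p2 = MassProfile((np.arange(16) + 0.5) * 2, np.random.rand(16), 2.0)
        with pytest.raises(ValueError):
            profile_similarity(p1, p2)
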