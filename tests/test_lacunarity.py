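"""Gliding-box lacunarity: oracle equivalence, analytic identities, curve
endpoints and randomness-scale detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lacunatex as lx
from lacunatex.lacunarity import LacunarityUndefinedError


def all_pore(dims):
    return lx.BinaryVolume(np.ones(dims, dtype=np.uint8))


class TestBoxOccupancyDistribution:
    def test_r_equal_min_dim_is_point_mass_at_total_pore_count(self, foam16):
        dist = lx.box_occupancy_distribution(foam16, 16)
        assert dist.total_boxes == 1
        assert dist.counts == {foam16.porosity().pore_voxels: 1}

    def test_r1_recovers_porosity(self, foam16):
        dist = lx.box_occupancy_distribution(foam16, 1)
        n = foam16.porosity()
        assert dist.total_boxes == n.total_voxels
        assert dist.probabilities[1] == pytest.approx(n.n, abs=0)
        assert dist.probabilities[0] == pytest.approx(1 - n.n, abs=1e-15)

    def test_matches_exhaustive_enumeration_4cubed_r2(self):
        vol = lx.bernoulli_volume((4, 4, 4), 0.5, seed=11)
        dist = lx.box_occupancy_distribution(vol, 2)
        # independent enumeration of all 27 box positions
        counts = {}
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    s = int(vol.voxels[i : i + 2, j : j + 2, k : k + 2].sum())
                    counts[s] = counts.get(s, 0) + 1
        assert dist.total_boxes == 27
        assert dist.counts == counts

    def test_probabilities_sum_to_one_and_moment_ratio_is_lac(self, foam16):
        for r in (1, 2, 3, 5):
            dist = lx.box_occupancy_distribution(foam16, r)
            assert sum(dist.probabilities.values()) == pytest.approx(1.0, abs=1e-12)
            mu1, mu2 = dist.moments()
            assert mu2 / mu1**2 == pytest.approx(
                lx.gliding_box_lacunarity(foam16, r), rel=1e-9
            )

    def test_rejects_oversized_box(self, foam16):
        with pytest.raises(ValueError):
            lx.box_occupancy_distribution(foam16, 17)


class TestGlidingBoxLacunarity:
    def test_all_pore_is_one_at_every_r(self):
        vol = all_pore((6, 6, 6))
        for r in (1, 2, 3, 6):
            assert lx.gliding_box_lacunarity(vol, r) == 1.0

    def test_r1_equals_inverse_porosity(self, bernoulli32, foam16):
        for vol in (bernoulli32, foam16):
            n = vol.porosity().n
            assert lx.gliding_box_lacunarity(vol, 1) == pytest.approx(1 / n, abs=1e-12)

    def test_empty_pore_phase_is_singular(self):
        solid = lx.BinaryVolume(np.zeros((4, 4, 4), dtype=np.uint8))
        with pytest.raises(LacunarityUndefinedError):
            lx.gliding_box_lacunarity(solid, 2)

    def test_regular_lattice_unity_at_period_multiples(self):
        vol = lx.regular_lattice((12, 12, 12), period=3, pores_per_period=4)
        for r in (3, 6, 9, 12):
            assert lx.gliding_box_lacunarity(vol, r) == pytest.approx(1.0, abs=1e-12)

    def test_number_of_boxes_follows_product_formula(self):
        vol = lx.bernoulli_volume((5, 6, 7), 0.5, seed=2)
        for r in (1, 2, 4):
            dist = lx.box_occupancy_distribution(vol, r)
            assert dist.total_boxes == (5 - r + 1) * (6 - r + 1) * (7 - r + 1)

    def test_scale_ordering_fewer_larger_pores_higher_lac(self):
        """At matched porosity, a coarse-pored foam is gappier at small box
        sizes than a fine-pored one."""
        coarse = lx.foam_volume(
            lx.SyntheticSpec((48, 48, 48), 0.7, "foam", pore_radius_mean=6.0,
                             pore_radius_sd=0.5, seed=3)
        )
        fine = lx.foam_volume(
            lx.SyntheticSpec((48, 48, 48), 0.7, "foam", pore_radius_mean=2.0,
                             pore_radius_sd=0.3, seed=3)
        )
        for r in (2, 3, 4):
            assert lx.gliding_box_lacunarity(coarse, r) > lx.gliding_box_lacunarity(fine, r)


class TestBruteForceOracle:
    @pytest.mark.parametrize("p", [0.2, 0.5, 0.8])
    @pytest.mark.parametrize("r", [1, 2, 3, 5])
    def test_optimized_matches_brute_force(self, p, r):
        vol = lx.bernoulli_volume((9, 9, 9), p, seed=int(p * 100) + r)
        assert lx.gliding_box_lacunarity(vol, r) == pytest.approx(
            lx.brute_force_lacunarity(vol, r), abs=1e-12
        )

    def test_brute_force_r1_identity(self, foam16):
        small = lx.extract_roi(foam16, (0, 0, 0), (8, 8, 8))
        assert lx.brute_force_lacunarity(small, 1) == pytest.approx(
            1 / small.porosity().n, abs=1e-12
        )

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 2**16),
        p=st.floats(0.1, 0.9),
        r=st.integers(1, 4),
        side=st.integers(4, 8),
    )
    def test_property_equivalence_and_lower_bound(self, seed, p, r, side):
        vol = lx.bernoulli_volume((side,) * 3, p, seed=seed)
        if vol.porosity().pore_voxels == 0:
            return
        lac = lx.gliding_box_lacunarity(vol, r)
        assert lac >= 1.0
        assert lac == pytest.approx(lx.brute_force_lacunarity(vol, r), abs=1e-12)


class TestRelativeLacunarity:
    def test_unity_lac_gives_zero(self):
        assert lx.relative_lacunarity(1.0, 0.3) == 0.0

    @pytest.mark.parametrize("n", [0.81, 0.70, 0.68, 0.5, 0.999])
    def test_inverse_porosity_lac_gives_one(self, n):
        assert lx.relative_lacunarity(1 / n, n) == pytest.approx(1.0, rel=1e-12)

    def test_direct_substitution(self):
        # lac = 1/n^2 at n = 0.5: -ln(4)/ln(0.5) = 2
        assert lx.relative_lacunarity(4.0, 0.5) == pytest.approx(2.0, rel=1e-12)

    @pytest.mark.parametrize("n", [0.0, 1.0])
    def test_degenerate_porosity_rejected(self, n):
        with pytest.raises(ValueError):
            lx.relative_lacunarity(1.5, n)

    def test_subunit_lac_rejected(self):
        with pytest.raises(ValueError):
            lx.relative_lacunarity(0.99, 0.5)


class TestLacunarityCurve:
    def test_all_pore_curve_is_flat(self):
        curve = lx.lacunarity_curve(all_pore((8, 8, 8)), [1, 2, 4, 8])
        assert [rec.lac for rec in curve.records] == [1.0] * 4
        assert [rec.rlf for rec in curve.records] == [0.0] * 4

    def test_bernoulli_matches_iid_closed_form(self, bernoulli32):
        p = bernoulli32.porosity().n
        curve = lx.lacunarity_curve(bernoulli32, [1, 2, 4, 8])
        for rec in curve.records:
            expected = 1 + (1 - p) / (p * rec.r**3)
            assert rec.lac == pytest.approx(expected, rel=0.10)

    def test_foam_curve_matches_brute_force_record_for_record(self, foam16):
        curve = lx.lacunarity_curve(foam16, [1, 2, 3, 5, 8])
        for rec in curve.records:
            assert rec.lac == pytest.approx(
                lx.brute_force_lacunarity(foam16, rec.r), abs=1e-12
            )

    def test_endpoints(self, bernoulli32):
        curve = lx.lacunarity_curve(bernoulli32, list(range(1, 33)))
        lacs = [rec.lac for rec in curve.records]
        assert lacs[0] == max(lacs)
        assert lacs[0] == pytest.approx(1 / bernoulli32.porosity().n, abs=1e-12)
        assert lacs[-1] == 1.0  # single box covers the cube: zero variance
        assert curve.records[0].rlf == pytest.approx(1.0, rel=1e-12)

    def test_internal_consistency_identities(self, foam16):
        curve = lx.lacunarity_curve(foam16, [1, 2, 4, 8])
        for rec in curve.records:
            assert rec.lac == pytest.approx(1 + rec.var_s / rec.mean_s**2, abs=1e-9)
            assert rec.lac == pytest.approx(rec.mu2 / rec.mu1**2, abs=1e-9)
            assert rec.ln_lac == pytest.approx(math.log(rec.lac), abs=1e-12)

    def test_unsorted_r_rejected(self, foam16):
        with pytest.raises(ValueError):
            lx.lacunarity_curve(foam16, [4, 2, 1])

    def test_all_solid_failures_recorded_not_dropped_silently(self):
        solid = lx.BinaryVolume(np.zeros((4, 4, 4), dtype=np.uint8))
        curve = lx.lacunarity_curve(solid, [1, 2])
        assert curve.records == []
        assert [r for r, _ in curve.failures] == [1, 2]


class TestRandomnessScale:
    def test_all_pore_settles_at_smallest_r(self):
        curve = lx.lacunarity_curve(all_pore((8, 8, 8)), [1, 2, 4, 8])
        rs = lx.randomness_scale(curve, epsilon=0.05)
        assert rs.r_star == 1 and not rs.beyond_range

    def test_bernoulli_threshold_matches_closed_form(self, bernoulli32):
        # 1 + (1-p)/(p r^3) <= 1.01 first at r^3 >= (1-p)/(0.01 p) ~ 43 => r = 4
        curve = lx.lacunarity_curve(bernoulli32, list(range(1, 17)))
        rs = lx.randomness_scale(curve, epsilon=0.01)
        assert rs.r_star == 4

    def test_beyond_range_sentinel(self):
        coarse = lx.foam_volume(
            lx.SyntheticSpec((32, 32, 32), 0.5, "foam", pore_radius_mean=6.0,
                             pore_radius_sd=0.5, seed=9)
        )
        curve = lx.lacunarity_curve(coarse, [1, 2, 3])
        rs = lx.randomness_scale(curve, epsilon=1e-6)
        assert rs.beyond_range and rs.r_star is None
        assert str(rs) == "beyond range"

    def test_clustered_scale_at_least_random_scale(self):
        """A clustered foam stays heterogeneous to larger box sizes than an
        i.i.d. field of the same porosity."""
        foam = lx.foam_volume(
            lx.SyntheticSpec((32, 32, 32), 0.7, "foam", pore_radius_mean=4.0,
                             pore_radius_sd=0.5, seed=21)
        )
        bern = lx.bernoulli_volume((32, 32, 32), foam.porosity().n, seed=21)
        r_values = list(range(1, 33))
        eps = 0.01
        rs_foam = lx.randomness_scale(lx.lacunarity_curve(foam, r_values), eps)
        rs_bern = lx.randomness_scale(lx.lacunarity_curve(bern, r_values), eps)
        assert rs_bern.r_star is not None
        assert rs_foam.beyond_range or rs_foam.r_star >= rs_bern.r_star

    def test_needs_three_records(self, foam16):
        curve = lx.lacunarity_curve(foam16, [1, 2])
        with pytest.raises(ValueError):
            lx.randomness_scale(curve)
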