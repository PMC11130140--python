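"""Per-patient readouts: worked examples, closed forms, and the spatial
invariance / monotonicity properties of the proximity scores."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import qcscore.features as F
from conftest import make_sample, random_sample


class TestOdQuantile:
    def test_constant_distribution(self):
        s = make_sample([[0, 0], [1, 0], [2, 0]], [10, 10, 10])
        for q in (5, 50, 95, "mean"):
            assert F.od_quantile(s, q) == 10.0

    def test_linear_interpolation(self):
        s = make_sample([[0, 0], [1, 0]], [0, 10])
        assert F.od_quantile(s, 50) == pytest.approx(5.0)

    def test_matches_sort_and_interpolate_oracle(self, rng):
        od = rng.lognormal(2, 1, 1000)
        s = make_sample(rng.uniform(0, 100, (1000, 2)), od)
        # brute-force oracle: sort, then linear interpolation between order stats
        x = np.sort(od)
        h = 0.05 * (len(x) - 1)
        lo = int(np.floor(h))
        expected = x[lo] + (h - lo) * (x[lo + 1] - x[lo])
        assert F.od_quantile(s, 5) == expected

    def test_empty_is_missing(self):
        assert np.isnan(F.od_quantile(make_sample(), 50))


class TestPctPositive:
    def test_direct_count(self):
        s = make_sample([[0, 0], [1, 0], [2, 0]], [5, 10, 20])
        assert F.pct_od_positive(s, 6) == pytest.approx(200 / 3)

    def test_threshold_zero_all_positive(self):
        s = make_sample([[0, 0], [1, 0]], [0, 3])
        assert F.pct_od_positive(s, 0) == 100.0

    def test_boundary_is_inclusive(self):
        assert F.pct_od_positive(make_sample([[0, 0]], [6]), 6) == 100.0


class TestPositiveDensity:
    def test_counts_per_area(self):
        xy = np.column_stack([np.arange(60.0), np.zeros(60)])
        od = np.r_[np.full(50, 20.0), np.full(10, 1.0)]
        s = make_sample(xy, od, epithelium_area_mm2=2.0)
        assert F.positive_density(s, 6) == pytest.approx(25.0)

    def test_no_positive_cells(self):
        s = make_sample([[0, 0]], [1.0], epithelium_area_mm2=2.0)
        assert F.positive_density(s, 6) == 0.0

    def test_poisson_field_matches_intensity(self, rng):
        # lambda cells/mm^2 uniform in 4 mm^2; density ~= lambda * P(OD >= t)
        lam, area = 800, 4.0
        n = rng.poisson(lam * area)
        xy = rng.uniform(0, 2000, (n, 2))
        od = rng.lognormal(np.log(10), 0.5, n)
        s = make_sample(xy, od, epithelium_area_mm2=area)
        p_pos = np.mean(od >= 10)
        got = F.positive_density(s, 10)
        assert got == pytest.approx(lam * p_pos, rel=0.1)

    def test_missing_area_is_error(self):
        with pytest.raises(ValueError):
            F.positive_density(make_sample([[0, 0]], [10], epithelium_area_mm2=None), 6)


class TestBsps:
    def test_r_zero_equals_pct_positive(self, rng):
        for _ in range(20):
            s = random_sample(rng, n_cells=int(rng.integers(5, 80)))
            for t in (6, 20, 60):
                assert F.bsps(s, 0.0, t) == F.pct_od_positive(s, t)

    def test_collinear_three_cell_example(self):
        # cell at 0 is positive; cell at 30 has it as neighbor; cell at 100 has neither
        s = make_sample([[0, 0], [30, 0], [100, 0]], [20, 2, 2])
        assert F.bsps(s, 50, 10) == pytest.approx(200 / 3)

    def test_saturation_when_all_positive(self, rng):
        s = make_sample(rng.uniform(0, 50, (10, 2)), np.full(10, 30.0))
        for r in (0, 10, 75):
            assert F.bsps(s, r, 6) == 100.0

    def test_inclusive_neighborhood_boundary(self):
        s = make_sample([[0, 0], [50, 0]], [20, 2])
        assert F.bsps(s, 50, 10) == 100.0
        assert F.bsps(s, 49.999, 10) == 50.0


class TestCsps:
    def test_isolated_cell_keeps_own_od(self):
        s = make_sample([[0, 0], [500, 500]], [7.5, 20])
        values = F.csps_cell_values(s, 25)
        assert values[0] == 7.5

    def test_r_zero_returns_raw_ods(self, rng):
        s = random_sample(rng, 30)
        assert np.array_equal(F.csps_cell_values(s, 0.0), s.membrane_od())

    def test_two_cells_at_half_radius_closed_form(self):
        a, b, r = 12.0, 4.0, 30.0
        s = make_sample([[0, 0], [r / 2, 0]], [a, b])
        values = F.csps_cell_values(s, r)
        assert values[0] == pytest.approx((a + 0.5 * b) / 1.5)
        assert values[1] == pytest.approx((b + 0.5 * a) / 1.5)

    def test_unnormalized_mode_is_weighted_sum(self):
        a, b, r = 12.0, 4.0, 30.0
        s = make_sample([[0, 0], [r / 2, 0]], [a, b])
        values = F.csps_cell_values(s, r, normalize=False)
        assert values[0] == pytest.approx(a + 0.5 * b)

    def test_convex_combination_bounds(self, rng):
        s = random_sample(rng, 60, extent=100.0)
        od = s.membrane_od()
        values = F.csps_cell_values(s, 40.0)
        assert np.all(values >= od.min() - 1e-12)
        assert np.all(values <= od.max() + 1e-12)


class TestStilDensity:
    def test_no_tils(self):
        assert F.stil_density(make_sample([[0, 0]], [1])) == 0.0

    def test_stromal_count_over_area(self):
        tils = (np.zeros((340, 2)), ["stromal"] * 337 + ["intraepithelial"] * 3)
        s = make_sample([[0, 0]], [1], tils=tils, tumor_center_area_mm2=2.0)
        assert F.stil_density(s) == pytest.approx(168.5)

    def test_poisson_fixture_recovers_density(self, rng):
        n = rng.poisson(300 * 4.0)
        tils = (rng.uniform(0, 2000, (n, 2)), ["stromal"] * n)
        s = make_sample([[0, 0]], [1], tils=tils, tumor_center_area_mm2=4.0)
        assert F.stil_density(s) == pytest.approx(300, rel=0.1)

    def test_zero_area_is_error(self):
        with pytest.raises(ValueError):
            F.stil_density(make_sample([[0, 0]], [1], tumor_center_area_mm2=None))


class TestFeatureGrid:
    def test_default_enumeration_count(self):
        specs = F.expand_feature_grid()
        assert len(specs) == 19 + 1 + 17 + 17 + 4 * 17 + 4 * 20 + 1 == 203
        names = [s.name for s in specs]
        assert len(set(names)) == len(names)

    def test_restricted_grid(self):
        grid = F.FeatureGrid(od_thresholds=(6,), radii_um=(50.0,))
        specs = F.expand_feature_grid(grid)
        assert len(specs) == 19 + 1 + 1 + 1 + 1 + 20 + 1

    def test_empty_family_list(self):
        assert F.expand_feature_grid(F.FeatureGrid(families=())) == []

    def test_order_is_stable(self):
        assert [s.name for s in F.expand_feature_grid()] == [s.name for s in F.expand_feature_grid()]


class TestReadoutMatrix:
    def test_single_patient_single_spec(self):
        s = make_sample([[0, 0]], [10])
        m = F.compute_readout_matrix([s], [F.FeatureSpec("od_mean")])
        assert m.values.shape == (1, 1)
        assert m.values.iloc[0, 0] == 10.0

    def test_duplicate_spec_gives_identical_columns(self, rng):
        s = random_sample(rng, 40)
        spec = F.FeatureSpec("pct_positive", od_threshold=6)
        m = F.compute_readout_matrix([s], [spec, spec])
        assert m.values.iloc[:, 0].equals(m.values.iloc[:, 1])

    def test_failures_recorded_as_missing(self, rng):
        s = random_sample(rng, 10)
        s.epithelium_area_mm2 = None
        m = F.compute_readout_matrix([s], [F.FeatureSpec("positive_density", od_threshold=6)])
        assert np.isnan(m.values.iloc[0, 0])
        assert "P1" in m.failures

    def test_cached_matrix_matches_direct_calls(self, rng):
        samples = [random_sample(rng, 80, patient_id=f"P{i}") for i in range(3)]
        specs = [
            F.FeatureSpec("bsps", od_threshold=10, radius_um=50.0),
            F.FeatureSpec("csps", radius_um=50.0, aggregation=50),
        ]
        m = F.compute_readout_matrix(samples, specs)
        for i, s in enumerate(samples):
            assert m.values.iloc[i, 0] == F.bsps(s, 50.0, 10)
            assert m.values.iloc[i, 1] == F.csps(s, 50.0, 50)


class TestSpatialProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bsps_monotone_in_radius_and_threshold(self, seed):
        rng = np.random.default_rng(seed)
        s = random_sample(rng, 40, extent=200.0)
        radii = [0, 10, 25, 50]
        thresholds = [6, 12, 30]
        for t in thresholds:
            vals = [F.bsps(s, r, t) for r in radii]
            assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))
        for r in radii:
            vals = [F.bsps(s, r, t) for t in thresholds]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        s = random_sample(rng, 30, extent=100.0)
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        xy2 = s.coordinates() @ rot.T + rng.uniform(-50, 50, 2)
        s2 = make_sample(xy2, s.membrane_od())
        assert F.bsps(s2, 25, 10) == pytest.approx(F.bsps(s, 25, 10), abs=1e-9)
        np.testing.assert_allclose(
            F.csps_cell_values(s2, 25), F.csps_cell_values(s, 25), rtol=1e-9
        )

    def test_quantiles_monotone_in_q(self, rng):
        s = random_sample(rng, 100)
        vals = [F.od_quantile(s, q) for q in range(5, 100, 5)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))
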