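import numpy as np
import pytest

from batscape.calibration import RMAModel
from batscape.circular import VonMisesModel
from batscape.mapping import (
    angular_map,
    bearing_grid,
    build_precip_pdf,
    combine,
    latitude_band_profile,
    map_centroid,
    merge_weighted,
    reclassify,
    run_stratified,
    simulate_precip,
)
from batscape.raster import Isoscape, ProbabilityMap, minmax_standardize

MODEL = RMAModel(slope=1.3, intercept=-10.0, resid_sd=6.3, n=50, r=0.95)


class TestSimulatePrecip:
    def test_degenerate_spread(self):
        d = simulate_precip(MODEL, -111.0, n=100, gamma_shape=11.1, gamma_scale=0.0)
        np.testing.assert_allclose(d, MODEL.invert(-111.0))

    def test_mean_near_inverted_value(self):
        d = simulate_precip(MODEL, -111.0, n=10000, rng=1)
        mu = float(MODEL.invert(-111.0))
        se = d.std() / np.sqrt(d.size)
        assert abs(d.mean() - mu) <= 3 * se

    def test_seed_reproducibility(self):
        a = simulate_precip(MODEL, -100.0, n=1000, rng=42)
        b = simulate_precip(MODEL, -100.0, n=1000, rng=42)
        np.testing.assert_array_equal(a, b)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_precip(MODEL, -100.0, n=0)
        with pytest.raises(ValueError):
            simulate_precip(MODEL, -100.0, gamma_shape=-1.0, gamma_scale=1.0)


class TestPrecipPDF:
    def test_standardized_max_is_one(self):
        d = np.random.default_rng(0).normal(-56, 8, 5000)
        pdf = build_precip_pdf(d)
        assert pdf.grid_y.max() == pytest.approx(1.0)
        assert pdf(pdf.argmax) == pytest.approx(1.0, abs=1e-3)

    def test_argmax_near_analytic_mode(self):
        d = np.random.default_rng(1).normal(-56, 8, 10000)
        assert build_precip_pdf(d).argmax == pytest.approx(-56.0, abs=0.8)

    def test_nonnegative_everywhere(self):
        d = np.random.default_rng(2).normal(-56, 8, 1000)
        pdf = build_precip_pdf(d)
        x = np.linspace(-200, 100, 500)
        assert np.all(pdf(x) >= 0)

    def test_point_mass(self):
        pdf = build_precip_pdf(np.full(200, -60.0))
        assert pdf(-60.0) == 1.0
        assert pdf(-61.0) == 0.0

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            build_precip_pdf(np.zeros(50))


class TestReclassify:
    def test_pointwise_evaluation(self, toy_isoscape):
        d = np.random.default_rng(3).normal(-68, 5, 2000)
        pdf = build_precip_pdf(d)
        pm = reclassify(toy_isoscape, pdf)
        for i in range(3):
            for j in range(3):
                v = toy_isoscape.values[i, j]
                if np.isnan(v):
                    assert np.isnan(pm.values[i, j])
                else:
                    assert pm.values[i, j] == pytest.approx(float(pdf(v)))

    def test_argmax_cell_scores_one(self, toy_isoscape):
        d = np.random.default_rng(4).normal(-68, 5, 2000)
        pdf = build_precip_pdf(d)
        iso = Isoscape(values=np.array([[pdf.argmax, -200.0]]), lat_max=52,
                       lon_min=10, cell_arcmin=60)
        pm = reclassify(iso, pdf)
        assert pm.values[0, 0] == pytest.approx(1.0, abs=1e-6)


class TestMerge:
    def pm(self, template, vals):
        return ProbabilityMap.like(template, np.asarray(vals, dtype=float))

    def test_single_map_identity(self, toy_isoscape):
        a = self.pm(toy_isoscape, np.random.default_rng(0).random((3, 3)))
        out = merge_weighted([a], [7.0])
        np.testing.assert_allclose(out.values, a.values)

    def test_weighted_mean_arithmetic(self, toy_isoscape):
        a = self.pm(toy_isoscape, np.full((3, 3), 0.2))
        b = self.pm(toy_isoscape, np.full((3, 3), 0.6))
        out = merge_weighted([a, b], [1.0, 3.0])
        np.testing.assert_allclose(out.values, (0.2 + 3 * 0.6) / 4)

    def test_permutation_invariance_and_idempotence(self, toy_isoscape):
        rng = np.random.default_rng(5)
        a = self.pm(toy_isoscape, rng.random((3, 3)))
        b = self.pm(toy_isoscape, rng.random((3, 3)))
        ab = merge_weighted([a, b], [2.0, 5.0])
        ba = merge_weighted([b, a], [5.0, 2.0])
        np.testing.assert_allclose(ab.values, ba.values)
        same = merge_weighted([a, a, a], [1, 1, 1])
        np.testing.assert_allclose(same.values, a.values)

    def test_provenance_weights_sum_to_one(self, toy_isoscape):
        a = ProbabilityMap.like(toy_isoscape, np.zeros((3, 3)), provenance={"S1": 1.0})
        b = ProbabilityMap.like(toy_isoscape, np.zeros((3, 3)), provenance={"S2": 1.0})
        out = merge_weighted([a, b], [1.0, 3.0])
        assert out.provenance == {"S1": 0.25, "S2": 0.75}

    def test_errors(self, toy_isoscape):
        a = self.pm(toy_isoscape, np.zeros((3, 3)))
        other = Isoscape(values=np.zeros((2, 2)), lat_max=54, lon_min=10,
                         cell_arcmin=60)
        b = ProbabilityMap.like(other, np.zeros((2, 2)))
        with pytest.raises(ValueError):
            merge_weighted([a, b], [1, 1])
        with pytest.raises(ValueError):
            merge_weighted([a], [0.0])


class TestBearingGrid:
    def test_due_north_cell(self, toy_isoscape):
        # site directly south of the middle column's cells
        b = bearing_grid(50.0, 11.5, toy_isoscape)
        assert b[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert b[1, 1] == pytest.approx(0.0, abs=1e-9)

    def test_masked_and_coincident_cells(self, toy_isoscape):
        b = bearing_grid(52.5, 11.5, toy_isoscape)  # coincides with center cell
        assert np.isnan(b[1, 1])
        assert np.isnan(b[2, 1])  # no-data cell
        finite = b[np.isfinite(b)]
        assert np.all((finite >= 0) & (finite < 360))


class TestAngularMap:
    def test_uniform_model_constant(self, toy_isoscape):
        pm = angular_map(50.0, 11.5, VonMisesModel(mu_deg=0, kappa=0.0), toy_isoscape)
        finite = pm.values[np.isfinite(pm.values)]
        np.testing.assert_allclose(finite, 1.0)

    def test_cells_along_mean_direction_score_max(self, toy_isoscape):
        pm = angular_map(50.0, 11.5, VonMisesModel(mu_deg=0.0, kappa=4.0), toy_isoscape)
        # middle column is due north of the site
        assert pm.values[0, 1] == pytest.approx(np.nanmax(pm.values))

    def test_equals_direct_evaluation(self, toy_isoscape):
        m = VonMisesModel(mu_deg=45.0, kappa=2.0)
        pm = angular_map(50.0, 10.0, m, toy_isoscape)
        b = bearing_grid(50.0, 10.0, toy_isoscape)
        sel = np.isfinite(b)
        np.testing.assert_allclose(pm.values[sel], m.density(b[sel]), atol=1e-12)


class TestCombine:
    def test_constant_angular_leaves_iso(self, toy_isoscape):
        rng = np.random.default_rng(6)
        iso_pm = ProbabilityMap.like(toy_isoscape, rng.random((3, 3)))
        ang = ProbabilityMap.like(toy_isoscape, np.ones((3, 3)), role="PM_Ang")
        breed = combine(iso_pm, ang)
        np.testing.assert_allclose(
            breed.values, minmax_standardize(iso_pm).values, atol=1e-12
        )

    def test_zero_factor_gives_zero(self, toy_isoscape):
        a = ProbabilityMap.like(toy_isoscape, np.array([[0.0, 0.5, 1.0]] * 3))
        b = ProbabilityMap.like(toy_isoscape, np.ones((3, 3)), role="PM_Ang")
        assert combine(a, b).values[0, 0] == 0.0

    def test_product_and_minmax_hand_arithmetic(self, toy_isoscape):
        a = ProbabilityMap.like(toy_isoscape, np.array(
            [[0.1, 0.2, 0.3], [0.4, 0.5, 0.6], [0.7, 0.8, 0.9]]))
        b = ProbabilityMap.like(toy_isoscape, np.array(
            [[0.9, 0.8, 0.7], [0.6, 0.5, 0.4], [0.3, 0.2, 0.1]]), role="PM_Ang")
        prod = a.values * b.values
        expected = (prod - prod.min()) / (prod.max() - prod.min())
        np.testing.assert_allclose(combine(a, b).values, expected, atol=1e-12)

    def test_product_bounded_by_factors(self, toy_isoscape):
        rng = np.random.default_rng(7)
        a = rng.random((3, 3))
        b = rng.random((3, 3))
        assert np.all(a * b <= np.minimum(a, b) + 1e-15)

    def test_range_invariant(self, toy_isoscape):
        rng = np.random.default_rng(8)
        a = ProbabilityMap.like(toy_isoscape, rng.random((3, 3)))
        b = ProbabilityMap.like(toy_isoscape, rng.random((3, 3)), role="PM_Ang")
        breed = combine(a, b)
        assert np.nanmin(breed.values) == 0.0 and np.nanmax(breed.values) == 1.0


@pytest.fixture(scope="module")
def published_rma(world):
    """External calibration parameters, as consumed in the study design."""
    c = world.config
    return RMAModel(slope=c.rma_slope, intercept=c.rma_intercept,
                    resid_sd=c.calib_resid_sd, n=50)


@pytest.fixture(scope="module")
def maps(world, published_rma):
    from batscape.calibration import classify_records

    cl = classify_records(world.records, world.sites, published_rma)
    return run_stratified(
        cl, world.sites, published_rma, world.isoscape, world.bearings,
        strata="sex", draws=4000, seed=11,
    )


class TestRunStratified:

    def test_all_roles_present_and_in_range(self, maps):
        for stratum, roles in maps.items():
            assert set(roles) == {"PM_Iso", "PM_Ang", "PM_Breed"}
            for pm in roles.values():
                finite = pm.values[np.isfinite(pm.values)]
                assert np.all((finite >= 0) & (finite <= 1))
            for role in ("PM_Iso", "PM_Breed"):
                assert np.nanmin(roles[role].values) == 0.0
                assert np.nanmax(roles[role].values) == 1.0

    def test_true_band_gets_highest_breed_mass(self, maps, world):
        band = world.config.migrant_band
        width = band[1] - band[0]
        for roles in maps.values():
            prof = latitude_band_profile(roles["PM_Breed"], width)
            top = prof.loc[prof["mean"].idxmax()]
            assert top.lat_lo <= (band[0] + band[1]) / 2 <= top.lat_hi

    def test_female_centroid_north_of_male(self, maps):
        f_lat, _ = map_centroid(maps["female"]["PM_Breed"])
        m_lat, _ = map_centroid(maps["male"]["PM_Breed"])
        assert f_lat > m_lat

    def test_unclassified_records_rejected(self, world, rma):
        with pytest.raises(ValueError):
            run_stratified(world.records, world.sites, rma, world.isoscape,
                           world.bearings)

    def test_stratum_without_migrants_skipped(self, world, rma, classified):
        females_only = classified[classified["sex"] == "female"]
        out = run_stratified(females_only, world.sites, rma, world.isoscape,
                             world.bearings, strata="sex", draws=500, seed=1)
        assert "male" not in out and "female" in out


class TestMonteCarloStability:
    def test_merged_pm_iso_stable_across_seeds(self, world, published_rma):
        from batscape.calibration import classify_records

        cl = classify_records(world.records, world.sites, published_rma)
        kw = dict(strata="all", draws=10000)
        a = run_stratified(cl, world.sites, published_rma, world.isoscape,
                           world.bearings, seed=1, **kw)["all"]["PM_Iso"]
        b = run_stratified(cl, world.sites, published_rma, world.isoscape,
                           world.bearings, seed=2, **kw)["all"]["PM_Iso"]
        assert np.nanmax(np.abs(a.values - b.values)) < 0.05
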