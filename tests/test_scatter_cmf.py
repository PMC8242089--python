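import numpy as np
import pandas as pd
import pytest

from foceamap import scatter_cmf as sc
from foceamap import synthetic


class TestLocateFocea:
    def test_finds_cortical_center_of_clean_map(self):
        cells = synthetic.simulate_cortex(
            synthetic.CortexModelParams(exponent_a=1.5, scatter_k=0.0)
        )
        x, y = sc.locate_focea_cortex(cells)
        assert abs(x) < 0.15 and abs(y) < 0.15

    def test_sparse_records_raise(self):
        rec = pd.DataFrame(
            dict(
                cortical_x_mm=[0.0, 1.0, 2.0],
                cortical_y_mm=[0.0, 1.0, 2.0],
                azi=[0.0, 10.0, 20.0],
                ele=[20.0, 20.0, 20.0],
            )
        )
        with pytest.raises(ValueError):
            sc.locate_focea_cortex(rec, window_radius_mm=0.1, min_cells=3)


class TestRotateAxes:
    def test_recovers_known_rotation(self):
        cells = synthetic.simulate_cortex(
            synthetic.CortexModelParams(exponent_a=1.0, scatter_k=0.0)
        )
        th = np.deg2rad(30.0)
        rot = cells.copy()
        x, y = cells.cortical_x_mm.to_numpy(), cells.cortical_y_mm.to_numpy()
        rot["cortical_x_mm"] = np.cos(th) * x - np.sin(th) * y
        rot["cortical_y_mm"] = np.sin(th) * x + np.cos(th) * y
        back, ang = sc.rotate_cortical_axes(rot)
        assert ang == pytest.approx(30.0, abs=0.5)
        # after rotation the azimuth gradient lies along x again
        X = np.stack(
            [np.ones(len(back)), back.cortical_x_mm, back.cortical_y_mm], axis=1
        )
        coef, *_ = np.linalg.lstsq(X, back.azi.to_numpy(), rcond=None)
        assert abs(coef[2]) < 1e-6 * abs(coef[1])

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            sc.rotate_cortical_axes(
                pd.DataFrame(dict(cortical_x_mm=[0.0], cortical_y_mm=[0.0], azi=[0.0]))
            )


class TestFitCMF:
    def test_noiseless_exponent_recovery(self):
        cells = synthetic.simulate_cortex(
            synthetic.CortexModelParams(
                exponent_a=1.5, scatter_k=0.0, decomposition="spherical"
            )
        )
        fit = sc.fit_cmf(cells, axis="eccentricity")
        assert fit.b == pytest.approx(1.5, abs=0.01)
        assert fit.a == pytest.approx(1.0 / 0.02, rel=0.01)
        assert np.max(np.abs(fit.residuals_deg)) < 0.5

    def test_linear_map_constant_cmf(self):
        cells = synthetic.simulate_cortex(
            synthetic.CortexModelParams(exponent_a=1.0, scatter_k=0.0)
        )
        fit = sc.fit_cmf(cells, axis="azimuth")
        assert fit.b == pytest.approx(1.0, abs=0.02)
        ok = np.isfinite(fit.cmf)
        assert np.allclose(fit.cmf[ok], 0.02, atol=2e-3)
        assert sc.cmf_at_focea(fit) == pytest.approx(0.02, abs=1e-3)

    def test_predict_round_trip(self):
        cells = synthetic.simulate_cortex(
            synthetic.CortexModelParams(exponent_a=1.2, scatter_k=0.0,
                                        decomposition="spherical")
        )
        fit = sc.fit_cmf(cells, axis="eccentricity")
        v = np.array([5.0, 20.0, 40.0])
        assert np.allclose(fit.predict_visual(fit.predict_cortical(v)), v, atol=1e-8)

    def test_robust_to_outliers(self):
        # least-absolute-deviation fit should shrug off a few wild records
        rng = np.random.default_rng(0)
        x = np.linspace(0.0, 2.0, 200)
        v = 50.0 * x
        v[rng.choice(200, 5, replace=False)] += 300.0
        rec = pd.DataFrame(dict(cortical_x_mm=x, azi=v))
        fit = sc.fit_cmf(rec, axis="azimuth")
        assert fit.b == pytest.approx(1.0, abs=0.05)

    def test_negative_values_shifted(self):
        x = np.linspace(0.0, 2.0, 100)
        rec = pd.DataFrame(dict(cortical_x_mm=x, azi=50.0 * x - 60.0))
        fit = sc.fit_cmf(rec, axis="azimuth")
        assert fit.shift == pytest.approx(61.0)  # -min + 1
        # the shifted power law cannot be exactly affine, but residuals stay
        # small relative to the 100-deg span
        assert np.max(np.abs(fit.residuals_deg)) < 2.0
        assert fit.b == pytest.approx(1.0, abs=0.05)

    def test_unknown_axis(self):
        with pytest.raises(ValueError):
            sc.fit_cmf(pd.DataFrame(), axis="diagonal")

    def test_narrow_span_raises(self):
        rec = pd.DataFrame(
            dict(cortical_x_mm=np.linspace(0, 1, 50), azi=np.full(50, 10.0))
        )
        with pytest.raises(ValueError):
            sc.fit_cmf(rec, axis="azimuth")


def _synthetic_cmf_fit(residuals, v):
    return sc.CMFFit(
        a=50.0, b=1.0, shift=0.0, axis="eccentricity",
        eval_v=np.array([2.5]), cmf=np.array([0.02]),
        v_obs=v + residuals, x_obs=v / 50.0, residuals_deg=residuals,
    )


class TestScatterProfile:
    def test_recovers_proportional_scatter(self):
        ks = []
        for seed in range(5):
            cells = synthetic.simulate_cortex(
                synthetic.CortexModelParams(
                    n_grid=32, exponent_a=1.0, scatter_k=0.18, seed=seed,
                    decomposition="spherical",
                )
            )
            fit = sc.fit_cmf(cells, axis="eccentricity")
            prof = sc.scatter_profile(fit, n_null=200, seed=seed)
            ks.append(prof.sigma_coefficient)
        assert 0.12 < np.mean(ks) < 0.22

    def test_heteroscedastic_residuals_significant(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0.0, 60.0, 500)
        res = rng.normal(0.0, 0.18 * v)
        prof = sc.scatter_profile(_synthetic_cmf_fit(res, v), n_null=1000, seed=0)
        assert prof.p < 0.01
        assert prof.slope > 0

    def test_null_is_calibrated(self):
        # under homoscedastic residuals the permutation p-value is uniform
        rng = np.random.default_rng(1)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            v = rng.uniform(0.0, 60.0, 400)
            res = rng.normal(0.0, 3.0, 400)
            prof = sc.scatter_profile(
                _synthetic_cmf_fit(res, v), n_null=400, seed=int(rng.integers(1 << 30))
            )
            hits += prof.p <= 0.1
        assert 2 <= hits <= 20  # ~Binomial(100, 0.1)

    def test_iqr_to_sigma_conversion(self):
        prof = sc.ScatterProfile(
            np.arange(10.0), np.arange(10.0), slope=sc.IQR_PER_SIGMA,
            intercept=0.0, p=0.0, n_null=0,
        )
        assert prof.sigma_coefficient == pytest.approx(1.0)

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            sc.scatter_profile(_synthetic_cmf_fit(np.zeros(10), np.arange(10.0)))


class TestBinocularScatter:
    def test_detects_lower_binocular_scatter(self):
        rng = np.random.default_rng(0)
        azi = np.concatenate([rng.uniform(-10, 10, 100), rng.uniform(20, 60, 100)])
        res = np.concatenate([rng.normal(0, 1, 100), rng.normal(0, 2, 100)])
        delta, p = sc.binocular_scatter_test(azi, res, seed=0)
        assert delta > 0.5
        assert p < 0.01

    def test_equal_scatter_not_significant(self):
        rng = np.random.default_rng(1)
        azi = np.concatenate([rng.uniform(-10, 10, 100), rng.uniform(20, 60, 100)])
        res = rng.normal(0, 1, 200)
        _, p = sc.binocular_scatter_test(azi, res, seed=0)
        assert p > 0.05

    def test_boundary_excluded_and_small_groups_raise(self):
        azi = np.full(100, 15.0)  # exactly on the cut: neither group
        with pytest.raises(ValueError):
            sc.binocular_scatter_test(azi, np.zeros(100))


class TestAggregatePRF:
    def test_two_disc_hull_oracle(self):
        # hull of two equal discs d apart: pi r^2 + 2 r d
        r, d = 10.0, 30.0
        area = sc.disc_union_hull_area([0.0, d], [0.0, 0.0], [2 * r, 2 * r])
        assert area == pytest.approx(np.pi * r * r + 2 * r * d, rel=0.002)

    def test_single_unit_diameter_is_fwhm(self):
        units = pd.DataFrame(
            dict(cortical_x_mm=[0.0], cortical_y_mm=[0.0],
                 azi=[10.0], ele=[20.0], fwhm=[24.0])
        )
        ag = sc.aggregate_prf(units, (0.0, 0.0), 0.1)
        assert ag.n_units == 1
        assert ag.diameter_deg == pytest.approx(24.0, rel=0.002)

    def test_empty_window_raises(self):
        units = pd.DataFrame(
            dict(cortical_x_mm=[1.0], cortical_y_mm=[1.0],
                 azi=[0.0], ele=[0.0], fwhm=[10.0])
        )
        with pytest.raises(ValueError):
            sc.aggregate_prf(units, (0.0, 0.0), 0.1)

    def test_diameter_monotone_in_window_radius(self):
        cells = synthetic.simulate_cortex(
            synthetic.CortexModelParams(exponent_a=1.0, scatter_k=0.0)
        )
        small = sc.aggregate_prf(cells, (0.0, 0.0), 0.2)
        large = sc.aggregate_prf(cells, (0.0, 0.0), 0.6)
        assert large.diameter_deg > small.diameter_deg
        assert large.n_units > small.n_units

    def test_table_and_regression(self):
        cells = synthetic.simulate_cortex(
            synthetic.CortexModelParams(exponent_a=1.5, scatter_k=0.0)
        )
        table = sc.aggregate_prf_table(cells, radius_mm=0.25)
        assert {"n", "sqrt_n", "ecc", "diameter_deg"} <= set(table.columns)
        out = sc.regress_prf_on_ecc(table)
        # compressive map: local magnification falls with eccentricity, so
        # a fixed cortical window spans more visual degrees peripherally
        assert out["slope"] > 0
        assert out["p"] < 1e-6

    def test_collinear_covariate_dropped(self):
        cells = synthetic.simulate_cortex(
            synthetic.CortexModelParams(exponent_a=1.5, scatter_k=0.0)
        )
        table = sc.aggregate_prf_table(cells, radius_mm=0.25)
        with pytest.warns(UserWarning, match="collinear"):
            out = sc.regress_prf_on_ecc(table, covariates=("n", "n"))
        assert out["covariates"] == ["n"]

    def test_too_few_aggregates(self):
        with pytest.raises(ValueError):
            sc.regress_prf_on_ecc(pd.DataFrame(dict(ecc=[1.0], diameter_deg=[1.0])))


def _linear_tile(origin, shape):
    r0, c0 = origin
    rows = np.arange(shape[0])[:, None] + r0
    cols = np.arange(shape[1])[None, :] + c0
    return dict(
        origin=origin,
        azimuth=np.broadcast_to(cols, shape).astype(float).copy(),
        elevation=np.broadcast_to(rows, shape).astype(float).copy(),
        fwhm=np.full(shape, 20.0),
    )


class TestStitching:
    def test_overlap_average_is_exact(self):
        tiles = [_linear_tile((0, 0), (12, 12)), _linear_tile((8, 8), (12, 12))]
        out = sc.stitch_tiles(tiles, (20, 20))
        obs = out["observed"]
        rr, cc = np.nonzero(obs)
        assert np.allclose(out["azimuth"][obs], cc)
        assert np.allclose(out["elevation"][obs], rr)

    def test_interior_gap_filled(self):
        tile = _linear_tile((0, 0), (12, 12))
        tile["azimuth"][5, 5] = np.nan
        out = sc.stitch_tiles([tile], (12, 12))
        assert not out["observed"][5, 5]
        assert out["azimuth"][5, 5] == pytest.approx(5.0, abs=1e-9)

    def test_disconnected_tiles_raise(self):
        tiles = [_linear_tile((0, 0), (5, 5)), _linear_tile((10, 10), (5, 5))]
        with pytest.raises(ValueError, match="disconnected"):
            sc.stitch_tiles(tiles, (20, 20))

    def test_pixel_prf_windows(self):
        tile = _linear_tile((0, 0), (24, 24))
        table = sc.stitch_and_pixel_prf(
            [tile], (24, 24), pixel_mm=0.05, window_radii_mm=(0.2,), stride_px=4
        )
        assert len(table) > 0
        assert (table["diameter_deg"] >= 20.0).all()
        assert (table["data_fraction"] >= 0.75).all()

    def test_pixel_prf_respects_data_fraction(self):
        tile = _linear_tile((0, 0), (24, 24))
        tile["azimuth"][:, 12:] = np.nan  # right half unobserved
        table = sc.stitch_and_pixel_prf(
            [tile], (24, 24), pixel_mm=0.05, window_radii_mm=(0.2,),
            stride_px=4, min_data_fraction=0.9,
        )
        full = sc.stitch_and_pixel_prf(
            [_linear_tile((0, 0), (24, 24))], (24, 24), pixel_mm=0.05,
            window_radii_mm=(0.2,), stride_px=4, min_data_fraction=0.9,
        )
        # windows overlapping the missing half are excluded
        assert len(table) < len(full)
        assert (table["center_x_mm"] <= 12 * 0.05).all()
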