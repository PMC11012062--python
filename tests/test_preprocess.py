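import numpy as np
import pytest

from specfuse.crossval import MCCVConfig
from specfuse.io import SpectralDataset
from specfuse.preprocess import (lrc, minmax_norm, msc, snv, ss_apply, ss_fit)
from specfuse.regressors import fit_plsr
from specfuse.simulate import MixtureModelParams, simulate_dataset

WL5 = np.array([600.0, 625.0, 650.0, 675.0, 700.0])


def ds_of(X, y=None):
    X = np.atleast_2d(np.asarray(X, float))
    wl = np.linspace(600.0, 700.0, X.shape[1])
    return SpectralDataset(wl, X, y=y)


class TestSNV:
    def test_postcondition(self, small_mixture):
        out = snv(small_mixture[0])
        assert np.allclose(out.X.mean(axis=1), 0, atol=1e-10)
        assert np.allclose(out.X.std(axis=1), 1, atol=1e-10)

    def test_idempotent_and_affine_invariant(self):
        x = np.array([[0.3, 0.9, 0.1, 0.5, 0.7]])
        once = snv(ds_of(x)).X
        assert np.allclose(snv(ds_of(once)).X, once, atol=1e-12)
        assert np.allclose(snv(ds_of(2.5 * x + 3.0)).X, once, atol=1e-10)

    def test_constant_spectrum_names_sample(self):
        ds = SpectralDataset(WL5, np.vstack([np.ones(5), np.arange(5.0)]),
                             ["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            snv(ds)


class TestMinMax:
    def test_example_row(self):
        out = minmax_norm(ds_of([[2.0, 4.0, 6.0]]))
        assert np.allclose(out.X, [[0.0, 0.5, 1.0]], atol=1e-12)

    def test_postcondition_and_affine_invariance(self, small_mixture):
        out = minmax_norm(small_mixture[0])
        assert np.allclose(out.X.min(axis=1), 0, atol=1e-10)
        assert np.allclose(out.X.max(axis=1), 1, atol=1e-10)
        scaled = small_mixture[0].with_X(3.0 * small_mixture[0].X - 1.0)
        assert np.allclose(minmax_norm(scaled).X, out.X, atol=1e-10)


class TestMSC:
    def test_affine_family_collapses_to_reference(self):
        ref = np.sin(np.linspace(0, np.pi, 20)) + 1.0
        rows = [2.0 * ref + 0.5, 0.7 * ref - 0.1, ref]
        out = msc(ds_of(rows), reference=ref)
        assert np.allclose(out.X, np.vstack([ref] * 3), atol=1e-10)

    def test_closed_form_simple_regression(self):
        """Coefficients match the hand least-squares formulas."""
        rng = np.random.default_rng(4)
        ref = rng.uniform(0.5, 1.5, size=7)
        X = rng.uniform(0.0, 2.0, size=(3, 7))
        out = msc(ds_of(X), reference=ref)
        for i in range(3):
            a = np.cov(ref, X[i], bias=True)[0, 1] / np.var(ref)
            b = X[i].mean() - a * ref.mean()
            assert np.allclose(out.X[i], (X[i] - b) / a, atol=1e-10)

    def test_idempotent_with_calibration_mean(self, small_mixture):
        ds, _ = small_mixture
        ref = ds.X.mean(axis=0)
        once = msc(ds, reference=ref)
        twice = msc(once, reference=ref)
        assert np.allclose(once.X, twice.X, atol=1e-8)


class TestLRC:
    def test_pure_additive_shifts_collapse(self):
        """Rows M + b_i all map to M + mean(b) after intercept removal."""
        wl = np.linspace(600, 700, 50)
        M = np.exp(-0.5 * ((wl - 660) / 15.0) ** 2) + 0.2
        shifts = [-0.2, 0.0, 0.3]
        X = np.vstack([M + b for b in shifts])
        res = lrc(SpectralDataset(wl, X))
        expected = M + np.mean(shifts)
        assert np.allclose(res.corrected.X, np.vstack([expected] * 3), atol=1e-10)
        assert np.allclose(res.intercepts, np.array(shifts) - np.mean(shifts),
                           atol=1e-10)

    def test_reference_row_unchanged(self):
        ref = np.linspace(0.2, 1.0, 10)
        res = lrc(ds_of([ref, 2 * ref]), reference_mean=ref)
        assert np.allclose(res.corrected.X[0], ref, atol=1e-12)
        assert abs(res.intercepts[0]) < 1e-12

    def test_recovers_true_baselines_on_additive_data(self):
        params = MixtureModelParams(n_samples=60,
                                    wavelengths=np.arange(600.0, 701.0),
                                    p_range=(1.0, 1.0), b_sd=0.05,
                                    noise_sd=1e-4, seed=5)
        ds, truth = simulate_dataset(params)
        res = lrc(ds)
        r = np.corrcoef(res.intercepts, truth["b"])[0, 1]
        assert r > 0.99

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            lrc(ds_of([[1.0, 2.0, 3.0]]), reference_mean=np.ones(3))


def _ss_mixture(seed=11, **kw):
    params = MixtureModelParams(n_samples=40,
                                wavelengths=np.arange(600.0, 701.0, 2.0),
                                noise_sd=1e-4, seed=seed, **kw)
    return simulate_dataset(params)


@pytest.fixture(scope="module")
def fitted():
    ds, truth = _ss_mixture()
    model = ss_fit(ds, mccv=MCCVConfig(n_repeats=15, seed=2), max_lvs=8)
    return ds, truth, model


class TestSpectraToSpectra:

    def test_reference_column_is_all_ones(self, fitted):
        ds, _, model = fitted
        out = ss_apply(ds, model)
        assert np.allclose(out.X[:, model.reference_wavelength_index], 1.0,
                           atol=1e-12)

    def test_reference_wavelength_in_dominance_region(self, fitted):
        """The search lands where the constant component dominates."""
        _, truth, model = fitted
        assert model.reference_wavelength_index in truth["dominance_region"]

    def test_ss_beats_raw_plsr(self, fitted):
        ds, _, model = fitted
        corrected = ss_apply(ds, model)
        mccv = MCCVConfig(n_repeats=15, seed=9)
        raw_fit = fit_plsr(ds.X, ds.y, max_lvs=8, mccv=mccv)
        ss_fit_m = fit_plsr(corrected.X, corrected.y, max_lvs=8, mccv=mccv)
        assert np.nanmin(ss_fit_m.rmsecv_by_lv) < np.nanmin(raw_fit.rmsecv_by_lv)

    def test_no_spurious_gain_without_effects(self):
        """With p=1, b=0 the ratio cannot beat raw PLSR beyond noise."""
        ds, _ = _ss_mixture(p_range=(1.0, 1.0), b_sd=0.0)
        model = ss_fit(ds, mccv=MCCVConfig(n_repeats=10, seed=2), max_lvs=8)
        raw = fit_plsr(ds.X, ds.y, max_lvs=8,
                       mccv=MCCVConfig(n_repeats=10, seed=2))
        # noise 1e-4 in absorbance maps to ~1e-3 in reference units
        assert np.nanmin(model.rmsecv_trace) >= \
            np.nanmin(raw.rmsecv_by_lv) - 1e-2

    def test_argmin_attained_over_non_excluded(self, fitted):
        _, _, model = fitted
        assert model.rmsecv_trace[model.reference_wavelength_index] == \
            np.nanmin(model.rmsecv_trace)
        assert np.all(np.isnan(model.rmsecv_trace[model.excluded_candidates]))

    def test_scale_invariance_of_single_sample(self, fitted):
        ds, _, model = fitted
        out1 = ss_apply(ds, model)
        scaled = ds.with_X(ds.X * 3.7)
        out2 = ss_apply(scaled, model)
        assert np.allclose(out1.X, out2.X, atol=1e-9)

    def test_identical_concentrations_agree_after_correction(self):
        """Two samples differing only in (p, b) become identical."""
        params = MixtureModelParams(n_samples=30,
                                    wavelengths=np.arange(600.0, 701.0, 2.0),
                                    noise_sd=1e-5, seed=3)
        ds, truth = simulate_dataset(params)
        # duplicate sample 0's concentrations with different p, b
        S = truth["component_spectra"]
        C = truth["concentrations"].copy()
        C[1] = C[0]
        X = ds.X.copy()
        X[1] = 0.82 * (C[1] @ S) + 0.07
        twin = SpectralDataset(ds.wavelengths, X, ds.sample_ids, ds.y)
        model = ss_fit(twin, mccv=MCCVConfig(n_repeats=10, seed=4), max_lvs=8)
        out = ss_apply(twin, model)
        assert np.max(np.abs(out.X[0] - out.X[1])) <= 5 * 1e-5 + 1e-6

    def test_determinism_and_serialization(self, fitted, tmp_path):
        ds, _, model = fitted
        again = ss_fit(ds, mccv=MCCVConfig(n_repeats=15, seed=2), max_lvs=8)
        assert again.reference_wavelength_index == model.reference_wavelength_index
        assert np.allclose(again.rmsecv_trace, model.rmsecv_trace,
                           equal_nan=True)
        path = tmp_path / "ss.json"
        model.to_json(path)
        loaded = type(model).from_json(path)
        out1 = ss_apply(ds, model)
        out2 = ss_apply(ds, loaded)
        assert np.allclose(out1.X, out2.X, atol=1e-12)

    def test_missing_y_rejected(self):
        ds, _ = _ss_mixture()
        no_y = SpectralDataset(ds.wavelengths, ds.X, ds.sample_ids, None)
        with pytest.raises(ValueError, match="y"):
            ss_fit(no_y)
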