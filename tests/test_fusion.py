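import numpy as np
import pytest

from specfuse.crossval import MCCVConfig
from specfuse.evaluation import evaluate
from specfuse.fusion import (FusionModel, MemberSpec, build_cncmf, build_mcmf,
                             fit_stack_mlr, fuse_bg, fuse_sa)
from specfuse.regressors import fit_plsr
from specfuse.selection import SelectionConfig, cars_select
from specfuse.simulate import MixtureModelParams, simulate_dataset
from specfuse.io import SpectralDataset


class TestCombinerPrimitives:
    def test_sa_is_rowwise_mean(self):
        assert fuse_sa(np.array([[1.0, 2.0, 3.0]])) == pytest.approx(2.0)
        P = np.tile(np.array([[5.0], [7.0]]), (1, 3))
        assert np.allclose(fuse_sa(P), [5.0, 7.0])

    def test_sa_equals_bg_under_equal_variances(self):
        rng = np.random.default_rng(0)
        P = rng.random((10, 3))
        fused, w = fuse_bg(P, [2.0, 2.0, 2.0])
        assert np.allclose(w, 1 / 3)
        assert np.allclose(fused, fuse_sa(P))

    def test_bg_hand_normalized_weights(self):
        """Variances (1, 2, 4) -> weights (4/7, 2/7, 1/7)."""
        _, w = fuse_bg(np.zeros((2, 3)), [1.0, 2.0, 4.0])
        assert np.allclose(np.round(w, 4), [0.5714, 0.2857, 0.1429])

    def test_bg_scale_invariance_and_positivity(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0.1, 3.0, 4)
        _, w1 = fuse_bg(np.zeros((1, 4)), v)
        _, w2 = fuse_bg(np.zeros((1, 4)), 2.0 * v)
        assert np.allclose(w1, w2)
        assert np.all(w1 >= 0) and w1.sum() == pytest.approx(1.0)
        with pytest.raises(ValueError, match="positive"):
            fuse_bg(np.zeros((1, 2)), [1.0, 0.0])


class TestMLRStack:
    def test_exact_predictor_recovered(self):
        rng = np.random.default_rng(2)
        y = rng.random(50)
        P = np.column_stack([y, rng.random(50), rng.random(50)])
        coef, intercept = fit_stack_mlr(P, y)
        assert np.allclose(coef, [1.0, 0.0, 0.0], atol=1e-6)
        assert abs(intercept) < 1e-6

    def test_single_member_matches_simple_regression(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 3.9, 6.2, 8.1, 9.8])
        coef, intercept = fit_stack_mlr(x[:, None], y)
        slope = np.cov(x, y, bias=True)[0, 1] / np.var(x)
        assert coef[0] == pytest.approx(slope)
        assert intercept == pytest.approx(y.mean() - slope * x.mean())

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        P = rng.random((30, 3))
        y = rng.random(30)
        coef, intercept = fit_stack_mlr(P, y)
        D = np.column_stack([P, np.ones(30)])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        assert np.allclose(np.append(coef, intercept), beta, atol=1e-9)

    def test_collinear_members_rejected(self):
        rng = np.random.default_rng(4)
        a = rng.random(20)
        with pytest.raises(ValueError, match="collinear"):
            fit_stack_mlr(np.column_stack([a, a]), rng.random(20))


@pytest.fixture(scope="module")
def fusion_data():
    params = MixtureModelParams(n_samples=60,
                                wavelengths=np.arange(600.0, 701.0, 2.0),
                                noise_sd=1e-3, seed=21)
    ds, _ = simulate_dataset(params)
    from specfuse.evaluation import SplitSpec, split_dataset
    cal, pred = split_dataset(ds, SplitSpec(seed=21))
    cars = cars_select(cal.X, cal.y, SelectionConfig(seed=21, n_runs=40,
                                                     max_lvs=8))
    return cal, pred, cars


class TestMCMF:
    def test_identical_members_sa_is_identity(self, fusion_data):
        cal, pred, cars = fusion_data
        sel = {"CARS": cars, "BOSS": cars, "iVISSA": cars}
        fm, preds = build_mcmf(cal, pred, sel, combiner="sa", seed=1,
                               max_lvs=8)
        member = fm.members[0].predict(pred.X)
        assert np.allclose(preds, member, atol=1e-9)

    def test_member_ordering_and_labels(self, fusion_data):
        cal, pred, cars = fusion_data
        sel = {"CARS": cars, "BOSS": cars, "iVISSA": cars}
        fm, _ = build_mcmf(cal, pred, sel, combiner="sa", seed=1, max_lvs=8)
        assert [m.label for m in fm.members] == ["f1", "f2", "f3"]
        assert [m.provenance for m in fm.members] == ["CARS", "BOSS", "iVISSA"]

    def test_mlr_fusion_never_worse_in_calibration(self, fusion_data):
        cal, pred, cars = fusion_data
        comp = np.setdiff1d(np.arange(cal.n_wavelengths), cars.selected)
        sel = {"CARS": cars, "BOSS": comp[: comp.size // 2],
               "iVISSA": comp[comp.size // 2:]}
        fm, _ = build_mcmf(cal, pred, sel, combiner="mlr", seed=2, max_lvs=8)
        fused_rmse = np.sqrt(np.mean((fm.predict(cal.X) - cal.y) ** 2))
        member_rmse = [np.sqrt(np.mean((m.predict(cal.X) - cal.y) ** 2))
                       for m in fm.members]
        assert fused_rmse <= min(member_rmse) + 1e-9

    def test_affine_shift_propagates_through_sa_bg(self):
        rng = np.random.default_rng(5)
        P = rng.random((15, 3))
        shift = 1.7
        assert np.allclose(fuse_sa(P + shift), fuse_sa(P) + shift)
        fused, w = fuse_bg(P, [1.0, 2.0, 3.0])
        fused_s, _ = fuse_bg(P + shift, [1.0, 2.0, 3.0])
        assert np.allclose(fused_s, fused + shift)

    def test_missing_selector_rejected(self, fusion_data):
        cal, pred, cars = fusion_data
        with pytest.raises(ValueError, match="BOSS"):
            build_mcmf(cal, pred, {"CARS": cars, "iVISSA": cars},
                       combiner="sa")


class TestCNCMF:
    def test_subsets_disjoint_and_exhaustive(self, fusion_data):
        cal, pred, cars = fusion_data
        fm, _ = build_cncmf(cal, pred, cars, combiner="sa", seed=3, max_lvs=8)
        a = set(fm.members[0].wavelength_subset.tolist())
        b = set(fm.members[1].wavelength_subset.tolist())
        assert not a & b
        assert a | b == set(range(cal.n_wavelengths))
        assert [m.label for m in fm.members] == ["f4", "f5"]

    def test_sa_is_halved_sum(self, fusion_data):
        cal, pred, cars = fusion_data
        fm, preds = build_cncmf(cal, pred, cars, combiner="sa", seed=3,
                                max_lvs=8)
        f4 = fm.members[0].predict(pred.X)
        f5 = fm.members[1].predict(pred.X)
        assert np.allclose(preds, (f4 + f5) / 2, atol=1e-12)
        assert fm.factor_string() == "(f4 + f5)/2"

    def test_full_subset_rejected(self, fusion_data):
        cal, pred, _ = fusion_data
        with pytest.raises(ValueError, match="complement"):
            build_cncmf(cal, pred, np.arange(cal.n_wavelengths), combiner="sa")

    def test_weak_complement_still_helps_mlr_calibration(self):
        """All signal inside the selected subset: the complement member is
        worse on prediction, yet MLR stacking cannot hurt calibration."""
        rng = np.random.default_rng(9)
        n, p = 60, 40
        X = rng.standard_normal((n, p))
        y = X[:, 5] + 0.5 * X[:, 10] + 0.05 * rng.standard_normal(n)
        ds = SpectralDataset(np.arange(600.0, 600.0 + p), X, y=y)
        from specfuse.evaluation import SplitSpec, split_dataset
        cal, pred = split_dataset(ds, SplitSpec(seed=4))
        subset = np.array([5, 10])
        fm, _ = build_cncmf(cal, pred, subset, combiner="mlr", seed=4,
                            max_lvs=5)
        f4_rmsep = np.sqrt(np.mean((fm.members[0].predict(pred.X) - pred.y) ** 2))
        f5_rmsep = np.sqrt(np.mean((fm.members[1].predict(pred.X) - pred.y) ** 2))
        assert f5_rmsep > f4_rmsep
        fused_rmsec = np.sqrt(np.mean((fm.predict(cal.X) - cal.y) ** 2))
        f4_rmsec = np.sqrt(np.mean((fm.members[0].predict(cal.X) - cal.y) ** 2))
        assert fused_rmsec <= f4_rmsec + 1e-9


class TestFusionModelInvariants:
    def _member(self, label, cols, X, y):
        model = fit_plsr(X[:, cols], y, n_lvs=2)
        return MemberSpec(label, np.asarray(cols), model)

    def test_duplicate_labels_rejected(self):
        rng = np.random.default_rng(6)
        X, y = rng.random((20, 6)), rng.random(20)
        m = self._member("f1", [0, 1], X, y)
        with pytest.raises(ValueError, match="unique"):
            FusionModel([m, m], combiner="sa")

    def test_cncmf_overlap_rejected(self):
        rng = np.random.default_rng(7)
        X, y = rng.random((20, 6)), rng.random(20)
        m1 = self._member("f4", [0, 1, 2], X, y)
        m2 = self._member("f5", [2, 3, 4], X, y)
        with pytest.raises(ValueError, match="disjoint"):
            FusionModel([m1, m2], combiner="sa", topology="CNCMF")

    def test_prediction_length_matches_input(self, fusion_data):
        cal, pred, cars = fusion_data
        fm, preds = build_cncmf(cal, pred, cars, combiner="bg", seed=8,
                                max_lvs=8)
        assert preds.shape == (pred.n_samples,)
        assert fm.predict(cal.X).shape == (cal.n_samples,)
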