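"""Feature screening: phi, PPV filter, trapezoidal ROC, backward elimination."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from mps2screen import (
    feature_ppv,
    feature_ppvs,
    learning_curve,
    phi,
    phi_matrix,
    ppv_filter,
    recursive_backward_elimination,
    roc_auc_importance,
    trapezoidal_auc,
)
from mps2screen.features import cross_validate_nbc, stratified_folds
from mps2screen.reference import REPORTED_FEATURE_PPV

from conftest import make_training


class TestPhi:
    def test_perfect_agreement(self):
        a = np.array([0, 1, 0, 1, 1])
        assert phi(a, a) == pytest.approx(1.0)

    def test_perfect_disagreement(self):
        a = np.array([0, 1, 0, 1])
        assert phi(a, 1 - a) == pytest.approx(-1.0)

    def test_constant_vector_undefined(self):
        assert math.isnan(phi(np.zeros(4, dtype=int), np.array([0, 1, 0, 1])))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            phi(np.array([0, 1]), np.array([0, 1, 0]))

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        pairs=st.lists(
            st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=2, max_size=40
        )
    )
    def test_equals_pearson_on_binary(self, pairs):
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        if a.min() == a.max() or b.min() == b.max():
            assert math.isnan(phi(a, b))
        else:
            pearson = np.corrcoef(a, b)[0, 1]
            assert phi(a, b) == pytest.approx(pearson, abs=1e-12)

    def test_matrix_symmetric_unit_diagonal(self, rng):
        X = pd.DataFrame(rng.integers(0, 2, size=(30, 4)), columns=list("abcd"))
        M = phi_matrix(X)
        assert np.allclose(M, M.T, equal_nan=True)
        assert (np.diag(M) == 1).all()
        vals = M.to_numpy()
        assert np.nanmax(np.abs(vals)) <= 1 + 1e-12


class TestFeaturePPV:
    def _ts(self, x, y):
        return make_training(pd.DataFrame({"Joint": x}), y)

    def test_only_in_positives(self):
        ts = self._ts([1, 1, 0, 0], [1, 1, 0, 0])
        assert feature_ppv(ts, "Joint") == 1.0

    def test_only_in_negatives(self):
        ts = self._ts([0, 0, 1, 1], [1, 1, 0, 0])
        assert feature_ppv(ts, "Joint") == 0.0

    def test_two_of_three_carriers(self):
        ts = self._ts([1, 1, 1, 0], [1, 1, 0, 0])
        assert feature_ppv(ts, "Joint") == pytest.approx(2 / 3)

    def test_no_carriers_undefined(self):
        ts = self._ts([0, 0, 0, 0], [1, 1, 0, 0])
        assert math.isnan(feature_ppv(ts, "Joint"))

    def test_unknown_feature_rejected(self):
        ts = self._ts([1, 0, 1, 0], [1, 1, 0, 0])
        with pytest.raises(ValueError):
            feature_ppv(ts, "NotASymptom")


class TestPPVFilter:
    def test_published_column_keeps_18(self):
        kept = ppv_filter(REPORTED_FEATURE_PPV, cutoff=0.15)
        assert len(kept) == 18
        assert "Pneumonia" not in kept and "Bladder" not in kept
        # features exactly at the cutoff are retained
        for f in ("SpinalInjury", "Vision", "Seizure"):
            assert f in kept

    def test_cutoff_zero_keeps_all(self):
        assert len(ppv_filter(REPORTED_FEATURE_PPV, cutoff=0.0)) == 20

    def test_cutoff_one_rejected(self):
        with pytest.raises(ValueError):
            ppv_filter(REPORTED_FEATURE_PPV, cutoff=1.0)

    def test_order_invariant(self):
        items = list(REPORTED_FEATURE_PPV.items())
        shuffled = dict(reversed(items))
        assert set(ppv_filter(REPORTED_FEATURE_PPV, 0.15)) == set(
            ppv_filter(shuffled, 0.15)
        )

    def test_nan_ppv_removed(self):
        assert ppv_filter({"a": math.nan, "b": 0.5}, 0.15) == ["b"]


class TestTrapezoidalAUC:
    def test_perfect_separator(self):
        y = np.array([0, 0, 1, 1])
        assert trapezoidal_auc(y, y) == pytest.approx(1.0)
        assert roc_auc_importance(y, y) == pytest.approx(1.0)

    def test_independent_feature_near_half(self, rng):
        n = 20_000
        y = rng.integers(0, 2, size=n)
        x = rng.integers(0, 2, size=n)
        assert trapezoidal_auc(x, y) == pytest.approx(0.5, abs=0.02)

    def test_importance_folds_below_half(self):
        y = np.array([0, 0, 1, 1])
        x = 1 - y  # anti-predictive
        assert trapezoidal_auc(x, y) == pytest.approx(0.0)
        assert roc_auc_importance(x, y) == pytest.approx(1.0)

    def test_binary_reduces_to_mean_sens_spec(self, rng):
        y = np.array([1] * 30 + [0] * 70)
        x = np.concatenate([rng.integers(0, 2, 30), rng.integers(0, 2, 70)])
        sens = x[y == 1].mean()
        spec = 1 - x[y == 0].mean()
        assert trapezoidal_auc(x, y) == pytest.approx((sens + spec) / 2)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.data())
    def test_equals_rank_statistic(self, data):
        n = data.draw(st.integers(4, 40))
        x = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        y = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        n1, n0 = (y == 1).sum(), (y == 0).sum()
        if n1 == 0 or n0 == 0:
            with pytest.raises(ValueError):
                trapezoidal_auc(x, y)
            return
        u = mannwhitneyu(x[y == 1], x[y == 0], alternative="two-sided").statistic
        assert trapezoidal_auc(x, y) == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_matches_sklearn(self, rng):
        y = rng.integers(0, 2, size=500)
        x = rng.integers(0, 2, size=500)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert trapezoidal_auc(x, y) == pytest.approx(roc_auc_score(y, x), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            trapezoidal_auc(np.array([0, 1]), np.array([1, 1]))


class TestCrossValidation:
    def test_stratified_folds_cover_all(self, rng):
        y = np.array([0] * 80 + [1] * 20)
        folds = stratified_folds(y, 10, rng)
        assert sorted(np.concatenate(folds)) == list(range(100))
        for f in folds:
            assert (y[f] == 1).sum() == 2  # 20 positives over 10 folds

    def test_separable_data_perfect_accuracy(self, rng):
        y = np.array([0] * 30 + [1] * 30)
        ts = make_training(pd.DataFrame({"Hearing": y}), y).restrict(["Hearing"])
        res = cross_validate_nbc(ts, k=5, replicates=2, seed=1)
        assert res.accuracy_mean == pytest.approx(1.0)
        assert res.kappa_mean == pytest.approx(1.0)


class TestBackwardElimination:
    def _noisy_ts(self, rng, n=60):
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        X = pd.DataFrame(
            {
                "Hearing": y,  # equals the label
                "Joint": rng.integers(0, 2, size=n),
                "Apnea": rng.integers(0, 2, size=n),
                "Skin": rng.integers(0, 2, size=n),
            }
        )
        return make_training(X, y).restrict(["Hearing", "Joint", "Apnea", "Skin"])

    def test_informative_feature_survives(self, rng):
        report = recursive_backward_elimination(
            self._noisy_ts(rng), k=5, replicates=2, seed=3
        )
        final = report.path[-1].features
        assert final == ("Hearing",)
        assert "Hearing" in report.best_features

    def test_path_sizes_strictly_decrease(self, rng):
        report = recursive_backward_elimination(
            self._noisy_ts(rng), k=5, replicates=2, seed=3
        )
        sizes = [len(s.features) for s in report.path]
        assert sizes == list(range(4, 0, -1))
        for step in report.path:
            assert step.accuracy_sd >= 0
            assert 0 <= step.accuracy_mean <= 1

    def test_deterministic(self, rng):
        ts = self._noisy_ts(rng)
        a = recursive_backward_elimination(ts, k=5, replicates=2, seed=9)
        b = recursive_backward_elimination(ts, k=5, replicates=2, seed=9)
        assert a.path_records() == b.path_records()
        assert a.best_features == b.best_features

    def test_leave_one_out_boundary(self):
        y = np.array([0, 1] * 6)
        X = pd.DataFrame({"Hearing": y, "Joint": [0, 1, 0, 0, 1, 1] * 2})
        ts = make_training(X, y).restrict(["Hearing", "Joint"])
        report = recursive_backward_elimination(ts, k=12, replicates=1, seed=1)
        for step in report.path:
            assert 0 <= step.accuracy_mean <= 1

    def test_k_exceeding_n_rejected(self, rng):
        ts = self._noisy_ts(rng, n=10)
        with pytest.raises(ValueError):
            recursive_backward_elimination(ts, k=20, replicates=1, seed=1)


class TestLearningCurve:
    def _ts(self, rng, n=80):
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        X = pd.DataFrame({"Hearing": y, "Joint": rng.integers(0, 2, n)})
        return make_training(X, y).restrict(["Hearing", "Joint"])

    def test_full_pool_point_matches_direct_cv(self, rng):
        ts = self._ts(rng)
        curve = learning_curve(ts, sizes=[80], k=5, replicates=2, seed=4)
        direct = cross_validate_nbc(ts, k=5, replicates=2, seed=4)
        assert curve.loc[0, "accuracy_mean"] == pytest.approx(direct.accuracy_mean)

    def test_accuracy_grows_on_separable_data(self, rng):
        ts = self._ts(rng)
        curve = learning_curve(ts, sizes=[20, 40, 80], k=5, replicates=2, seed=4)
        accs = curve["accuracy_mean"].to_numpy()
        sds = curve["accuracy_sd"].to_numpy()
        assert accs[-1] >= accs[0] - 2 * max(sds[0], 1e-9)

    def test_size_below_k_rejected(self, rng):
        with pytest.raises(ValueError):
            learning_curve(self._ts(rng), sizes=[3], k=5, seed=1)

    def test_reproducible(self, rng):
        ts = self._ts(rng)
        a = learning_curve(ts, sizes=[40, 80], k=5, replicates=2, seed=6)
        b = learning_curve(ts, sizes=[40, 80], k=5, replicates=2, seed=6)
        pd.testing.assert_frame_equal(a, b)


class TestOnStudyDesign:
    def test_ppvs_defined_for_all_attributes(self, study_design_training):
        ppvs = feature_ppvs(study_design_training)
        assert len(ppvs) == 20
        # age and the high-frequency symptoms must be strongly predictive
        assert ppvs["Hearing"] > 0.5

    def test_hearing_in_top_importance(self, study_design_training):
        # hearing loss carries one of the highest published frequencies, so
        # its ROC importance must rank in the top 4 on regenerated data
        ts = study_design_training
        imp = {
            f: roc_auc_importance(ts.X[f].to_numpy(), ts.y)
            for f in ts.feature_names
        }
        top4 = sorted(imp, key=imp.get, reverse=True)[:4]
        assert "Hearing" in top4
        assert imp["Hearing"] > 0.9
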