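"""NIPALS PLS, LOOCV and calibration/validation statistics."""

import numpy as np
import pytest

from aquaspec import (
    NipalsPls,
    SpectraSet,
    calibration_stats,
    loocv,
    regression_vector,
    split_by_plant,
    validation_stats,
)

from conftest import make_meta


def brute_force_loo_secv(X, y, max_lv):
    """Independent LOO oracle: refit a fresh model per (sample, LV count)."""
    n = X.shape[0]
    secv = np.zeros(max_lv)
    for k in range(1, max_lv + 1):
        errs = []
        for i in range(n):
            keep = np.arange(n) != i
            m = NipalsPls(n_components=k).fit(X[keep], y[keep])
            errs.append(m.predict(X[i][None, :])[0] - y[i])
        secv[k - 1] = np.sqrt(np.mean(np.square(errs)))
    return secv


class TestFit:
    def test_rank_one_problem_is_exact(self, rng):
        w = rng.normal(size=8)
        t = rng.normal(size=20)
        X = np.outer(t, w)
        y = X @ w
        m = NipalsPls(n_components=1).fit(X, y)
        np.testing.assert_allclose(m.predict(X), y, atol=1e-10)

    def test_full_rank_equals_ols(self, rng):
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        m = NipalsPls(n_components=6).fit(X, y)
        Xc = X - X.mean(axis=0)
        b_ols = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(m.coef_, b_ols, atol=1e-8)
        yhat_ols = Xc @ b_ols + y.mean()
        np.testing.assert_allclose(m.predict(X), yhat_ols, atol=1e-8)

    def test_shifting_y_shifts_predictions(self, rng):
        X = rng.normal(size=(15, 10))
        y = rng.normal(size=15)
        m0 = NipalsPls(n_components=3).fit(X, y)
        m1 = NipalsPls(n_components=3).fit(X, y + 5.0)
        np.testing.assert_allclose(m1.predict(X), m0.predict(X) + 5.0, atol=1e-10)

    def test_matches_sklearn_nipals(self, rng):
        """Independent cross-check against scikit-learn's PLS implementation."""
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(30, 12))
        y = X @ rng.normal(size=12) + rng.normal(0, 0.1, size=30)
        ours = NipalsPls(n_components=4).fit(X, y)
        theirs = PLSRegression(n_components=4, scale=False).fit(X, y)
        np.testing.assert_allclose(ours.coef_, theirs.coef_.ravel(), atol=1e-8)

    def test_zero_variance_y_rejected(self, rng):
        X = rng.normal(size=(10, 5))
        with pytest.raises(ValueError, match="variance"):
            NipalsPls(n_components=2).fit(X, np.ones(10))

    def test_too_many_components_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="n_components"):
            NipalsPls(n_components=5).fit(X, rng.normal(size=5))

    def test_json_roundtrip(self, rng, tmp_path):
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        m = NipalsPls(n_components=3).fit(X, y)
        m.save(tmp_path / "m.json")
        back = NipalsPls.load(tmp_path / "m.json")
        np.testing.assert_allclose(back.predict(X), m.predict(X), atol=1e-12)


class TestPredict:
    def test_mean_input_predicts_mean_response(self, rng):
        X = rng.normal(size=(15, 8))
        y = rng.normal(size=15)
        m = NipalsPls(n_components=3).fit(X, y)
        assert m.predict(X.mean(axis=0)[None, :])[0] == pytest.approx(y.mean())

    def test_row_permutation_permutes_predictions(self, rng):
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        m = NipalsPls(n_components=2).fit(X, y)
        perm = rng.permutation(10)
        np.testing.assert_allclose(m.predict(X[perm]), m.predict(X)[perm], atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        m = NipalsPls(n_components=2).fit(rng.normal(size=(10, 6)), rng.normal(size=10))
        with pytest.raises(ValueError, match="channels"):
            m.predict(np.zeros((2, 5)))


class TestLoocv:
    def test_matches_brute_force_oracle(self, rng):
        X = rng.normal(size=(12, 7))
        y = X @ rng.normal(size=7) + rng.normal(0, 0.5, size=12)
        cv = loocv(X, y, max_lv=4)
        oracle = brute_force_loo_secv(X, y, 4)
        np.testing.assert_allclose(cv.secv_by_lv, oracle, atol=1e-10)

    def test_chosen_lv_is_first_minimum(self, rng):
        X = rng.normal(size=(14, 6))
        y = X[:, 0] + rng.normal(0, 0.1, size=14)
        cv = loocv(X, y, max_lv=4)
        assert cv.chosen_lv == int(np.argmin(cv.secv_by_lv)) + 1

    def test_duplicated_rows_shrink_loo_error(self, rng):
        """Duplicating every sample leaks the held-out row into training,
        pulling SECV down toward the calibration error."""
        X = rng.normal(size=(10, 5))
        y = X @ rng.normal(size=5) + rng.normal(0, 1.0, size=10)
        base = loocv(X, y, max_lv=3)
        dup = loocv(np.vstack([X, X]), np.r_[y, y], max_lv=3)
        assert dup.secv_by_lv[-1] < base.secv_by_lv[-1]

    def test_pure_noise_has_no_loo_skill(self):
        rng = np.random.default_rng(2024)
        ok = 0
        for _ in range(50):
            X = rng.normal(size=(40, 10))
            y = rng.normal(size=40)
            cv = loocv(X, y, max_lv=5)
            ok += bool(np.all(cv.secv_by_lv >= 0.9 * y.std()))
        assert ok >= 48

    def test_degenerate_sizes_rejected(self, rng):
        X = rng.normal(size=(4, 3))
        y = rng.normal(size=4)
        with pytest.raises(ValueError):
            loocv(X, y, max_lv=3)


class TestStats:
    def test_perfect_predictions(self, rng):
        X = rng.normal(size=(10, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        m = NipalsPls(n_components=3).fit(X, y)
        sec, rcal = calibration_stats(m, X, y)
        sep, rval = validation_stats(m, X, y)
        assert sec == pytest.approx(0.0, abs=1e-8)
        assert sep == pytest.approx(0.0, abs=1e-8)
        assert rcal == pytest.approx(1.0)
        assert rval == pytest.approx(1.0)

    def test_constant_bias_gives_sep_abs_c(self, rng):
        X = rng.normal(size=(10, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        m = NipalsPls(n_components=3).fit(X, y)
        sep, rval = validation_stats(m, X, y - 3.0)  # predictions = reference + 3
        assert sep == pytest.approx(3.0, abs=1e-8)
        assert rval == pytest.approx(1.0)

    def test_hand_computed_four_sample_case(self):
        """Residuals (1, -1, 2, -2) with a 1-LV model:
        SEC = sqrt(10 / (4-1-1)) = sqrt(5); SEP = sqrt(10/4)."""
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = y + np.array([1.0, -1.0, 2.0, -2.0])

        class _Stub:
            n_components_ = 1
            def predict(self, X, n_components=None):
                return yhat

        sec, _ = calibration_stats(_Stub(), None, y)
        sep, _ = validation_stats(_Stub(), None, y)
        assert sec == pytest.approx(np.sqrt(5.0))
        assert sep == pytest.approx(np.sqrt(2.5))

    def test_sec_needs_enough_samples(self, rng):
        X = rng.normal(size=(4, 3))
        y = rng.normal(size=4)
        m = NipalsPls(n_components=3).fit(X, y)
        with pytest.raises(ValueError, match="SEC"):
            calibration_stats(m, X, y)


class TestRegressionVector:
    def test_rank_one_vector_aligns_with_weights(self, rng):
        w = rng.normal(size=8)
        X = np.outer(rng.normal(size=20), w)
        y = X @ w
        m = NipalsPls(n_components=1).fit(X, y)
        b = regression_vector(m)
        cos = abs(b @ w) / (np.linalg.norm(b) * np.linalg.norm(w))
        assert cos > 1 - 1e-8

    def test_signal_band_localised(self, rng):
        """With y depending only on channels 10..14, the largest |b|
        coefficients stay inside that band (+-2 channels)."""
        X = rng.normal(size=(60, 30))
        y = X[:, 10:15].sum(axis=1) + rng.normal(0, 0.05, size=60)
        m = NipalsPls(n_components=3).fit(X, y)
        top = np.argsort(np.abs(m.coef_))[-5:]
        assert top.min() >= 8 and top.max() <= 16

    def test_invariant_to_row_permutation(self, rng):
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        perm = rng.permutation(20)
        b1 = NipalsPls(n_components=3).fit(X, y).coef_
        b2 = NipalsPls(n_components=3).fit(X[perm], y[perm]).coef_
        np.testing.assert_allclose(b1, b2, atol=1e-10)


class TestSplitByPlant:
    def _set(self, plant_ids, rng):
        n = len(plant_ids)
        meta = make_meta(n, plant_id=plant_ids)
        return SpectraSet(np.arange(1, 6.0), rng.normal(size=(n, 5)), meta)

    def test_default_split(self, rng):
        s = self._set(list(range(1, 11)), rng)
        cal, val = split_by_plant(s)
        assert sorted(cal.meta["plant_id"]) == [1, 2, 4, 5, 7, 8, 10]
        assert sorted(val.meta["plant_id"]) == [3, 6, 9]

    def test_empty_validation_warns(self, rng):
        s = self._set([1, 2, 3], rng)
        with pytest.warns(UserWarning, match="empty"):
            cal, val = split_by_plant(s, cal_ids=(1, 2, 3), val_ids=())
        assert val.n_measurements == 0

    def test_orphan_plant_rejected(self, rng):
        s = self._set(list(range(1, 12)), rng)
        with pytest.raises(ValueError, match="11"):
            split_by_plant(s)

    def test_overlapping_ids_rejected(self, rng):
        s = self._set([1, 2], rng)
        with pytest.raises(ValueError, match="overlap"):
            split_by_plant(s, cal_ids=(1, 2), val_ids=(2,))
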