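"""MSC, Savitzky–Golay second derivative and difference spectra."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aquaspec import (
    MscScatterCorrection,
    SpectraSet,
    difference_spectra,
    generate_spectra,
    group_mean,
    msc_correct,
    second_derivative,
    select_subset,
)
from aquaspec.preprocessing import SavitzkyGolayDerivative
from aquaspec.synthetic import StressSimConfig

from conftest import make_meta


def ols_oracle(x, ref):
    """Closed-form simple-regression fit of one spectrum on the reference."""
    n = ref.size
    sx, sy = ref.sum(), x.sum()
    sxx, sxy = (ref * ref).sum(), (ref * x).sum()
    b = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    a = (sy - b * sx) / n
    return a, b


class TestMsc:
    def test_exact_affine_model_recovered(self, rng):
        ref = rng.normal(0.5, 0.2, size=20)
        x = 0.5 + 2.0 * ref
        est = MscScatterCorrection(reference=ref).fit(x[None, :])
        corrected = est.transform(x[None, :])
        np.testing.assert_allclose(corrected[0], ref, atol=1e-12)
        assert est.intercept_[0] == pytest.approx(0.5)
        assert est.slope_[0] == pytest.approx(2.0)

    def test_identity_spectrum(self, rng):
        ref = rng.normal(0.5, 0.2, size=20)
        est = MscScatterCorrection(reference=ref).fit(ref[None, :])
        corrected = est.transform(ref[None, :])
        np.testing.assert_allclose(corrected[0], ref, atol=1e-12)
        assert est.intercept_[0] == pytest.approx(0.0, abs=1e-12)
        assert est.slope_[0] == pytest.approx(1.0)

    def test_matches_per_row_ols_oracle(self, rng):
        X = rng.normal(0.5, 0.1, size=(3, 10))
        est = MscScatterCorrection().fit(X)
        est.transform(X)
        ref = X.mean(axis=0)
        for i in range(3):
            a, b = ols_oracle(X[i], ref)
            assert est.intercept_[i] == pytest.approx(a, abs=1e-10)
            assert est.slope_[i] == pytest.approx(b, abs=1e-10)

    def test_idempotent_with_same_reference(self, rng):
        X = rng.normal(0.5, 0.1, size=(5, 30))
        est = MscScatterCorrection().fit(X)
        once = est.transform(X)
        twice = est.transform(once)
        np.testing.assert_allclose(twice, once, atol=1e-10)

    def test_removes_injected_affine_scatter(self, rng):
        signal = np.sin(np.linspace(0, 3, 50)) + 1.5
        a = rng.normal(0, 0.3, size=40)
        b = rng.lognormal(0, 0.2, size=40)
        noise_sd = 1e-3
        X = b[:, None] * signal + a[:, None] + rng.normal(0, noise_sd, (40, 50))
        corrected = MscScatterCorrection(reference=signal).fit(X).transform(X)
        between_row_rms = np.sqrt(corrected.var(axis=0).mean())
        assert between_row_rms <= 2 * noise_sd

    def test_degenerate_slope_rejected(self, rng):
        ref = rng.normal(0.5, 0.2, size=20)
        orthogonal = np.ones(20)  # zero covariance with any centred reference
        est = MscScatterCorrection(reference=ref).fit(ref[None, :])
        with pytest.raises(ValueError, match="row 0"):
            est.transform(orthogonal[None, :])

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            MscScatterCorrection(reference=np.ones(10)).fit(np.ones((2, 10)))

    def test_spectraset_wrapper_appends_log(self, small_set):
        out, coef = msc_correct(small_set)
        assert out.processing_log[-1] == "msc"
        assert small_set.processing_log == []
        assert coef.slope.shape == (3,)


class TestSecondDerivative:
    def test_exact_on_quadratic(self):
        wl = np.linspace(1000.0, 1124.0, 32)
        c2, c1, c0 = 3e-4, -0.2, 40.0
        y = c2 * wl**2 + c1 * wl + c0
        meta = make_meta(1)
        s = SpectraSet(wl, y[None, :], meta)
        out = second_derivative(s, window=11, polyorder=3, scale="per_nm")
        np.testing.assert_allclose(out.absorbance[0], 2 * c2, atol=1e-9)
        assert out.n_wavelengths == 32 - 10

    def test_constant_maps_to_zero(self):
        wl = np.linspace(1000.0, 1124.0, 32)
        s = SpectraSet(wl, np.full((1, 32), 0.7), make_meta(1))
        out = second_derivative(s)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-12)

    def test_gaussian_band_matches_analytic_derivative(self):
        # 1 nm channel spacing so the 11-channel window spans a small
        # fraction of the 30 nm band
        wl = np.arange(1100.0, 1501.0)
        A, mu, sig = 1.0, 1300.0, 30.0
        y = A * np.exp(-((wl - mu) ** 2) / (2 * sig**2))
        analytic = y * (((wl - mu) ** 2) / sig**4 - 1 / sig**2)
        s = SpectraSet(wl, y[None, :], make_meta(1))
        out = second_derivative(s, window=11, polyorder=3, scale="per_nm")
        inner = np.isin(wl, out.wavelengths)
        err = np.max(np.abs(out.absorbance[0] - analytic[inner]))
        p2p = analytic.max() - analytic.min()
        assert err < 0.01 * p2p

    def test_nonuniform_grid_rejected(self):
        wl = np.array([1000.0, 1001.0, 1003.0, 1007.0, 1015.0, 1031.0,
                       1063.0, 1127.0, 1255.0, 1256.0, 1257.0, 1258.0])
        s = SpectraSet(wl, np.ones((1, 12)), make_meta(1))
        with pytest.raises(ValueError, match="uniform"):
            second_derivative(s)

    def test_window_larger_than_grid_rejected(self):
        X = np.ones((1, 9))
        with pytest.raises(ValueError, match="window"):
            SavitzkyGolayDerivative(window=11).fit(X)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        alpha=st.floats(-3, 3, allow_nan=False),
        beta=st.floats(-3, 3, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    def test_linearity(self, alpha, beta, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 40))
        est = SavitzkyGolayDerivative(delta=2.0)
        mixed = est.fit(x[None, :]).transform((alpha * x + beta * y)[None, :])
        separate = alpha * est.transform(x[None, :]) + beta * est.transform(y[None, :])
        np.testing.assert_allclose(mixed, separate, atol=1e-10)


class TestDifferenceSpectra:
    def _daily_means(self, rows_by_day):
        days = sorted(rows_by_day)
        wl = np.arange(1.0, 1.0 + len(next(iter(rows_by_day.values()))))
        meta = make_meta(len(days), plant_id=[1] * len(days), day=days)
        mat = np.vstack([rows_by_day[d] for d in days])
        return SpectraSet(wl, mat, meta)

    def test_identical_days_give_zero(self):
        row = np.linspace(0, 1, 6)
        s = self._daily_means({0: row, 1: row, 2: row})
        out = difference_spectra(s, baseline_day=0)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-14)
        assert list(out.meta["day"]) == [1, 2]
        assert (out.meta["baseline_day"] == 0).all()

    def test_exact_delta_recovered(self):
        r0 = np.linspace(0, 1, 6)
        delta = np.full(6, 0.25)
        s = self._daily_means({0: r0, 1: r0 + delta})
        out = difference_spectra(s, baseline_day=0)
        np.testing.assert_allclose(out.absorbance[0], delta, atol=1e-14)

    def test_antisymmetric_under_baseline_swap(self):
        rng = np.random.default_rng(3)
        s = self._daily_means({0: rng.normal(size=6), 1: rng.normal(size=6)})
        fwd = difference_spectra(s, baseline_day=0)
        rev = difference_spectra(s, baseline_day=1)
        np.testing.assert_allclose(fwd.absorbance, -rev.absorbance, atol=1e-14)

    def test_missing_baseline_names_group(self):
        row = np.ones(6)
        wl = np.arange(1.0, 7.0)
        meta = make_meta(2, cultivar=["A", "B"], day=[0, 1])
        s = SpectraSet(wl, np.vstack([row, row]), meta)
        with pytest.raises(ValueError, match="B"):
            difference_spectra(s, baseline_day=0, keys=["cultivar"])

    def test_peak_change_channel_matches_generator(self):
        """At day 7 the largest |difference| sits on the strongest injected
        band trajectory (the free-water band) to within +-10 nm."""
        cfg = dataclasses.replace(
            StressSimConfig(), cultivars=("sensitive",), leaves=("first",), seed=11
        )
        s, _ = generate_spectra(cfg)
        stress = select_subset(s, treatment="stress")
        means = group_mean(stress, ["day"])
        out = difference_spectra(means, baseline_day=0)
        day7 = out.absorbance[out.meta["day"].to_numpy() == 7][0]
        peak_wl = out.wavelengths[np.argmax(np.abs(day7))]
        strongest = max(
            cfg.sensitive_slopes, key=lambda c: abs(cfg.sensitive_slopes[c])
        )
        assert abs(peak_wl - strongest) <= 10.0
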