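"""Scatter correction, derivative transformation and difference spectra.

Two scikit-learn style transformers operate on plain ``(n_samples,
n_channels)`` matrices:

* :class:`MscScatterCorrection` — multiplicative scatter correction: each
  spectrum x is regressed on a reference spectrum r by ordinary least
  squares, x ≈ a + b·r, and replaced by (x − a)/b.  This removes the
  per-measurement additive offset and multiplicative gain produced by
  varying leaf thickness and surface texture.
* :class:`SavitzkyGolayDerivative` — Savitzky–Golay second-derivative
  filter; resolves overlapping absorption bands and removes baseline and
  linear slope.  Edge channels where the window does not fit are dropped.

The module-level functions wrap these for :class:`~aquaspec.spectra.SpectraSet`
inputs and keep the processing log.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .spectra import SpectraSet, group_mean

_B_TINY = 1e-12


@dataclasses.dataclass
class MscCoefficients:
    """Per-measurement MSC fit: x_i ≈ intercept_i + slope_i · reference."""

    intercept: np.ndarray
    slope: np.ndarray
    reference: np.ndarray


class MscScatterCorrection(TransformerMixin, BaseEstimator):
    """Multiplicative scatter correction against a reference spectrum.

    Parameters
    ----------
    reference : ndarray of shape (n_channels,), optional
        Reference spectrum.  If None (default), the mean spectrum of the
        data seen by :meth:`fit` is used, computed once (not iterated).

    Attributes
    ----------
    reference_ : ndarray of shape (n_channels,)
        The reference actually used.
    intercept_, slope_ : ndarray of shape (n_samples,)
        OLS coefficients for the most recently transformed matrix.
    """

    def __init__(self, reference=None):
        self.reference = reference

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.reference is not None:
            ref = np.asarray(self.reference, dtype=float)
            if ref.shape != (X.shape[1],):
                raise ValueError("reference length must equal the channel count")
        else:
            if X.shape[0] < 2:
                raise ValueError(
                    "MSC needs >= 2 spectra to form a mean reference; "
                    "pass an explicit reference otherwise"
                )
            ref = X.mean(axis=0)
        if np.ptp(ref) < _B_TINY:
            raise ValueError("reference spectrum is constant; MSC slope undefined")
        self.reference_ = ref
        self.n_features_in_ = X.shape[1]
        return self

    def coefficients(self, X) -> MscCoefficients:
        """Closed-form per-row OLS fit of X against the fitted reference."""
        check_is_fitted(self, "reference_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        ref = self.reference_
        rc = ref - ref.mean()
        denom = rc @ rc
        slope = (X @ rc) / denom
        intercept = X.mean(axis=1) - slope * ref.mean()
        return MscCoefficients(intercept, slope, ref.copy())

    def transform(self, X):
        coef = self.coefficients(X)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        small = np.abs(coef.slope) < _B_TINY
        if small.any():
            row = int(np.argwhere(small)[0][0])
            raise ValueError(
                f"degenerate spectrum at row {row}: fitted MSC slope |b| < {_B_TINY}"
            )
        self.intercept_, self.slope_ = coef.intercept, coef.slope
        return (X - coef.intercept[:, None]) / coef.slope[:, None]


class SavitzkyGolayDerivative(TransformerMixin, BaseEstimator):
    """Savitzky–Golay derivative filter with edge-channel trimming.

    Parameters
    ----------
    window : odd int >= 5
        Filter window length in channels.
    polyorder : int >= 2
        Local polynomial order; must exceed ``deriv``.
    deriv : int
        Derivative order (2 by default — the transform used throughout).
    delta : float
        Channel spacing in nm; used when ``scale='per_nm'`` so output is
        d²A/dλ² in nm⁻².  Ignored for ``scale='per_channel'``.
    scale : {'per_nm', 'per_channel'}
    """

    def __init__(self, window=11, polyorder=3, deriv=2, delta=1.0, scale="per_nm"):
        self.window = window
        self.polyorder = polyorder
        self.deriv = deriv
        self.delta = delta
        self.scale = scale

    def _validate(self, n_channels):
        if self.window < 5 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 5")
        if self.polyorder < 2 or self.polyorder >= self.window:
            raise ValueError("need 2 <= polyorder < window")
        if self.deriv > self.polyorder:
            raise ValueError("deriv must not exceed polyorder")
        if self.scale not in ("per_nm", "per_channel"):
            raise ValueError(f"unknown scale: {self.scale!r}")
        if self.window >= n_channels:
            raise ValueError(
                f"window ({self.window}) must be smaller than the channel count ({n_channels})"
            )

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self._validate(X.shape[1])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self._validate(X.shape[1])
        delta = self.delta if self.scale == "per_nm" else 1.0
        out = savgol_filter(
            X, self.window, self.polyorder, deriv=self.deriv, delta=delta, axis=1
        )
        h = (self.window - 1) // 2
        return out[:, h:-h]

    @property
    def half_window_(self) -> int:
        return (self.window - 1) // 2


# ---------------------------------------------------------------------------
# SpectraSet-level wrappers
# ---------------------------------------------------------------------------

def msc_correct(s: SpectraSet, reference=None):
    """MSC-correct every spectrum of ``s``; returns (corrected, coefficients)."""
    est = MscScatterCorrection(reference=reference).fit(s.absorbance)
    corrected = est.transform(s.absorbance)
    coef = MscCoefficients(est.intercept_, est.slope_, est.reference_.copy())
    return s.with_matrix(corrected, log_entry="msc"), coef


def second_derivative(
    s: SpectraSet, window: int = 11, polyorder: int = 3, scale: str = "per_nm"
) -> SpectraSet:
    """Savitzky–Golay second derivative of every spectrum.

    Requires a uniform grid; the (window−1)/2 edge channels on each side
    are dropped from the output grid.
    """
    if not s.is_uniform_grid():
        raise ValueError(
            "second_derivative requires a uniform wavelength grid; resample first"
        )
    delta = float(s.wavelengths[1] - s.wavelengths[0])
    est = SavitzkyGolayDerivative(
        window=window, polyorder=polyorder, deriv=2, delta=delta, scale=scale
    )
    mat = est.fit(s.absorbance if s.n_measurements else np.zeros((1, s.n_wavelengths))).transform(
        s.absorbance if s.n_measurements else np.zeros((0, s.n_wavelengths))
    )
    h = est.half_window_
    return s.with_matrix(
        mat,
        wavelengths=s.wavelengths[h:-h].copy(),
        log_entry=f"sg2[window={window},polyorder={polyorder},scale={scale}]",
    )


def difference_spectra(
    s: SpectraSet, baseline_day: int, keys: Sequence[str] = ()
) -> SpectraSet:
    """Per-group day-minus-baseline difference spectra.

    ``s`` must already be group-averaged so that each (keys, day)
    combination occurs exactly once (see :func:`~aquaspec.spectra.group_mean`).
    For every key group and every day other than ``baseline_day`` the
    output row is ``mean(day) − mean(baseline_day)``; the metadata keeps
    the day and records the baseline in a ``baseline_day`` column.
    """
    keys = list(keys)
    if "day" not in s.meta.columns:
        raise ValueError("difference_spectra needs a 'day' metadata column")
    combo = keys + ["day"]
    if s.meta.duplicated(subset=combo).any():
        raise ValueError(
            "input must be group-averaged: duplicate (keys, day) combinations found"
        )
    rows, meta_rows = [], []
    if keys:
        grouped = s.meta.groupby(keys, sort=False).indices.items()
    else:
        grouped = [((), np.arange(s.n_measurements))]
    for key_vals, idx in grouped:
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        days = s.meta["day"].iloc[idx]
        base = idx[(days == baseline_day).to_numpy()]
        if len(base) == 0:
            raise ValueError(
                f"baseline day {baseline_day} missing in group {dict(zip(keys, key_vals))}"
            )
        base_row = s.absorbance[base[0]]
        for i in idx:
            day = int(s.meta["day"].iloc[i])
            if day == baseline_day:
                continue
            rows.append(s.absorbance[i] - base_row)
            meta_rows.append(dict(zip(keys, key_vals), day=day, baseline_day=baseline_day))
    meta = pd.DataFrame(
        meta_rows, columns=keys + ["day", "baseline_day"]
    )
    mat = np.vstack(rows) if rows else np.zeros((0, s.n_wavelengths))
    return s.with_matrix(
        mat, meta=meta, log_entry=f"difference[baseline_day={baseline_day}]"
    )
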