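"""Aquagram computation over water-matrix-coordinate (WAMAC) wavelengths.

An aquagram is a radar chart of normalised absorbance at a set of
characteristic water-absorption wavelengths in the first overtone region
(~1300–1600 nm).  For each coordinate λ the statistic is the plain z-score

    Aq_λ = (A_λ − μ_λ) / σ_λ

where A_λ is the MSC-corrected absorbance of one measurement and μ_λ, σ_λ
are the mean and (sample) standard deviation of all measurements in the
normalisation pool at that wavelength.  Group aquagram values are the
arithmetic means of the per-measurement z-scores within each group.

Two built-in coordinate schemes are provided: the 12 classic WAMACs of
the first-overtone water bands (free water, dimers, solvation shells and
water clusters with 1–4 hydrogen bonds) and an extended 7-coordinate set
emphasising strongly bound, polymer-associated water (1503–1571 nm).
Both are overridable: any custom (label, wavelength) list works.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .spectra import SpectraSet

#: classic first-overtone water coordinates (label, nm): c1–c12
CLASSIC12 = (
    ("c1", 1348.0),
    ("c2", 1360.0),
    ("c3", 1373.0),
    ("c4", 1385.0),
    ("c5", 1410.0),
    ("c6", 1422.0),
    ("c7", 1441.0),
    ("c8", 1453.0),
    ("c9", 1466.0),
    ("c10", 1478.0),
    ("c11", 1490.0),
    ("c12", 1503.0),
)

#: extended coordinates for strongly bound / polymer-associated water
EXTENDED7 = (
    ("e1", 1416.0),
    ("e2", 1447.0),
    ("e3", 1503.0),
    ("e4", 1521.0),
    ("e5", 1534.0),
    ("e6", 1551.0),
    ("e7", 1571.0),
)


@dataclasses.dataclass(frozen=True)
class WamacSet:
    """Named, ordered set of water-matrix coordinates."""

    name: str
    coordinates: tuple  # of (label, wavelength_nm)

    def __post_init__(self):
        wl = self.wavelengths
        if np.any(np.diff(wl) <= 0):
            raise ValueError("WAMAC wavelengths must be strictly increasing")

    @property
    def labels(self):
        return [lab for lab, _ in self.coordinates]

    @property
    def wavelengths(self) -> np.ndarray:
        return np.array([w for _, w in self.coordinates], dtype=float)

    def __len__(self):
        return len(self.coordinates)


def default_wamacs(scheme: str = "classic12") -> WamacSet:
    """Return a built-in WAMAC scheme: ``classic12`` or ``extended7``."""
    if scheme == "classic12":
        return WamacSet("classic12", CLASSIC12)
    if scheme == "extended7":
        return WamacSet("extended7", EXTENDED7)
    raise ValueError(f"unknown WAMAC scheme: {scheme!r}")


def custom_wamacs(coordinates, name: str = "custom") -> WamacSet:
    """Build a WamacSet from (label, nm) pairs or bare wavelengths."""
    coords = []
    for item in coordinates:
        if isinstance(item, (int, float)):
            coords.append((f"{float(item):g}", float(item)))
        else:
            lab, wl = item
            coords.append((str(lab), float(wl)))
    return WamacSet(name, tuple(coords))


def nearest_channel(wavelengths: np.ndarray, target_nm: float) -> int:
    """Index of the grid wavelength closest to ``target_nm``.

    Ties break toward the lower wavelength.  Targets outside the grid span
    by more than half the local spacing are rejected.
    """
    wl = np.asarray(wavelengths, dtype=float)
    half = float(np.mean(np.diff(wl))) / 2.0 if wl.size > 1 else 0.0
    if target_nm < wl[0] - half or target_nm > wl[-1] + half:
        raise ValueError(
            f"target {target_nm} nm outside grid span [{wl[0]}, {wl[-1]}] nm"
        )
    return int(np.argmin(np.abs(wl - target_nm)))


@dataclasses.dataclass
class AquagramResult:
    """Group-level aquagram values (radar-chart data)."""

    wamacs: WamacSet
    group_keys: list
    groups: pd.DataFrame            # one row of key values per group
    values: np.ndarray              # n_groups × n_coordinates z-score means
    counts: np.ndarray              # group sizes
    mu: np.ndarray                  # pooled mean per coordinate
    sigma: np.ndarray               # pooled sample sd per coordinate

    def to_frame(self) -> pd.DataFrame:
        """Long-form radar data: group, coordinate_label, wavelength_nm, value."""
        recs = []
        for g in range(len(self.groups)):
            label = "/".join(str(v) for v in self.groups.iloc[g].tolist())
            for (clab, wl), val in zip(self.wamacs.coordinates, self.values[g]):
                recs.append(
                    dict(
                        group=label,
                        coordinate_label=clab,
                        wavelength_nm=wl,
                        aquagram_value=val,
                    )
                )
        return pd.DataFrame(recs)


class AquagramScaler(TransformerMixin, BaseEstimator):
    """Pooled z-score transform at WAMAC wavelengths.

    ``fit`` stores the pooled mean and standard deviation of every
    coordinate over all samples (the normalisation pool); ``transform``
    maps a spectrum matrix to its per-coordinate z-scores.

    Parameters
    ----------
    wamacs : WamacSet, optional (default: classic12)
    wavelengths : ndarray, optional
        Grid of the input matrices; each coordinate is read from the
        nearest channel.  Required before fitting.
    ddof : int
        1 (default) for the sample standard deviation, 0 for population.
    """

    def __init__(self, wamacs=None, wavelengths=None, ddof=1):
        self.wamacs = wamacs
        self.wavelengths = wavelengths
        self.ddof = ddof

    def fit(self, X, y=None):
        if self.wavelengths is None:
            raise ValueError("wavelengths must be provided to locate WAMAC channels")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] < 2:
            raise ValueError("aquagram normalisation needs >= 2 measurements")
        wamacs = self.wamacs if self.wamacs is not None else default_wamacs()
        wl = np.asarray(self.wavelengths, dtype=float)
        idx = np.array([nearest_channel(wl, t) for t in wamacs.wavelengths])
        pool = X[:, idx]
        mu = pool.mean(axis=0)
        sigma = pool.std(axis=0, ddof=self.ddof)
        zero = sigma <= 0
        if zero.any():
            lab = wamacs.labels[int(np.argwhere(zero)[0][0])]
            raise ValueError(
                f"zero standard deviation at coordinate {lab}; aquagram undefined"
            )
        self.wamacs_ = wamacs
        self.channel_idx_ = idx
        self.mu_ = mu
        self.sigma_ = sigma
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mu_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X[:, self.channel_idx_] - self.mu_) / self.sigma_


def compute_aquagram(
    s: SpectraSet,
    wamacs: WamacSet | None = None,
    group_keys: Sequence[str] = ("treatment",),
    ddof: int = 1,
) -> AquagramResult:
    """Aquagram of ``s`` grouped by metadata fields.

    The normalisation pool is the *entire* set passed in — callers control
    the pool by pre-filtering (typically one cultivar × leaf).  The input
    is expected to be MSC-corrected; a warning is issued if the processing
    log does not record an ``msc`` step.
    """
    if not any(entry.startswith("msc") for entry in s.processing_log):
        warnings.warn(
            "aquagram input does not record an MSC step; Aq values assume "
            "scatter-corrected absorbances"
        )
    group_keys = list(group_keys)
    for k in group_keys:
        if k not in s.meta.columns:
            raise KeyError(f"unknown metadata field: {k!r}")
    scaler = AquagramScaler(wamacs=wamacs, wavelengths=s.wavelengths, ddof=ddof)
    z = scaler.fit(s.absorbance).transform(s.absorbance)
    grouped = s.meta.groupby(group_keys, sort=False)
    rows, meta_rows, counts = [], [], []
    for key_vals, idx in grouped.indices.items():
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        rows.append(z[idx].mean(axis=0))
        meta_rows.append(dict(zip(group_keys, key_vals)))
        counts.append(len(idx))
    return AquagramResult(
        wamacs=scaler.wamacs_,
        group_keys=group_keys,
        groups=pd.DataFrame(meta_rows),
        values=np.vstack(rows),
        counts=np.array(counts),
        mu=scaler.mu_,
        sigma=scaler.sigma_,
    )


def plot_aquagram(result: AquagramResult, ax=None):
    """Minimal radar-chart rendering of an :class:`AquagramResult`."""
    import matplotlib.pyplot as plt

    n = len(result.wamacs)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    if ax is None:
        _, ax = plt.subplots(subplot_kw=dict(polar=True))
    for g in range(len(result.groups)):
        label = "/".join(str(v) for v in result.groups.iloc[g].tolist())
        vals = result.values[g]
        ax.plot(np.r_[angles, angles[0]], np.r_[vals, vals[0]], label=label)
    ax.set_xticks(angles)
    ax.set_xticklabels([f"{w:g}" for w in result.wamacs.wavelengths], fontsize=7)
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize=7)
    return ax
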