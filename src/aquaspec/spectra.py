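"""Spectral data container and CSV I/O.

A :class:`SpectraSet` bundles a wavelength grid (nm), an absorbance matrix
(one row per measurement) and per-measurement experimental metadata
(cultivar, treatment, plant, leaf, day, replicate).  It is the currency
every other module consumes and produces.  Two plain-text dialects are
supported:

* ``wide_csv`` — metadata columns first, then one column per wavelength;
* ``long_csv`` — one row per (measurement, wavelength) pair.

Transform history is tracked in an append-only ``processing_log`` which is
serialised as ``#log:`` comment lines at the top of wide/long CSV files.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: canonical metadata columns of a raw measurement, in file order
META_COLUMNS = ["cultivar", "treatment", "plant_id", "leaf", "day", "replicate"]

TREATMENTS = ("control", "stress", "recovery")
LEAVES = ("cotyledon", "first", "second")

_LOG_PREFIX = "#log:"


class SpectraFormatError(ValueError):
    """Raised for malformed spectra files or inconsistent containers."""


@dataclasses.dataclass
class SpectraSet:
    """Absorbance spectra with aligned measurement metadata.

    Parameters
    ----------
    wavelengths : ndarray, shape (n_wavelengths,)
        Strictly increasing wavelength grid in nm.
    absorbance : ndarray, shape (n_measurements, n_wavelengths)
        Unitless absorbance, all values finite.
    meta : DataFrame, length n_measurements
        Any subset of :data:`META_COLUMNS`; raw sets carry all six.
    processing_log : list of str
        Append-only record of transforms applied (empty for raw data).
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    meta: pd.DataFrame
    processing_log: list = dataclasses.field(default_factory=list)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.absorbance.size == 0:
            self.absorbance = self.absorbance.reshape(0, self.wavelengths.size)
        self.meta = self.meta.reset_index(drop=True)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        wl = self.wavelengths
        if wl.ndim != 1 or wl.size == 0:
            raise SpectraFormatError("wavelength grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(wl)) or np.any(wl <= 0):
            raise SpectraFormatError("wavelengths must be finite and positive")
        if np.any(np.diff(wl) <= 0):
            raise SpectraFormatError("wavelengths must be strictly increasing")
        n, p = self.absorbance.shape
        if p != wl.size:
            raise SpectraFormatError(
                f"absorbance has {p} columns but grid has {wl.size} wavelengths"
            )
        if len(self.meta) != n:
            raise SpectraFormatError(
                f"metadata has {len(self.meta)} rows but matrix has {n}"
            )
        if n and not np.all(np.isfinite(self.absorbance)):
            raise SpectraFormatError("absorbance contains non-finite values")
        unknown = set(self.meta.columns) - set(META_COLUMNS) - {"baseline_day"}
        if unknown:
            raise SpectraFormatError(f"unknown metadata columns: {sorted(unknown)}")
        if "treatment" in self.meta.columns and n:
            bad = set(self.meta["treatment"].unique()) - set(TREATMENTS)
            if bad:
                raise SpectraFormatError(f"unknown treatments: {sorted(bad)}")
        if "leaf" in self.meta.columns and n:
            bad = set(self.meta["leaf"].unique()) - set(LEAVES)
            if bad:
                raise SpectraFormatError(f"unknown leaf types: {sorted(bad)}")
        if "day" in self.meta.columns and n and (self.meta["day"] < 0).any():
            raise SpectraFormatError("day must be >= 0")
        if n and self.meta.duplicated().any():
            dup = self.meta[self.meta.duplicated()].iloc[0].to_dict()
            raise SpectraFormatError(f"duplicate measurement key: {dup}")
        # recovery measurements must postdate the last stress day
        if {"treatment", "day"} <= set(self.meta.columns) and n:
            rec = self.meta.loc[self.meta["treatment"] == "recovery", "day"]
            stress = self.meta.loc[self.meta["treatment"] == "stress", "day"]
            if len(rec) and len(stress) and rec.min() <= stress.max():
                raise SpectraFormatError(
                    "recovery measurements must have day greater than the last stress day"
                )

    # -- convenience -----------------------------------------------------
    @property
    def n_measurements(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def copy(self) -> "SpectraSet":
        return SpectraSet(
            self.wavelengths.copy(),
            self.absorbance.copy(),
            self.meta.copy(),
            list(self.processing_log),
        )

    def with_matrix(
        self,
        absorbance: np.ndarray,
        *,
        wavelengths: np.ndarray | None = None,
        meta: pd.DataFrame | None = None,
        log_entry: str | None = None,
    ) -> "SpectraSet":
        """Derive a new set sharing this one's grid/metadata unless overridden."""
        log = list(self.processing_log)
        if log_entry is not None:
            log.append(log_entry)
        return SpectraSet(
            self.wavelengths.copy() if wavelengths is None else wavelengths,
            absorbance,
            self.meta.copy() if meta is None else meta,
            log,
        )

    def grid_spacing(self) -> float:
        """Mean channel spacing in nm (grids may be non-uniform)."""
        return float(np.mean(np.diff(self.wavelengths)))

    def is_uniform_grid(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.wavelengths)
        return bool(np.allclose(d, d[0], rtol=rtol, atol=0))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _read_log_lines(path) -> list:
    log = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(_LOG_PREFIX):
                log.append(line[len(_LOG_PREFIX):].strip())
            else:
                break
    return log


def read_spectra(path, dialect: str = "wide_csv") -> SpectraSet:
    """Read a :class:`SpectraSet` from a wide or long CSV file.

    Wide CSV: metadata columns first, then one column per wavelength (the
    header holds the wavelengths in nm).  Long CSV: columns
    ``...meta..., wavelength_nm, absorbance``.  ``#log:`` comment lines at
    the top of the file restore the processing log.
    """
    if dialect not in ("wide_csv", "long_csv"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    log = _read_log_lines(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraFormatError(f"missing metadata column(s): {missing}")

    if dialect == "wide_csv":
        wl_cols = [c for c in df.columns if c not in META_COLUMNS]
        try:
            wl = np.array([float(c) for c in wl_cols])
        except ValueError as e:
            raise SpectraFormatError(f"non-numeric wavelength column header: {e}")
        order = np.argsort(wl)
        if not np.all(order == np.arange(wl.size)):
            warnings.warn("wavelength columns were unsorted; sorting ascending")
        wl = wl[order]
        mat = df[wl_cols].to_numpy(dtype=float)[:, order]
        meta = df[META_COLUMNS].copy()
    else:
        for col in ("wavelength_nm", "absorbance"):
            if col not in df.columns:
                raise SpectraFormatError(f"missing column: {col}")
        if df.duplicated(subset=META_COLUMNS + ["wavelength_nm"]).any():
            raise SpectraFormatError("duplicate (measurement, wavelength) rows in long CSV")
        wl = np.sort(df["wavelength_nm"].unique().astype(float))
        pivot = df.pivot_table(
            index=META_COLUMNS, columns="wavelength_nm", values="absorbance",
            sort=False,
        )
        pivot = pivot.reindex(columns=wl)
        if pivot.isna().any().any():
            raise SpectraFormatError("long CSV is ragged: some (measurement, wavelength) cells missing")
        meta = pivot.index.to_frame(index=False)[META_COLUMNS]
        mat = pivot.to_numpy(dtype=float)

    bad = ~np.isfinite(mat)
    if bad.any():
        row = int(np.argwhere(bad)[0][0])
        raise SpectraFormatError(f"non-numeric/non-finite absorbance at measurement row {row}")
    return SpectraSet(wl, mat, meta, log)


def write_spectra(s: SpectraSet, path, dialect: str = "wide_csv") -> None:
    """Write ``s`` as CSV; numeric values keep >= 10 significant digits."""
    if dialect not in ("wide_csv", "long_csv"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    missing = [c for c in META_COLUMNS if c not in s.meta.columns]
    if missing:
        raise SpectraFormatError(
            f"cannot serialise a set lacking metadata column(s) {missing}"
        )
    with open(path, "w") as fh:
        for entry in s.processing_log:
            fh.write(f"{_LOG_PREFIX}{entry}\n")
        if dialect == "wide_csv":
            wide = pd.concat(
                [
                    s.meta[META_COLUMNS].reset_index(drop=True),
                    pd.DataFrame(
                        s.absorbance, columns=[f"{w:.12g}" for w in s.wavelengths]
                    ),
                ],
                axis=1,
            )
            wide.to_csv(fh, index=False, float_format="%.12g")
        else:
            n, p = s.absorbance.shape
            meta_rep = s.meta[META_COLUMNS].loc[
                s.meta.index.repeat(p)
            ].reset_index(drop=True)
            long = meta_rep.assign(
                wavelength_nm=np.tile(s.wavelengths, max(n, 0)),
                absorbance=s.absorbance.ravel(),
            )
            long.to_csv(fh, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# selection and aggregation
# ---------------------------------------------------------------------------

def select_subset(s: SpectraSet, predicate=None, **field_values) -> SpectraSet:
    """Rows whose metadata match; grid and processing log are untouched.

    ``field_values`` maps metadata fields to a scalar or an iterable of
    allowed values; multiple fields are combined conjunctively.  A callable
    ``predicate(meta) -> boolean mask`` may be given instead (or as well).
    """
    mask = np.ones(s.n_measurements, dtype=bool)
    for field, allowed in field_values.items():
        if field not in s.meta.columns:
            raise KeyError(f"unknown metadata field: {field!r}")
        if isinstance(allowed, (list, tuple, set, frozenset, np.ndarray, range)):
            mask &= s.meta[field].isin(list(allowed)).to_numpy()
        else:
            mask &= (s.meta[field] == allowed).to_numpy()
    if predicate is not None:
        mask &= np.asarray(predicate(s.meta), dtype=bool)
    return SpectraSet(
        s.wavelengths.copy(),
        s.absorbance[mask],
        s.meta.loc[mask].reset_index(drop=True),
        list(s.processing_log),
    )


def group_mean(s: SpectraSet, keys: Sequence[str]) -> SpectraSet:
    """Average spectra over groups of identical ``keys`` metadata.

    The result has one row per distinct key combination (first-appearance
    order); its metadata keeps only ``keys`` plus ``replicate`` set to the
    member count.  Weighted by member counts, the grand mean is conserved.
    """
    if s.n_measurements == 0:
        raise ValueError("cannot group-average an empty SpectraSet")
    keys = list(keys)
    for k in keys:
        if k not in s.meta.columns:
            raise KeyError(f"unknown metadata field: {k!r}")
    grouped = s.meta.groupby(keys, sort=False)
    rows, meta_rows = [], []
    for key_vals, idx in grouped.indices.items():
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        rows.append(s.absorbance[idx].mean(axis=0))
        meta_rows.append(dict(zip(keys, key_vals), replicate=len(idx)))
    meta = pd.DataFrame(meta_rows)
    return SpectraSet(
        s.wavelengths.copy(),
        np.vstack(rows),
        meta,
        list(s.processing_log) + [f"group_mean[{','.join(keys)}]"],
    )
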