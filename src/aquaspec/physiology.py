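"""Physiology and metabolomics computations.

Covers the non-spectral read-outs of a chilling-stress experiment:

* electrolyte leakage — conductivity before autoclaving (E1, membrane
  leakage) over conductivity after autoclaving (E2, total electrolytes),
  as a percentage: 100 · E1/E2.  An index of cell-membrane damage.
* gas-exchange summaries — mean ± sd of net photosynthesis rate (Pn),
  transpiration rate (E) and stomatal conductance (C) per cultivar ×
  treatment × day, with a two-sample t-test against the same-day control.
* metabolite fold changes — log2 of the condition-mean over control-mean
  concentration per metabolite (heat-map matrix), with per-cell t-tests
  and the conventional significance stars.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def star_code(p: float) -> str:
    """Conventional significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def electrolyte_leakage(e1, e2):
    """Electrolyte leakage percentage, 100 · E1/E2.

    E1 is the conductivity (µS/cm) of the incubation solution before
    autoclaving, E2 after autoclaving (complete electrolyte release).
    Values are in [0, 100] for physically consistent pairs; E1 > E2
    (instrument noise) yields a value above 100 with a warning.
    """
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if np.any(e2 <= 0):
        raise ValueError("E2 must be positive")
    if np.any(e1 < 0):
        raise ValueError("E1 must be non-negative")
    if np.any(e1 > e2):
        warnings.warn("E1 exceeds E2 for some samples; leakage > 100% returned")
    out = 100.0 * e1 / e2
    return float(out) if out.ndim == 0 else out


def ttest_vs_control(values, control, mode: str = "student"):
    """Two-sample t-test of a treatment group against its control.

    ``mode='student'`` (default) assumes equal variances; ``'welch'``
    does not.  Returns (t, two-sided p, star code).  Degenerate inputs
    (zero variance in both groups) give p = 1 for equal means and p = 0
    for unequal means.
    """
    x = np.asarray(values, dtype=float)
    c = np.asarray(control, dtype=float)
    if x.size < 2 or c.size < 2:
        raise ValueError("each group needs >= 2 replicates")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(c))):
        raise ValueError("inputs must be finite")
    if x.std(ddof=1) == 0 and c.std(ddof=1) == 0:
        if x.mean() == c.mean():
            return 0.0, 1.0, ""
        warnings.warn("zero variance with unequal means: degenerate t-test, p -> 0")
        return float(np.inf) * np.sign(x.mean() - c.mean()), 0.0, "***"
    if mode == "student":
        t, p = stats.ttest_ind(x, c, equal_var=True)
    elif mode == "welch":
        t, p = stats.ttest_ind(x, c, equal_var=False)
    else:
        raise ValueError(f"unknown t-test mode: {mode!r}")
    return float(t), float(p), star_code(float(p))


# ---------------------------------------------------------------------------
# metabolites
# ---------------------------------------------------------------------------

def log2_to_control(
    table: pd.DataFrame,
    condition_col: str = "condition",
    control_label: str = "control",
    value_col: str = "value",
    group_cols=("cultivar", "metabolite"),
    center: str = "mean",
) -> pd.DataFrame:
    """Log2 fold-change matrix of condition means over the control mean.

    ``table`` is replicate-level and long-form; missing values (NaN) are
    ignored within a cell, and a cell with no observed replicates is
    reported as NaN (the "not detected" marker).  The control column of
    the output is identically 0.
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    group_cols = list(group_cols)
    agg = "mean" if center == "mean" else "median"
    cell = (
        table.groupby(group_cols + [condition_col], sort=False)[value_col]
        .agg(agg)
        .unstack(condition_col)
    )
    if control_label not in cell.columns:
        raise ValueError(f"no {control_label!r} condition in table")
    ctrl = cell[control_label]
    if (ctrl <= 0).any() or ctrl.isna().any():
        bad = ctrl.index[(ctrl <= 0) | ctrl.isna()][0]
        raise ValueError(f"non-positive or missing control mean for {bad}")
    out = np.log2(cell.div(ctrl, axis=0))
    out[control_label] = 0.0
    return out


def metabolite_report(
    table: pd.DataFrame,
    condition_col: str = "condition",
    control_label: str = "control",
    value_col: str = "value",
    group_cols=("cultivar", "metabolite"),
    test_on: str = "raw",
    mode: str = "student",
    fdr: bool = False,
):
    """Fold-change matrix plus per-cell significance stars.

    T-tests compare each condition's replicates with the control
    replicates, on raw concentrations by default (``test_on='log2'``
    tests log-transformed values).  ``fdr=True`` applies a
    Benjamini–Hochberg adjustment across all cells before starring —
    off by default (single-cell tests are the classical presentation,
    at the cost of multiplicity).
    Returns (log2 DataFrame, stars DataFrame of identical shape).
    """
    if test_on not in ("raw", "log2"):
        raise ValueError("test_on must be 'raw' or 'log2'")
    lfc = log2_to_control(table, condition_col, control_label, value_col, group_cols)
    stars = pd.DataFrame("", index=lfc.index, columns=lfc.columns)
    pvals, cells = [], []
    for key in lfc.index:
        sel = table
        for col, val in zip(list(group_cols), key if isinstance(key, tuple) else (key,)):
            sel = sel[sel[col] == val]
        ctrl = sel.loc[sel[condition_col] == control_label, value_col].dropna()
        for cond in lfc.columns:
            if cond == control_label:
                continue
            vals = sel.loc[sel[condition_col] == cond, value_col].dropna()
            if len(vals) < 2 or len(ctrl) < 2:
                continue
            a, c = vals.to_numpy(), ctrl.to_numpy()
            if test_on == "log2":
                if (a <= 0).any() or (c <= 0).any():
                    continue
                a, c = np.log2(a), np.log2(c)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, p, _ = ttest_vs_control(a, c, mode=mode)
            pvals.append(p)
            cells.append((key, cond))
    if fdr and pvals:
        pvals = list(stats.false_discovery_control(pvals))
    for (key, cond), p in zip(cells, pvals):
        stars.loc[key, cond] = star_code(p)
    return lfc, stars


# ---------------------------------------------------------------------------
# gas exchange
# ---------------------------------------------------------------------------

def gas_exchange_summary(
    readings: pd.DataFrame,
    parameters=("Pn", "E", "C"),
    mode: str = "student",
) -> pd.DataFrame:
    """Mean ± sd of gas-exchange parameters with stars vs same-day control.

    ``readings`` is long-form with columns ``cultivar, treatment, day,
    plant_id, parameter, value``.  Each (cultivar, day, parameter) needs a
    control group of >= 2 plants; stressed groups are tested against it.
    """
    required = {"cultivar", "treatment", "day", "plant_id", "parameter", "value"}
    missing = required - set(readings.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for (cultivar, day, param), sub in readings.groupby(
        ["cultivar", "day", "parameter"], sort=False
    ):
        if param not in parameters:
            continue
        ctrl = sub.loc[sub["treatment"] == "control", "value"].to_numpy()
        if ctrl.size < 2:
            raise ValueError(
                f"missing/undersized control group for {cultivar} day {day} {param}"
            )
        for treatment, grp in sub.groupby("treatment", sort=False):
            v = grp["value"].to_numpy()
            if treatment == "control":
                stars = ""
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, p, stars = ttest_vs_control(v, ctrl, mode=mode)
            rows.append(
                dict(
                    cultivar=cultivar,
                    treatment=treatment,
                    day=day,
                    parameter=param,
                    mean=float(v.mean()),
                    sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
                    n=int(v.size),
                    stars=stars,
                )
            )
    return pd.DataFrame(rows)


def electrolyte_leakage_summary(
    conductivity: pd.DataFrame, mode: str = "student"
) -> pd.DataFrame:
    """Per (cultivar, treatment, day) electrolyte-leakage mean ± sd with stars.

    ``conductivity`` columns: ``cultivar, treatment, day, plant_id, e1, e2``.
    """
    required = {"cultivar", "treatment", "day", "plant_id", "e1", "e2"}
    missing = required - set(conductivity.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = conductivity.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df["el_pct"] = electrolyte_leakage(df["e1"].to_numpy(), df["e2"].to_numpy())
    rows = []
    for (cultivar, day), sub in df.groupby(["cultivar", "day"], sort=False):
        ctrl = sub.loc[sub["treatment"] == "control", "el_pct"].to_numpy()
        for treatment, grp in sub.groupby("treatment", sort=False):
            v = grp["el_pct"].to_numpy()
            if treatment == "control" or ctrl.size < 2 or v.size < 2:
                stars = ""
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, p, stars = ttest_vs_control(v, ctrl, mode=mode)
            rows.append(
                dict(
                    cultivar=cultivar,
                    treatment=treatment,
                    day=day,
                    el_pct_mean=float(v.mean()),
                    el_pct_sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
                    n=int(v.size),
                    stars=stars,
                )
            )
    return pd.DataFrame(rows)
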