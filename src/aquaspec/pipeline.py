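"""End-to-end study workflow orchestration.

Stages mirror the experimental analysis chain and each one reads only
files written by earlier stages, so a run can be resumed mid-pipeline:

1. ``simulate``   — synthetic spectra + physiology + metabolite tables
2. ``preprocess`` — MSC per cultivar × leaf; Savitzky–Golay second
   derivative; per-day mean spectra and day-minus-day-0 differences
3. ``aquagram``   — by-treatment and by-day aquagrams per cultivar ×
   leaf, classic and extended WAMAC schemes
4. ``fit-days``   — per cultivar × leaf PLS day-of-stress models with a
   plant-wise calibration/validation split and LOOCV model selection
5. ``report``     — physiology and metabolite summary tables

All numeric output is CSV at 10+ significant digits; a manifest records
the package version, seed and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aquagram import compute_aquagram, default_wamacs
from .chemometrics import (
    DEFAULT_CAL_PLANTS,
    DEFAULT_VAL_PLANTS,
    NipalsPls,
    calibration_stats,
    loocv,
    split_by_plant,
    validation_stats,
)
from .physiology import (
    electrolyte_leakage_summary,
    gas_exchange_summary,
    metabolite_report,
)
from .preprocessing import difference_spectra, msc_correct, second_derivative
from .spectra import SpectraSet, group_mean, read_spectra, select_subset, write_spectra
from .synthetic import (
    StressSimConfig,
    generate_metabolites,
    generate_physiology,
    generate_spectra,
)

_FLOAT_FMT = "%.12g"


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    outdir: str = "aquaspec_run"
    seed: int = 0
    replicate_handling: str = "as_is"   # or "average_per_leaf"
    sg_window: int = 11
    sg_polyorder: int = 3
    sg_scale: str = "per_nm"
    max_lv: int = 10
    cal_plants: tuple = DEFAULT_CAL_PLANTS
    val_plants: tuple = DEFAULT_VAL_PLANTS
    secv_denominator: str = "n"
    aquagram_sd_mode: int = 1           # ddof for the pooled sd
    run_aquagrams: bool = True
    run_pls: bool = True
    run_physiology: bool = True
    sim: StressSimConfig = dataclasses.field(default_factory=StressSimConfig)
    input_spectra: str | None = None    # path to an existing wide CSV instead of simulating

    def __post_init__(self):
        if self.replicate_handling not in ("as_is", "average_per_leaf"):
            raise ValueError("replicate_handling must be 'as_is' or 'average_per_leaf'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        cfg = cls(**raw)
        if sim_raw:
            cfg.sim = dataclasses.replace(cfg.sim, **sim_raw)
        return cfg

    def config_hash(self) -> str:
        def normalise(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                o = dataclasses.asdict(o)
            if isinstance(o, dict):
                return {str(k): normalise(v) for k, v in sorted(o.items(), key=lambda kv: str(kv[0]))}
            if isinstance(o, (list, tuple, set, np.ndarray)):
                return [normalise(v) for v in o]
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return o if isinstance(o, (int, float, str, bool, type(None))) else str(o)

        d = dataclasses.asdict(self)
        d.pop("outdir", None)  # the analysis is identified by its settings, not its destination
        blob = json.dumps(normalise(d), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending group."""

    def __init__(self, stage: str, group: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for {group}: {cause}")
        self.stage = stage
        self.group = group


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
    spectra, _ = generate_spectra(sim)
    write_spectra(spectra, outdir / "spectra_raw.csv", "wide_csv")
    conductivity, gas = generate_physiology(sim)
    _write_csv(conductivity, outdir / "conductivity.csv")
    _write_csv(gas, outdir / "gas_exchange.csv")
    _write_csv(generate_metabolites(sim), outdir / "metabolites.csv")
    truth = {
        "changed_bands": {
            c: sim.changed_band_centers(c).tolist() for c in sim.cultivars
        }
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))


def stage_preprocess(cfg: RunConfig, outdir: Path) -> None:
    s = read_spectra(outdir / "spectra_raw.csv", "wide_csv")
    if cfg.replicate_handling == "average_per_leaf":
        s = group_mean(s, ["cultivar", "treatment", "plant_id", "leaf", "day"])
        # restore the full metadata schema expected by downstream file I/O
        s.meta["replicate"] = 1
        missing = [c for c in ["cultivar", "treatment", "plant_id", "leaf", "day"]
                   if c not in s.meta.columns]
        if missing:  # pragma: no cover - guarded by group keys above
            raise StageError("preprocess", "replicate averaging", KeyError(missing))

    d2 = second_derivative(s, cfg.sg_window, cfg.sg_polyorder, cfg.sg_scale)
    write_spectra(d2, outdir / "spectra_d2.csv", "wide_csv")

    cultivars = s.meta["cultivar"].unique()
    leaves = s.meta["leaf"].unique()
    msc_parts = []
    for cultivar in cultivars:
        for leaf in leaves:
            sub = select_subset(s, cultivar=cultivar, leaf=leaf)
            if sub.n_measurements < 2:
                continue
            try:
                corrected, _ = msc_correct(sub)
            except ValueError as e:
                raise StageError("preprocess", f"{cultivar}/{leaf}", e)
            msc_parts.append(corrected)
            # per-day mean second-derivative spectra and day-minus-day-0
            # differences of the stressed plants
            d2_sub = select_subset(d2, cultivar=cultivar, leaf=leaf, treatment="stress")
            if d2_sub.n_measurements == 0:
                continue
            means = group_mean(d2_sub, ["cultivar", "leaf", "day"])
            write_spectra_like(means, outdir / f"mean_d2_{cultivar}_{leaf}.csv")
            try:
                diffs = difference_spectra(means, baseline_day=0, keys=["cultivar", "leaf"])
            except ValueError as e:
                raise StageError("preprocess", f"{cultivar}/{leaf}", e)
            write_spectra_like(diffs, outdir / f"diff_d2_{cultivar}_{leaf}.csv")
    merged = _concat_sets(msc_parts)
    write_spectra(merged, outdir / "spectra_msc.csv", "wide_csv")


def write_spectra_like(s: SpectraSet, path: Path) -> None:
    """Wide-CSV export for aggregated sets (partial metadata allowed)."""
    wide = pd.concat(
        [
            s.meta.reset_index(drop=True),
            pd.DataFrame(s.absorbance, columns=[f"{w:.12g}" for w in s.wavelengths]),
        ],
        axis=1,
    )
    wide.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _concat_sets(parts) -> SpectraSet:
    if not parts:
        raise ValueError("nothing to concatenate")
    wl = parts[0].wavelengths
    mat = np.vstack([p.absorbance for p in parts])
    meta = pd.concat([p.meta for p in parts], ignore_index=True)
    return SpectraSet(wl, mat, meta, list(parts[0].processing_log))


def stage_aquagram(cfg: RunConfig, outdir: Path) -> None:
    s = read_spectra(outdir / "spectra_msc.csv", "wide_csv")
    for cultivar in s.meta["cultivar"].unique():
        for leaf in s.meta["leaf"].unique():
            sub = select_subset(s, cultivar=cultivar, leaf=leaf)
            if sub.n_measurements < 2:
                continue
            for scheme in ("classic12", "extended7"):
                wam = default_wamacs(scheme)
                try:
                    by_treatment = compute_aquagram(
                        sub, wam, ["treatment"], ddof=cfg.aquagram_sd_mode
                    )
                    stress = select_subset(sub, treatment="stress")
                    by_day = compute_aquagram(
                        stress, wam, ["day"], ddof=cfg.aquagram_sd_mode
                    )
                except (ValueError, KeyError) as e:
                    raise StageError("aquagram", f"{cultivar}/{leaf}/{scheme}", e)
                _write_csv(
                    by_treatment.to_frame(),
                    outdir / f"aquagram_{scheme}_treatment_{cultivar}_{leaf}.csv",
                )
                _write_csv(
                    by_day.to_frame(),
                    outdir / f"aquagram_{scheme}_day_{cultivar}_{leaf}.csv",
                )


def stage_fit_days(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    d2 = read_spectra(outdir / "spectra_d2.csv", "wide_csv")
    # day-of-stress models use stressed plants only; recovery is excluded
    d2 = select_subset(d2, treatment="stress")
    rows = []
    vec_rows = []
    for cultivar in d2.meta["cultivar"].unique():
        for leaf in d2.meta["leaf"].unique():
            sub = select_subset(d2, cultivar=cultivar, leaf=leaf)
            if sub.n_measurements == 0:
                continue
            try:
                cal, val = split_by_plant(sub, cfg.cal_plants, cfg.val_plants)
                Xc, yc = cal.absorbance, cal.meta["day"].to_numpy(float)
                Xv, yv = val.absorbance, val.meta["day"].to_numpy(float)
                cv = loocv(Xc, yc, cfg.max_lv, denominator=cfg.secv_denominator)
                model = NipalsPls(n_components=cv.chosen_lv).fit(Xc, yc)
                sec, rcal = calibration_stats(model, Xc, yc)
                sep, rval = validation_stats(model, Xv, yv)
            except (ValueError, KeyError) as e:
                raise StageError("fit-days", f"{cultivar}/{leaf}", e)
            model.save(outdir / f"pls_model_{cultivar}_{leaf}.json")
            rows.append(
                dict(cultivar=cultivar, leaf=leaf, pls_factors=cv.chosen_lv,
                     secv=cv.secv, rcv=cv.rcv, sec=sec, rcal=rcal,
                     sep=sep, rval=rval, n_cal=len(yc), n_val=len(yv))
            )
            for wl, b in zip(sub.wavelengths, model.coef_):
                vec_rows.append(
                    dict(cultivar=cultivar, leaf=leaf, wavelength_nm=wl, coefficient=b)
                )
    table = pd.DataFrame(rows)
    _write_csv(table, outdir / "pls_tables.csv")
    _write_csv(pd.DataFrame(vec_rows), outdir / "regression_vectors.csv")
    return table


def stage_report(cfg: RunConfig, outdir: Path) -> None:
    conductivity = pd.read_csv(outdir / "conductivity.csv")
    gas = pd.read_csv(outdir / "gas_exchange.csv")
    metabolites = pd.read_csv(outdir / "metabolites.csv")
    try:
        _write_csv(electrolyte_leakage_summary(conductivity),
                   outdir / "electrolyte_leakage.csv")
        _write_csv(gas_exchange_summary(gas), outdir / "gas_exchange_summary.csv")
        lfc, stars = metabolite_report(metabolites)
    except (ValueError, KeyError) as e:
        raise StageError("report", "physiology tables", e)
    lfc.to_csv(outdir / "metabolite_log2.csv", float_format=_FLOAT_FMT)
    stars.to_csv(outdir / "metabolite_stars.csv")


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every stage in order; returns a small report dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.input_spectra is not None:
        s = read_spectra(cfg.input_spectra, "wide_csv")
        write_spectra(s, outdir / "spectra_raw.csv", "wide_csv")
        sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        _write_csv(generate_physiology(sim)[0], outdir / "conductivity.csv")
        _write_csv(generate_physiology(sim)[1], outdir / "gas_exchange.csv")
        _write_csv(generate_metabolites(sim), outdir / "metabolites.csv")
    else:
        stage_simulate(cfg, outdir)
    stage_preprocess(cfg, outdir)
    if cfg.run_aquagrams:
        stage_aquagram(cfg, outdir)
    pls_table = stage_fit_days(cfg, outdir) if cfg.run_pls else None
    if cfg.run_physiology:
        stage_report(cfg, outdir)
    manifest = {
        "package": "aquaspec",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"outdir": str(outdir), "pls_table": pls_table, "manifest": manifest}
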