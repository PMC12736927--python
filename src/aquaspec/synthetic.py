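"""Synthetic leaf-spectra, physiology and metabolite generator.

Emulates a two-cultivar cucumber chilling-stress experiment: a
chilling-tolerant and a chilling-sensitive cultivar, control / stress /
recovery treatments, 10 plants per cultivar per treatment, three leaf
types (cotyledon, first, second true leaf), daily NIR measurements over
days 0–7 of stress at 8 °C plus a recovery timepoint three days after
return to normal temperature, and at least two replicate spectra per
leaf per day.

Leaf absorbance is modelled as a sum of Gaussian absorption bands — the
dominant free-water first-overtone band near 1416 nm, water species of
increasing hydrogen-bonding around 1450–1490 nm, polymer-bound water at
1534/1571 nm and weaker O–H bands at 970/1087/1155 nm — on a flat
continuum.  Chilling shifts the water spectral pattern linearly with
day of stress: free/weakly bound water band amplitudes decrease while
strongly hydrogen-bonded and polymer-associated water increase, far more
for the sensitive cultivar than for the tolerant one and more in
cotyledons than in the second leaf.  Each measurement receives an affine
scatter distortion (multiplicative gain b ~ LogNormal, additive offset
a ~ Normal) — exactly the model MSC inverts, so scatter-correction
accuracy is testable against ground truth — plus white channel noise.

Everything is deterministic under the configured seed, and the returned
ground-truth record exposes every per-row band amplitude and scatter
coefficient for recovery tests.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import SpectraSet, LEAVES


def reflectance_to_absorbance(r):
    """A = log10(1/R) for reflectance in (0, 1]."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0) or np.any(r > 1):
        raise ValueError("reflectance must lie in (0, 1]")
    return np.log10(1.0 / r)


@dataclasses.dataclass(frozen=True)
class Band:
    """A Gaussian absorption band: amplitude · exp(−(λ−center)²/(2·width²))."""

    center: float          # nm
    width: float           # Gaussian sigma, nm
    base_amplitude: float  # absorbance units at day 0

    def __post_init__(self):
        if self.width <= 0 or self.base_amplitude < 0:
            raise ValueError("band width must be > 0 and amplitude >= 0")


#: default band library: weak O–H combination/overtone bands below 1200 nm,
#: free and weakly bound water around 1373–1450 nm, water species with 1–4
#: hydrogen bonds at 1441–1490 nm, polymer-bound water above 1500 nm.
DEFAULT_BANDS = (
    Band(970.0, 35.0, 0.15),
    Band(1087.0, 30.0, 0.08),
    Band(1155.0, 30.0, 0.12),
    Band(1373.0, 16.0, 0.12),
    Band(1416.0, 20.0, 0.50),
    Band(1450.0, 16.0, 0.20),
    Band(1466.0, 14.0, 0.15),
    Band(1478.0, 14.0, 0.12),
    Band(1490.0, 14.0, 0.10),
    Band(1534.0, 18.0, 0.08),
    Band(1571.0, 18.0, 0.06),
)

#: per-day amplitude change of each band under stress, sensitive cultivar
#: (absorbance units/day).  Free/weakly bound water declines; strongly
#: hydrogen-bonded and polymer-associated water accumulates.
DEFAULT_SENSITIVE_SLOPES = {
    970.0: -0.002,
    1087.0: -0.001,
    1155.0: -0.002,
    1373.0: -0.008,
    1416.0: -0.020,
    1450.0: -0.008,
    1466.0: 0.006,
    1478.0: 0.005,
    1490.0: 0.004,
    1534.0: 0.004,
    1571.0: 0.003,
}

#: electrolyte-leakage trajectories (%), by cultivar and day; the recovery
#: timepoint uses the key 'recovery'.  Sensitive: sigmoid rise to ~92% at
#: day 7 and complete membrane disruption (100%) after recovery; tolerant:
#: stable with a slight rise at day 7 and recovery afterwards.
DEFAULT_EL_CURVES = {
    "sensitive": {0: 8.0, 3: 35.0, 5: 60.0, 7: 92.0, "recovery": 100.0},
    "tolerant": {0: 8.0, 3: 9.0, 5: 10.0, 7: 20.0, "recovery": 12.0},
}

#: fraction of the control value retained under stress, per parameter.
#: Pn falls ~90% by day 7 in the sensitive cultivar, ~30% in the tolerant.
DEFAULT_GAS_RETENTION = {
    "sensitive": {0: 1.0, 3: 0.5, 5: 0.5, 7: 0.1},
    "tolerant": {0: 1.0, 3: 0.9, 5: 0.8, 7: 0.7},
}

#: control-condition gas-exchange levels (Pn µmol CO2 m⁻² s⁻¹,
#: E mmol H2O m⁻² s⁻¹, C mol H2O m⁻² s⁻¹)
DEFAULT_GAS_CONTROL = {"Pn": 20.0, "E": 4.0, "C": 0.3}

#: configured log2 fold-changes to control, (tolerant, sensitive) per
#: metabolite and stress day; None marks a not-detected cell.
DEFAULT_METABOLITE_EFFECTS = {
    # metabolite: class, {cultivar: {day: log2fc}}
    "fructose": ("sugars", {"tolerant": {3: -1.7, 5: -2.2, 7: -0.2},
                            "sensitive": {3: -1.7, 5: -1.1, 7: -2.7}}),
    "glucose": ("sugars", {"tolerant": {3: -2.5, 5: -2.6, 7: -0.8},
                           "sensitive": {3: -2.8, 5: -2.9, 7: -3.4}}),
    "sucrose": ("sugars", {"tolerant": {3: -2.1, 5: -3.8, 7: -2.2},
                           "sensitive": {3: -3.3, 5: -0.5, 7: -6.7}}),
    "myo-inositol": ("sugars", {"tolerant": {3: -0.2, 5: -0.1, 7: 0.1},
                                "sensitive": {3: 0.2, 5: 0.3, 7: 0.1}}),
    "glycerol": ("alcohols", {"tolerant": {3: 0.2, 5: 0.2, 7: -0.5},
                              "sensitive": {3: 0.5, 5: 0.6, 7: -0.1}}),
    "galactinol": ("alcohols", {"tolerant": {3: -0.9, 5: -1.0, 7: -2.5},
                                "sensitive": {3: -1.5, 5: -1.6, 7: -2.2}}),
    "lactic acid": ("organic acids", {"tolerant": {3: 0.0, 5: 0.0, 7: -0.1},
                                      "sensitive": {3: 0.1, 5: 0.0, 7: -0.2}}),
    "glycolic acid": ("organic acids", {"tolerant": {3: -0.3, 5: -0.2, 7: -0.3},
                                        "sensitive": {3: -0.6, 5: -0.5, 7: -0.9}}),
    "succinic acid": ("organic acids", {"tolerant": {3: -0.1, 5: -0.8, 7: -0.8},
                                        "sensitive": {3: -0.6, 5: -0.3, 7: -0.8}}),
    "glyceric acid": ("organic acids", {"tolerant": {3: -2.1, 5: -1.9, 7: -2.4},
                                        "sensitive": {3: -0.7, 5: -0.6, 7: -1.4}}),
    "fumaric acid": ("organic acids", {"tolerant": {3: -0.1, 5: -0.5, 7: -0.9},
                                       "sensitive": {3: -1.6, 5: -1.2, 7: -2.0}}),
    "malic acid": ("organic acids", {"tolerant": {3: -1.6, 5: -2.7, 7: -2.9},
                                     "sensitive": {3: -2.1, 5: -2.9, 7: -3.2}}),
    "cinnamic acid": ("phenolic acids", {"tolerant": {3: 0.1, 5: -0.8, 7: 1.1},
                                         "sensitive": {3: -0.8, 5: -1.9, 7: -1.5}}),
    "ferulic acid": ("phenolic acids", {"tolerant": {3: 0.1, 5: 0.4, 7: 0.2},
                                        "sensitive": {3: -1.2, 5: -1.6, 7: None}}),
    "palmitic acid": ("fatty acids", {"tolerant": {3: -0.2, 5: 0.2, 7: 0.2},
                                      "sensitive": {3: 0.5, 5: 0.8, 7: 0.1}}),
    "stearic acid": ("fatty acids", {"tolerant": {3: 0.4, 5: 0.2, 7: -0.2},
                                     "sensitive": {3: 1.1, 5: 1.4, 7: 0.5}}),
    "1-monopalmitin": ("fatty acids", {"tolerant": {3: -0.6, 5: -0.5, 7: -3.7},
                                       "sensitive": {3: -0.2, 5: -0.8, 7: -1.7}}),
    "glycerol monostearate": ("fatty acids", {"tolerant": {3: 0.4, 5: 0.4, 7: -1.1},
                                              "sensitive": {3: -0.2, 5: -0.4, 7: -4.0}}),
}


@dataclasses.dataclass
class StressSimConfig:
    """Ground-truth parameters of the simulated chilling-stress experiment."""

    # instrument grid
    n_channels: int = 125
    wl_min: float = 908.0
    wl_max: float = 1676.0
    # spectral model
    bands: tuple = DEFAULT_BANDS
    sensitive_slopes: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SENSITIVE_SLOPES)
    )
    tolerant_factor: float = 0.3       # tolerant slope = factor × sensitive
    continuum: float = 0.05            # flat absorbance baseline
    leaf_effect: dict = dataclasses.field(
        default_factory=lambda: {"cotyledon": 1.2, "first": 1.0, "second": 0.6}
    )
    leaf_base: dict = dataclasses.field(
        default_factory=lambda: {"cotyledon": 1.1, "first": 1.0, "second": 0.95}
    )
    recovery_multiplier: dict = dataclasses.field(
        default_factory=lambda: {"sensitive": 1.4, "tolerant": 0.3}
    )
    # experimental design
    cultivars: tuple = ("tolerant", "sensitive")
    leaves: tuple = LEAVES
    n_plants: int = 10
    stress_days: tuple = tuple(range(8))
    recovery_day: int = 10
    replicates: int = 2
    recovery_replicates: int = 3
    spectra_per_leaf: tuple = (140, 150)     # trim target per cultivar×treatment×leaf
    recovery_spectra_per_leaf: tuple = (25, 30)
    # noise / scatter
    scatter_sigma_b: float = 0.08      # log-sd of multiplicative gain
    scatter_sigma_a: float = 0.01      # sd of additive offset (AU)
    noise_sd: float = 0.0015           # white channel noise (AU)
    plant_sigma: float = 0.02          # between-plant amplitude multiplier sd
    # physiology
    el_curves: dict = dataclasses.field(default_factory=lambda: {
        c: dict(v) for c, v in DEFAULT_EL_CURVES.items()})
    gas_retention: dict = dataclasses.field(default_factory=lambda: {
        c: dict(v) for c, v in DEFAULT_GAS_RETENTION.items()})
    gas_control: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_GAS_CONTROL))
    physiology_days: tuple = (0, 3, 5, 7)
    n_physio_plants: int = 5
    el_noise_sd: float = 3.0           # percentage points
    gas_noise_frac: float = 0.08       # sd as fraction of control level
    e2_mean: float = 1200.0            # µS/cm
    e2_sd: float = 100.0
    # metabolites
    metabolite_effects: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_METABOLITE_EFFECTS))
    metabolite_control_mean: float = 10.0   # arbitrary concentration units
    n_metabolite_replicates: int = 5
    metabolite_log2_sd: float = 0.3
    # reproducibility
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 5:
            raise ValueError("need at least 5 channels")
        if not 0 <= self.tolerant_factor < 1:
            raise ValueError("tolerant_factor must be in [0, 1)")
        for b in self.bands:
            if b.width <= 0:
                raise ValueError("band widths must be positive")
        # the sensitive cultivar must change strictly more than the tolerant
        # one in the 1410–1478 nm water region
        for b in self.bands:
            if 1410 <= b.center <= 1478:
                s = abs(self.sensitive_slopes.get(b.center, 0.0))
                if s > 0 and abs(s * self.tolerant_factor) >= s:
                    raise ValueError(
                        "sensitive trajectory must exceed tolerant at 1410–1478 nm"
                    )

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.wl_min, self.wl_max, self.n_channels)

    def slope(self, cultivar: str, center: float) -> float:
        base = self.sensitive_slopes.get(center, 0.0)
        if cultivar == "sensitive":
            return base
        return base * self.tolerant_factor

    def changed_band_centers(self, cultivar: str, min_slope: float = 1e-6):
        """Band centers whose amplitude trajectory is non-flat for a cultivar."""
        return np.array(
            sorted(
                b.center
                for b in self.bands
                if abs(self.slope(cultivar, b.center)) > min_slope
            )
        )


@dataclasses.dataclass
class GroundTruth:
    """Per-row generative parameters exposed for recovery tests."""

    band_centers: np.ndarray
    amplitudes: np.ndarray     # n_rows × n_bands, after plant effect, before scatter
    scatter_a: np.ndarray
    scatter_b: np.ndarray
    plant_effect: pd.DataFrame  # cultivar, treatment, plant_id -> multiplier


def _band_matrix(config: StressSimConfig) -> np.ndarray:
    wl = config.grid
    centers = np.array([b.center for b in config.bands])
    widths = np.array([b.width for b in config.bands])
    return np.exp(-((wl[None, :] - centers[:, None]) ** 2) / (2 * widths[:, None] ** 2))


def _effective_day(config, cultivar, treatment, day):
    """Cumulative stress exposure driving band amplitude change."""
    if treatment == "control":
        return 0.0
    if treatment == "stress":
        return float(day)
    last = max(config.stress_days)
    return float(last) * config.recovery_multiplier[cultivar]


def generate_spectra(config: StressSimConfig | None = None, seed: int | None = None):
    """Simulate the full spectral dataset.

    Returns ``(SpectraSet, GroundTruth)``.  Row counts per cultivar ×
    treatment × leaf are trimmed to a uniform draw from
    ``spectra_per_leaf`` (control/stress) or ``recovery_spectra_per_leaf``,
    emulating occasionally discarded field measurements.
    """
    config = config or StressSimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    wl = config.grid
    shapes = _band_matrix(config)              # n_bands × n_channels
    centers = np.array([b.center for b in config.bands])
    base_amp = np.array([b.base_amplitude for b in config.bands])

    # per (cultivar, treatment, plant) amplitude multiplier, constant over days
    plant_rows = []
    plant_mult = {}
    for cultivar in config.cultivars:
        for treatment in ("control", "stress", "recovery"):
            for plant in range(1, config.n_plants + 1):
                m = float(rng.normal(1.0, config.plant_sigma))
                plant_mult[(cultivar, treatment, plant)] = m
                plant_rows.append(
                    dict(cultivar=cultivar, treatment=treatment, plant_id=plant,
                         multiplier=m)
                )

    meta_rows, amp_rows = [], []
    for cultivar in config.cultivars:
        for treatment in ("control", "stress", "recovery"):
            if treatment == "recovery":
                days = (config.recovery_day,)
                reps = config.recovery_replicates
            else:
                days = config.stress_days
                reps = config.replicates
            for leaf in config.leaves:
                for day in days:
                    eff = _effective_day(config, cultivar, treatment, day)
                    slopes = np.array(
                        [config.slope(cultivar, c) for c in centers]
                    )
                    amp = (
                        base_amp * config.leaf_base[leaf]
                        + slopes * eff * config.leaf_effect[leaf]
                    )
                    amp = np.clip(amp, 0.0, None)
                    for plant in range(1, config.n_plants + 1):
                        m = plant_mult[(cultivar, treatment, plant)]
                        for rep in range(1, reps + 1):
                            meta_rows.append(
                                dict(cultivar=cultivar, treatment=treatment,
                                     plant_id=plant, leaf=leaf, day=day,
                                     replicate=rep)
                            )
                            amp_rows.append(amp * m)

    meta = pd.DataFrame(meta_rows)
    amps = np.vstack(amp_rows)

    # trim each cultivar×treatment×leaf group to its configured spectra count
    keep = np.ones(len(meta), dtype=bool)
    for (cultivar, treatment, leaf), idx in meta.groupby(
        ["cultivar", "treatment", "leaf"], sort=False
    ).indices.items():
        lo, hi = (
            config.recovery_spectra_per_leaf
            if treatment == "recovery"
            else config.spectra_per_leaf
        )
        target = int(rng.integers(lo, hi + 1))
        if len(idx) > target:
            drop = rng.choice(idx, size=len(idx) - target, replace=False)
            keep[drop] = False
    meta = meta.loc[keep].reset_index(drop=True)
    amps = amps[keep]

    n = len(meta)
    signal = amps @ shapes + config.continuum
    b = rng.lognormal(0.0, config.scatter_sigma_b, size=n)
    a = rng.normal(0.0, config.scatter_sigma_a, size=n)
    noise = rng.normal(0.0, config.noise_sd, size=(n, config.n_channels))
    absorbance = b[:, None] * signal + a[:, None] + noise

    truth = GroundTruth(
        band_centers=centers,
        amplitudes=amps,
        scatter_a=a,
        scatter_b=b,
        plant_effect=pd.DataFrame(plant_rows),
    )
    return SpectraSet(wl, absorbance, meta), truth


def generate_physiology(config: StressSimConfig | None = None, seed: int | None = None):
    """Simulate conductivity pairs and gas-exchange readings.

    Returns ``(conductivity, gas_exchange)`` DataFrames.  Expected
    electrolyte leakage follows the configured per-cultivar trajectories
    (sensitive rising to ~92% at day 7, 100% after recovery); expected
    net photosynthesis under stress is the control level times the
    configured retention fraction.
    """
    config = config or StressSimConfig()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)

    cond_rows = []
    for cultivar in config.cultivars:
        curve = config.el_curves[cultivar]
        control_el = curve[0]
        points = [("control", d, control_el) for d in config.physiology_days]
        points += [("stress", d, curve[d]) for d in config.physiology_days]
        points += [("recovery", config.recovery_day, curve["recovery"])]
        for treatment, day, el in points:
            for plant in range(1, config.n_physio_plants + 1):
                el_i = float(np.clip(rng.normal(el, config.el_noise_sd), 0.0, 100.0))
                e2 = float(rng.normal(config.e2_mean, config.e2_sd))
                cond_rows.append(
                    dict(cultivar=cultivar, treatment=treatment, day=day,
                         plant_id=plant, e1=el_i / 100.0 * e2, e2=e2)
                )
    conductivity = pd.DataFrame(cond_rows)

    gas_rows = []
    for cultivar in config.cultivars:
        retention = config.gas_retention[cultivar]
        for param, level in config.gas_control.items():
            sd = config.gas_noise_frac * level
            for day in config.physiology_days:
                for treatment in ("control", "stress"):
                    mean = level if treatment == "control" else level * retention[day]
                    for plant in range(1, config.n_physio_plants + 1):
                        gas_rows.append(
                            dict(cultivar=cultivar, treatment=treatment, day=day,
                                 plant_id=plant, parameter=param,
                                 value=float(max(rng.normal(mean, sd), 0.0)))
                        )
    gas = pd.DataFrame(gas_rows)
    return conductivity, gas


def generate_metabolites(config: StressSimConfig | None = None, seed: int | None = None):
    """Simulate a replicate-level metabolite concentration table.

    Concentrations are lognormal draws around condition means whose
    log2-ratios to control equal the configured effects; 5 biological
    replicates per cell by default.  ``None`` effects yield not-detected
    (NaN) cells.
    """
    config = config or StressSimConfig()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    rows = []
    for metabolite, (klass, per_cultivar) in config.metabolite_effects.items():
        for cultivar, per_day in per_cultivar.items():
            conditions = [("control", 0.0)] + [
                (f"day{d}", fc) for d, fc in per_day.items()
            ]
            for condition, log2fc in conditions:
                for rep in range(1, config.n_metabolite_replicates + 1):
                    if log2fc is None:
                        value = np.nan
                    else:
                        mean_log2 = np.log2(config.metabolite_control_mean) + log2fc
                        value = float(
                            2.0 ** rng.normal(mean_log2, config.metabolite_log2_sd)
                        )
                    rows.append(
                        dict(metabolite=metabolite, metabolite_class=klass,
                             cultivar=cultivar, condition=condition,
                             replicate=rep, value=value)
                    )
    return pd.DataFrame(rows)
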