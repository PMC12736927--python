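# aquaspec

NIR aquaphotomics toolkit for plant chilling-stress phenotyping.

`aquaspec` implements the complete analysis chain used to characterise
low-temperature stress in leaves from near-infrared absorbance spectra
(~900–1700 nm), alongside the physiological and metabolic read-outs the
spectra are compared against.  It is aimed at chemometricians and plant
physiologists who want a tested, scriptable version of this workflow:

* **scatter correction** — multiplicative scatter correction (MSC):
  each spectrum *x* is regressed on a reference spectrum *r*,
  *x* ≈ *a* + *b·r*, and replaced by (*x* − *a*)/*b*, removing additive
  and multiplicative effects of leaf thickness and surface texture;
* **derivative spectroscopy** — Savitzky–Golay second derivative
  (default window 11 channels, polynomial order 3), resolving
  overlapping water bands and removing baselines, plus per-day mean
  spectra and day-minus-day-0 difference spectra;
* **aquagrams** — the water-spectral-pattern statistic over WAMAC
  (water matrix coordinate) wavelengths in the first overtone of water:

      Aq_λ = (A_λ − μ_λ) / σ_λ

  where *A*_λ is the MSC-corrected absorbance of one measurement and
  μ_λ, σ_λ are the mean and sample standard deviation over all spectra
  in the pool.  Built-in coordinate sets: the 12 classic WAMACs
  (1348–1503 nm) and an extended 7-coordinate set for strongly bound,
  polymer-associated water (1416–1571 nm); both fully overridable;
* **PLS day-of-stress models** — NIPALS PLS1 on second-derivative
  spectra with a plant-wise calibration/validation split (plants
  1, 2, 4, 5, 7, 8, 10 vs 3, 6, 9), leave-one-out cross-validation,
  latent-variable selection at the first SECV minimum, and SEC / SECV /
  SEP / R reporting, with regression-vector export;
* **physiology** — electrolyte leakage (100 · E1/E2 from pre-/
  post-autoclave conductivities), gas-exchange summaries (Pn, E, C)
  with Student t-tests against same-day controls, and metabolite
  log2-fold-change matrices with significance stars;
* **a synthetic generator** — Gaussian-band leaf spectra with
  stress-dependent water-band trajectories, affine scatter and noise,
  emulating a two-cultivar (tolerant / sensitive) chilling experiment
  with full ground truth for recovery testing.

The chemometric estimators (`MscScatterCorrection`,
`SavitzkyGolayDerivative`, `AquagramScaler`, `NipalsPls`) follow
scikit-learn conventions (`fit`/`transform`/`predict`, `get_params`,
fitted attributes with trailing underscores) and compose with sklearn
pipelines and model selection.

## Worked example

Run the full synthetic study (simulate → MSC → second derivative →
difference spectra → aquagrams → PLS → physiology report):

```bash
aquaspec run-all --outdir demo --seed 1
```

prints the per-cultivar × per-leaf day-of-stress PLS table:

```
 cultivar      leaf  pls_factors     secv      rcv      sec     rcal      sep     rval  n_cal  n_val
 tolerant cotyledon            2 0.267100 0.992979 0.255985 0.993748 0.256315 0.994907     99     44
 tolerant     first            2 0.269200 0.993287 0.255970 0.994113 0.243730 0.995518    101     41
 tolerant    second            2 0.319667 0.990366 0.312025 0.991068 0.369102 0.987184    106     44
sensitive cotyledon            2 0.196169 0.996251 0.188083 0.996655 0.209359 0.996102    102     44
sensitive     first            2 0.197150 0.996325 0.189025 0.996724 0.208292 0.996145     99     43
sensitive    second            2 0.193824 0.996360 0.183912 0.996818 0.193509 0.996645    104     44
```

Each row is one PLS model predicting the day of chilling (0–7) from
second-derivative spectra of one leaf type of one cultivar: the chosen
number of latent variables, the cross-validation error (SECV, in days)
and correlation (Rcv), the calibration statistics (SEC, Rcal), and the
error and correlation on the three held-out validation plants (SEP,
Rval).  Errors well below a day mean the water spectral pattern tracks
stress duration closely.  `demo/` also contains the aquagram radar data
(by treatment and by day), difference spectra, regression vectors,
electrolyte-leakage and gas-exchange summaries, the metabolite log2
heat-map matrix, and a manifest with the seed and config hash.

The same workflow is available programmatically:

```python
from aquaspec import RunConfig, run_full_analysis
report = run_full_analysis(RunConfig(outdir="demo", seed=1))
print(report["pls_table"])
```

## Layout

| module | contents |
| --- | --- |
| `aquaspec.spectra` | `SpectraSet` container, wide/long CSV I/O, selection, group means |
| `aquaspec.preprocessing` | MSC, Savitzky–Golay second derivative, difference spectra |
| `aquaspec.aquagram` | WAMAC sets, aquagram z-scores, radar export |
| `aquaspec.chemometrics` | NIPALS PLS1, LOOCV, SEC/SECV/SEP/R, plant-wise splits |
| `aquaspec.physiology` | electrolyte leakage, gas exchange, metabolite fold changes, t-tests |
| `aquaspec.synthetic` | configurable stress-spectra / physiology / metabolite generator |
| `aquaspec.pipeline` / `aquaspec.cli` | staged workflow and `aquaspec` command |

See `docs/methods.md` for the model, parameter and design notes.
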