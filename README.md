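# leafnir

Chemometric calibration of **pear-leaf nitrogen concentration (g/kg) from
in-field visible/near-infrared spectra**, built for agronomists and
spectroscopists who want a tested, reproducible version of the standard
leaf-clip workflow: measure leaves at 350–2500 nm, pre-treat the library,
fit calibrations, and rank them.

Timely leaf-N diagnosis drives fertilizer decisions in orchards, but the
chemical reference method (CHN analysis of dried, ground leaves) is slow
and destructive. Vis/NIR reflectance responds to N through chlorophyll
absorption in the visible and protein features in the short-wave infrared,
so a calibrated spectral model can replace most laboratory measurements.

## What the package does

* **`leafnir.synth`** — a documented analytic generator of leaf spectra
  (green peak, red edge, NIR plateau, 1440/1900 nm water wells, N-coupled
  absorption wells) under three measurement modes: black-background
  reflectance, white-background transflectance, and sun-lit 25° bare
  fibre. Defaults reproduce a realistic study: 5 fertilization levels,
  720 leaves, pooled N = 25.4 ± 3.0 g/kg.
* **`leafnir.preprocess`** — white-reference ratioing, replicate
  averaging, atmospheric-window masking, Hotelling-T² PCA outlier
  screening, unit-vector normalization, seeded calibration/validation
  splits, all logged in an auditable record.
* **`leafnir.calibrate`** — the four engines, implemented here:
  * **PCR** — principal component regression;
  * **PLSR** — PLS1 by NIPALS with the factor count chosen by exact
    leave-one-out cross-validation:
    `w ∝ X'y`, `t = Xw`, deflate, repeat; coefficients
    `b = W(P'W)⁻¹q`;
  * **SMLR** — greedy forward stepwise wavelength selection gated by the
    partial-F p-value;
  * **BPNN** — back-propagation network on leading PC scores with
    multiple seeded restarts and hold-out model selection.
* **`leafnir.bandpair`** — exhaustive two-band index search at 10 nm
  intervals for `DSI = R₁−R₂`, `RSI = R₁/R₂`,
  `NDSI = (R₁−R₂)/(R₁+R₂)`, scored by linear-regression R² against N,
  with contour-map export.
* **`leafnir.evaluate`** — R², RMSEC/RMSEV, mean relative error,
  calibration grading (R² > 0.91 excellent, 0.82–0.91 good), correlograms,
  the N–yield polynomial, and a ranked method-comparison table with an
  overfitting flag.
* **`leafnir` CLI** — `simulate`, `preprocess`, `fit`, `bandsearch`,
  `evaluate`, `report`, and an all-in-one seeded `run`.

See `docs/methods.md` for the model details and assumptions.

## Worked example

```python
import numpy as np
from leafnir import (Mode, simulate_dataset, plant_outliers, exhaustive_search,
                     fit_plsr, predict, evaluation_report)
from leafnir.pipeline import PipelineConfig, preprocess_mode
from leafnir.synth import SimulationConfig

raw = simulate_dataset(SimulationConfig(mode=Mode.BLACK_BACKGROUND, seed=123))
raw, _ = plant_outliers(raw, 10, 3.0, np.random.default_rng(7))  # gross failures
cal, val, record = preprocess_mode(raw, PipelineConfig(), seed=5)
print(len(raw), "->", len(cal) + len(val), "after the T2 screen")

Xc, wl = cal.matrix(); Xv, _ = val.matrix()
model = fit_plsr(Xc, cal.n_gkg, max_factors=20, wavelengths=wl)
rep = evaluation_report("PLSR", cal.n_gkg, predict(model, Xc),
                        val.n_gkg, predict(model, Xv))
print(f"factors={model.meta['n_factors']}  "
      f"R2cal={rep.r2_calibration:.2f}  R2val={rep.r2_validation:.2f}  "
      f"RMSEV={rep.rmsev_gkg:.2f} g/kg  MRE={rep.mean_relative_error_pct:.1f}%")

res = exhaustive_search(cal, "dsi", interval_nm=10)
print(f"best DSI pair {res.best_pair} nm, R2={res.best_r2:.2f}")
```

Output:

```
720 -> 709 after the T2 screen
factors=10  R2cal=0.91  R2val=0.85  RMSEV=1.20 g/kg  MRE=3.9%
best DSI pair (720.0, 770.0) nm, R2=0.47
```

Reading: the screen removed the 10 planted gross outliers plus one false
flag (720 → 709, reproducing the intended ~710 sample flow); the PLS
calibration predicts held-out leaf N with R² = 0.85 and under 4 % mean
relative error — a "good" grade on the published scale — and the best
difference index pairs a red-edge band with a nearby NIR reference,
reaching R² = 0.47, clearly below the full-spectrum calibration: two bands
carry far less N information than ten latent factors.

Or from the shell:

```bash
leafnir run --seed 1 --outdir runs/demo
column -s, -t runs/demo/comparison.csv | head
```

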