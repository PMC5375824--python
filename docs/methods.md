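# Methods

`leafnir` implements a complete in-field visible/near-infrared calibration
analysis for leaf nitrogen in pear, from spectra to ranked models. Because
no public spectral library of this kind exists, the package ships a
synthetic-data generator whose defaults encode the study conditions the
analysis assumes; everything downstream is tested against it.

## The measurement model

A leaf measurement is a reflectance-like vector on a 350–2500 nm grid at
1 nm (2151 bands). Three geometries are modelled:

* **black background** — leaf-clip measurement against a light-trap
  backing: absolute reflectance, values in [0, 1];
* **white background** — the same clip with a white backing, so light
  transmitted through the leaf is re-reflected and adds to the signal
  (transflectance). The offset is non-negative and concentrated in
  800–1300, 1550–1850 and ~2200 nm, values ≤ 1.5;
* **solar 25°** — bare-fibre measurement under sunlight: large-variance
  noise inside the atmospheric water-vapour windows (1350–1460, 1790–1970,
  2350–2500 nm) and a depressed 2000–2500 nm region. The windows are fixed
  at standard field-spectroscopy values.

## The synthetic leaf spectrum

The noise-free black-background spectrum is an analytic closed form — a sum
of a visible baseline, a Gaussian green peak at 550 nm, a logistic red edge
rising to an NIR plateau (~0.47), a linear SWIR taper, Gaussian water wells
at 1440 and 1900 nm (plus the 2500 nm tail), and Gaussian absorption wells
whose depths grow linearly with leaf N: chlorophyll features at 450 and
680 nm and protein features at 1510, 1690, 2150 and 2180 nm. The red-edge
inflection also shifts red with N (0.6 nm per g/kg), the green peak shrinks,
and the NIR plateau brightens slightly (confined to the NIR by a Gaussian
gain around 1050 nm, so the SWIR protein region stays locally informative).
This is a deliberately simple, invertible stand-in for radiative-transfer
models: every term is documented, differentiable in N, and re-evaluated
independently by the test suite. All N→optics couplings are configurable
linear gains and can be zeroed to build planted-signal fixtures.

### Nitrogen distribution

Five fertilization treatments N0–N4 with leaf-N means
25.4 + {−4, −2, 0, +2, +4} g/kg and within-treatment SD 1.0 g/kg, so the
pooled distribution has mean 25.4 g/kg and SD 3.0 g/kg; draws are clipped
to [17, 36] g/kg. The default library is 5 treatments × 3 trees × 12
leaves × 2 sampling times (50 and 80 days after full bloom) × 2 years
= 720 leaves.

### Noise and nuisance structure

Defaults (all free parameters of the generator, in reflectance units unless
stated):

| parameter | default | emulates |
|---|---|---|
| additive band noise SD | 0.008 | detector noise |
| multiplicative SD | 0.01 | illumination/contact variation (per spectrum) |
| latent N SD | 1.1 g/kg | biochemical mismatch between optics and the CHN reference |
| water content SD | 12 % | leaf water status (scales both water wells) |
| structure SD | 0.025 | leaf thickness/structure (NIR plateau amplitude) |
| smooth drift SD / scale | 0.015 / 80 nm | baseline drift, surface effects |

Two of these are load-bearing. The *latent N* term makes spectra respond to
an effective N rather than the chemical reference, bounding any
calibration's validation R² near 1 − (1.1/3.0)² ≈ 0.87 — the accuracy
regime in-field calibrations actually occupy. The *structured nuisances*
(water, structure, drift) create dominant variance directions unrelated to
N: on the default library the N-specific directions rank around PC 12–15,
which is why principal-component regression truncated at the conventional
"80 % of variance" cut (11 PCs) reaches only R² ≈ 0.4 while PLS, which uses
the response when extracting factors, reaches ≈ 0.85. The generator does
not attempt PROSPECT-level fidelity, canopy geometry, or specular effects;
passing tests demonstrate the *relative* behaviour of the methods under
these conditions, not absolute field accuracy.

## Pre-treatment chain

Ratio to the white reference → replicate averaging (two points × five
scans) → atmospheric-window masking (solar mode only) → Hotelling-T²
outlier screen → unit-vector normalization → random calibration/validation
split. Every removal and constant is logged in a `PretreatmentRecord`.

The screen centres the spectra, takes the first k = 5 principal components
and flags samples whose T² exceeds the (1 − α) quantile of
k(n−1)/(n−k)·F(k, n−k) at α = 0.005; a configurable cap (default 5 % of
the set) turns a mass removal into an error. The screen runs on the *raw*
spectra, before normalization: gross measurement failures are
predominantly scale anomalies, and unit-vector normalization — which is
applied precisely because it removes per-spectrum scale — would otherwise
hide them. "Normalization" is pinned to the unit Euclidean norm over
unmasked bands; it is idempotent and scale-invariant, which is the property
replicate merging needs. The split is plain uniform sampling without
stratification; the default takes 600 of the ~710 screened samples for
calibration.

## Calibration engines

All four are implemented in `leafnir.calibrate`; an established PLS
implementation is used in the test suite only, as an independent
cross-check.

**PCR.** Mean-centre, project onto leading PCs, ordinary least squares on
the scores, fold back to per-band coefficients. The pipeline default keeps
the smallest PC set reaching 80 % cumulative variance (capped at 30).

**PLSR.** PLS1 by NIPALS on mean-centred data (no autoscaling — spectra
are already normalized upstream). The factor count (cap 20) minimizes the
exact leave-one-out RMSE, with a one-standard-error tie-break toward fewer
factors (delta-method SE of the RMSE at the minimum). LOO is computed on an
SVD-compressed copy of X: PLS1 predictions depend on the training rows only
through their Gram matrix, and rows of every leave-one-out subset stay in
the full row space, so replacing X by X·V (V from the SVD of X) changes no
fitted or held-out value while reducing the per-fold cost from O(np) to
O(n²) per factor. A brute-force n-refit oracle verifies the equality.

**SMLR.** Greedy forward selection over bands: at each step the band with
the largest incremental explained variance enters, gated by its partial-F
p-value (default p ≤ 0.05, max 15 terms); entered bands are never removed;
near-collinear candidates (residual norm below 1e-10 of the original) are
skipped. Selection uses an orthonormalized basis so each step is O(np).

**BPNN.** PCA first; the smallest PC set carrying at least the variance
target (pipeline default 0.85) feeds a single sigmoid hidden layer with a
linear output, trained by full-batch gradient descent with momentum
(learning rate 0.1, momentum 0.9, target MSE 1e-4 on the standardized
scale, 500 iterations) on standardized scores. Each hidden size in
{3, 5, 8, 12} is trained from 10 random initializations and the network
with least RMSE on an internal 20 % hold-out is kept. Transfer functions,
rates and stopping values are assumptions surfaced in the configuration;
they are not prescribed by any reference.

Degenerate-limit identities used as tests: full-component PCR ≡ OLS; PLSR
at full factors ≡ OLS on full-rank problems; PLSR recovers noiseless linear
targets exactly; the first PLS weight is the normalized X'y direction.

## Two-band index search

DSI(λ₁,λ₂) = R₁ − R₂, RSI = R₁/R₂, NDSI = (R₁−R₂)/(R₁+R₂), the standard
remote-sensing forms. The reduced-sampling search reads reflectance at
10 nm intervals (216 bands over 350–2500 nm), regresses N on the index for
every *ordered* pair (RSI is order-sensitive) and records R² = squared
Pearson correlation. Degenerate pairs (constant or non-finite index) are
NaN-masked; ties break toward the lexicographically smallest pair; the R²
matrix exports as a labelled table and optional contour plot. DSI/NDSI
matrices are symmetric because R² is invariant under a sign flip of the
regressor; the full three-kind search at n ≈ 710 runs in a few seconds.

## Evaluation

R² is the squared Pearson correlation of predicted vs measured N (equal to
1 − SS_res/SS_tot for training fits with intercept); RMSEC/RMSEV are on the
g/kg scale, which is stated explicitly because transformed-scale RMSEs are
not comparable. Mean relative error is 100·mean(|ŷ−y|/y). Calibration
grades follow the published rule of thumb: R² > 0.91 excellent, 0.82–0.91
good (both boundaries closed into "good" — the source prose leaves them
open), else below good. `compare_methods` ranks reports by validation R²
then RMSEV and flags overfitting when calibration R² exceeds validation R²
by more than 0.1. A quadratic polynomial fit of per-treatment yield on
mean leaf N (`polyfit_n_yield`) supports the agronomic threshold question;
the generator produces no yields, so callers supply them.

## Pipeline and reproducibility

`run_pipeline` executes both probe modes (black/white backgrounds): 720
simulated leaves per mode, 10 planted gross outliers (×3 scaling, emulating
measurement failures — the screen then reproduces the 720 → ~710 sample
flow), pre-treatment, the four fits, the three index searches, and a ranked
comparison table. One global seed fans out to per-stage child seeds via
`numpy.random.SeedSequence`, so a run is byte-reproducible and stages can
be re-run in isolation. A default two-mode run takes roughly a minute on
one CPU; problem sizes throughout (n = 720 per mode, 216-band searches,
LOO at n = 600) were chosen so the full analysis stays interactive.

## Known limitations

* The spectral shape is phenomenological; it cannot be used to study
  radiative transfer, canopy effects, or moisture chemistry beyond the
  built-in couplings.
* The latent-N ceiling is a single Gaussian term; real reference-method
  error is likely heteroscedastic.
* BPNN training is plain gradient descent; it is adequate for the small
  PC-score inputs used here but not a general-purpose network trainer.
* The solar mode is generated but the calibration comparison focuses on
  the two probe modes, mirroring the low signal-to-noise of sun-lit
  bare-fibre measurements rather than attempting to repair it.
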