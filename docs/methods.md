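# Methods

`actimpute` imputes missing intervals in minute-level actigraphy records. A
missing interval is a run of 30 or more consecutive zero counts (the usual
count-based nonwear heuristic). The package implements one learned imputer —
a zero-inflated denoising convolutional autoencoder (ZI-DCAE) — three
classical baselines, the preprocessing and corruption protocol used to
evaluate them, and the evaluation statistics themselves. Because the
interesting behaviour of all of these depends on the statistical structure of
activity counts, the package also ships a synthetic actigraphy generator that
serves as its test bed.

## Data model and preprocessing

A record is one subject-day of nonnegative counts at one-minute epochs:
1440 values for a full day (minute 0 = local midnight), 720 after extraction
of the 9 AM – 9 PM waking window (positions [540, 1260), 0-based half-open —
all coordinates in the package follow this convention). Only *complete*
records — no ≥30-minute zero run over the full day — enter the pipeline, so
that reconstruction error can be scored against known truth. Evaluation-time
corruption overwrites one uniformly-placed interval of L ∈ {30, 90, 180}
minutes with zeros and records the positions in a boolean mask
(I_ij = 1 ⇔ cell imputed). Completeness is judged on the full day by default
(records are selected before windowing); a window-only scope is available for
data that never had night coverage.

Triaxial samples are combined as the magnitude vector √(x²+y²+z²); streams
at higher rates are downsampled by per-minute averaging, and partial minutes
at a day boundary are rejected rather than padded (whole-day records only).
Zero-run detection uses exact equality to zero: device counts are integers,
so equality is well defined even though values are stored as floats.

## The autoencoder

The ZI-DCAE is a ten-layer 1-D convolutional autoencoder. The encoder is
five valid (no-padding) convolutions whose channel count doubles 8 → 128
while the temporal length falls 720 → k; the decoder is the transposed
mirror (same filter sizes and strides in reverse) and lands back on exactly
720. For the reference geometry (first filter m = 30, latent length k = 60):

    encoder  8×30 s2 → 16×20 s2 → 32×10 s2 → 64×10 s1 → 128×10 s1
    lengths  720 → 346 → 164 → 78 → 69 → 60

Valid convolution maps L → ⌊(L − f)/s⌋ + 1 and transposed convolution maps
L → (L − 1)s + f, so the decoder inverts the encoder length-for-length only
when every strided layer satisfies (L − f) mod s = 0. For grid cells other
than (30, 60) no published geometry exists; a deterministic staged solver
keeps the early layers at the reference pattern and adjusts trailing layers
(first {4,5}, then {3,4,5}, then {2..5}), searching filter-ascending then
stride-ascending under the divisibility constraint, and returns the first
chain that reaches k exactly. These reconstructed geometries are well-formed
but are our own choices, not reproductions.

Inputs are min–max normalized to [0, 1] by a single scale learned from the
training set (minimum taken as 0 since counts are nonnegative; values above
the scale are clipped to 1 at inference), then every position inside the
missing interval is overwritten with the token 0.5. A global rather than
per-record scale keeps the token's meaning consistent across records.

Batch normalization and tanh follow every layer except the last, which
applies a *clamped tanh*, max(0, tanh(x)), with no batch normalization
(normalizing the output would destroy its exact point mass at zero). The
clamped tanh is what makes the model zero-inflated by construction: negative
pre-activations collapse onto exactly 0, so the reconstruction can place
probability mass on zero counts without any parametric zero model.

Training minimizes the RMSE between the reconstruction and the normalized
uncorrupted record over the *whole* record (imputed and observed parts), so
the network learns simultaneously to copy observed structure and to fill the
gap. Each epoch corrupts every training record with a fresh seeded random
interval (the denoising-autoencoder convention); validation corruption is
fixed once by seed, and the weights with the best validation partial RMSE
are kept (early stop on patience). Optimization is Adam. All of the
optimizer settings are exposed in `TrainConfig`; none is prescribed by the
method itself. Defaults: learning rate 10⁻³, batch size 32 (small batches
matter — at desk-scale record counts a large batch starves the optimizer of
steps within a modest epoch budget), patience 30 epochs (the validation
curve typically shows an early dip and a hump while the batch-norm running
statistics settle, so an aggressive patience aborts prematurely; with
best-weight tracking a patient stop is safe).

The network and its backpropagation are implemented directly in numpy
(float32, im2col + BLAS matmul); the gradient of every layer is verified
against central differences in the test suite. Hyperparameter selection over
m ∈ {20, 30} × k ∈ {40, 60, 80} uses seeded record-level 10-fold
cross-validation on the training set, selecting the cell with the lowest
mean held-out partial RMSE.

Imputation splices the denormalized reconstruction into the masked cells
only; observed cells pass through bit-identical. Imputed counts are left
continuous (fractional counts are fine for the error metrics). A model
checkpoint is a single `.npz` file holding weights, geometry, normalization
scale and seed.

## Baselines

**Mean imputation** replaces a masked cell at minute t with the mean of the
valid (unmasked) values at t across reference records. In the experiment
protocol the reference is the training split for the primary dataset and the
evaluation dataset itself for external datasets (the external-validation
convention: reference-free imputers are rebuilt per dataset without a
train/test split).

**MICE** (multiple imputation by chained equations) initializes every masked
cell with the per-minute mean, then cycles over minute positions, regressing
each position on its n_lead preceding and n_lag following minutes (current
completed values) across records, re-filling the masked cells from the
fitted regressor; after n_cycles sweeps the n_imputations completed datasets
are combined by the per-cell mean. Defaults: lead/lag 5 + 5 minutes, 5
cycles, 5 imputations — reasonable conventions, all configurable; boundary
positions use truncated covariate windows rather than discarding edge
minutes. With zero cycles the procedure degenerates exactly to mean
imputation.

Two regressors are provided:

* *Zero-inflated Poisson* (ZIP): P(0|x) = π + (1−π)e^{−λ},
  P(y>0|x) = (1−π)·Pois(y; λ), with logit π = x·γ and log λ = x·β, fitted by
  direct maximum likelihood (L-BFGS with the analytic gradient; warm-started
  across MICE cycles). A masked cell receives the expected count (1−π̂)λ̂.
  Because that point prediction is deterministic given the completed data,
  the n_imputations chains are identical and only one is computed. Inside
  MICE the covariates are standardized per position before fitting — the log
  link is badly conditioned on raw thousand-count scales — and predictions
  are capped at the largest observed response for that position, preventing
  the exponential link from extrapolating beyond the data. If the optimizer
  fails, the position falls back to a plain Poisson regression (π = 0); an
  all-zero response yields the degenerate fit π̂ = 1.

* *Bayesian linear regression*: conjugate normal–inverse-gamma posterior
  with a weakly-informative zero-mean prior whose precision doubles as a
  ridge term (posteriors stay proper for singular designs). Masked cells are
  filled with seeded posterior-predictive draws; negative draws are clamped
  to zero since counts are nonnegative.

## Evaluation statistics

With X the original and X′ the imputed record set, and I_ij = 1 marking
imputed cells,

* partial RMSE = √( Σ_ij I_ij (X_ij − X′_ij)² / Σ_ij I_ij ) and partial MAE
  analogously — reconstruction error over imputed cells only;
* RMSE of an aggregate A: √( (1/M) Σ_i (A_i^origin − A_i^imputed)² ) across
  the M records, for A ∈ {sample SD, intradaily variability, MVPA minutes
  inside the missing interval};
* intradaily variability IV = [N Σ_{j≥2} (X_j − X_{j−1})²] /
  [(N−1) Σ_j (X_j − X̄)²], the nonparametric circadian fragmentation index
  (≈2 for white noise, small for smooth series). A constant record has
  undefined IV; such records are flagged and excluded from the aggregate
  RMSE with M reduced accordingly (warned, never silently);
* MVPA minutes by the 10-minute bout rule: scanning left to right, a
  10-minute window with at least 80% of values above the intensity cutoff
  credits 10 minutes and the scan jumps past it (greedy, non-overlapping);
  otherwise the scan advances one minute. The cutoff is keyed to the device
  type: 1267 counts/min for uniaxial data, 2691 counts/min for triaxial
  magnitude data. "Over 80%" is implemented as ≥ 0.8 (8 of 10 qualifies),
  the common operationalization; a strict-> mode is available.

SD uses the N−1 divisor (configurable). SD and IV are computed over the
720-minute window, since full days are discarded earlier in the pipeline.
All of these statistics are checked against independent naive-loop oracles.

## Synthetic data generator

The generator emulates the structure that makes imputation of activity
counts both hard and possible:

* a diurnal base intensity μ(t): trough ≈ 5 counts/min before 6 AM, linear
  ramps, plateau 800 counts/min between 9 AM and 9 PM;
* time-varying structural-zero probability π(t) (0.8 at night, 0.35 in the
  waking window), realized through a thresholded AR(1) Gaussian copula with
  ≈8-minute correlation time, so zeros form clustered sedentary runs with
  the exact marginal π(t) rather than salt-and-pepper noise;
* smooth within-day intensity modulation: a unit-mean lognormal AR(1)
  process (log-SD 0.6, ≈30-minute correlation time) multiplying μ(t) —
  activity is bout-structured and strongly autocorrelated at the minute
  scale;
* lognormal between-subject heterogeneity (log-SD 0.4, unit mean);
* conditional counts: negative binomial around the latent intensity with
  size r = 5 — mildly overdispersed given the behavioural state, with the
  bulk of the *marginal* overdispersion carried by the behavioural process
  itself. This allocation matters: if all marginal variance were white
  conditional noise, no context-using imputer could beat the per-minute mean
  even in principle;
* injected MVPA bouts: Poisson(1.5)/day contiguous 10–20-minute episodes at
  ≈2500 counts/min inside the waking window;
* an optional completeness guarantee that interrupts any ≥30-minute zero run
  (on by default), so generated records survive the completeness filter.

Defaults were calibrated once against the marginal scale of population
waist-worn uniaxial actigraphy — overall mean within 10% of 344 counts/min,
SD/mean around 2, lag-1 waking-window autocorrelation above 0.5 — and the
test suite checks those three properties on freshly generated data.
What the generator does *not* emulate: multi-day rhythms and weekday
structure, device saturation, posture-specific count signatures, covariance
between demographics and activity, and real nonwear behaviour (its zeros are
behavioural, with nonwear injected only via the corruption protocol). Tests
passing on this generator show the machinery is correct and that the
learned imputer can exploit realistic temporal structure; they do not
certify effect sizes on any real dataset.

`generate_zip_table` draws i.i.d. zero-inflated Poisson counts and exists as
a fixture for the ZIP-fitting tests, where method-of-moments inversion of
the ZIP mean and zero-mass formulas provides an independent oracle.

## Experiment protocols

`run_experiment` wires the stages together: preprocess → seeded split
(default 90% train / 10% test, with 10% of train held out for validation;
by-record by default, subject-disjoint optionally) → fixed seeded corruption
of the evaluation sets → per-method imputation → metrics. The autoencoder is
trained once on the primary dataset and applied to external datasets without
retraining; baselines are rebuilt per dataset. `finetune_protocol` splits a
new dataset 9:1:1, continues training from the pre-trained weights with
early stopping on the new validation split (keeping the pre-training
normalization scale so counts remain comparable), and reports test metrics
for the baseline and fine-tuned models side by side.

Every stage derives its randomness from explicit integer seeds; identical
seeds give bit-identical datasets, splits, corruption, initialization and
trained weights.

## Numerical choices and limitations

* Problem sizes in the test suite are scaled down (hundreds to a couple of
  thousand records, tens of training epochs) — chosen so the full suite runs
  comfortably on a single CPU while the ordering results remain stable.
* The RMSE loss gradient is skipped for an exactly-zero batch loss
  (degenerate but possible on constant toy data).
* ZIP likelihood evaluations clip the log-link at ±30 for overflow safety.
* Non-convergent ZIP fits fall back to Poisson; fully-masked positions
  (no observed data anywhere) are an error, as is a mean-imputation position
  with no valid data.
* The comparison of imputers on synthetic data is a qualitative check of
  ordering under realistic structure, not a reproduction of any published
  effect size; published real-data error magnitudes depend on the source
  datasets, which this package deliberately does not ingest.
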