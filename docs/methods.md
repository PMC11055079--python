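# Methods

## Problem setting

Livestock barns are instrumented with environmental sensors — indoor
temperature (°C), relative humidity (%), CO₂, NH₃ and H₂S (ppm), and an
outdoor weather station adding solar irradiance (W/m²) and a per-day
accumulated solar series — sampled every 5 minutes.  The stream is
unlabelled; faults (sensor glitches, ventilation failures, data-link
drops) must be found without supervision.  TimeTector treats anomaly
detection as a reconstruction problem: a model trained to reproduce normal
windows will reproduce anomalous samples badly, and the reconstruction
error becomes the anomaly score.

## Model

One forward pass over a window X ∈ R^(L×F) (L = 24 steps ≈ 2 h, F sensors):

1. **Shared encoder.**  Two stacked LSTM layers (width d_model = 64) map the
   window to a hidden sequence H = [h₁ … h_L].  The standard gated cell is
   used: input/forget/output gates and a tanh candidate, zero initial state.
2. **Attention phase.**  Four mechanisms refine H in parallel, each with its
   own projections Q = H·W_Q, K = H·W_K, V = H·W_V split into 8 heads of
   depth D_k = 64/8 = 8 and scored with softmax(QKᵀ/√D_k)V:
   * *standard* multi-head self-attention;
   * *hierarchical* — 4 stacked layers; each layer's output is the next
     layer's query source while keys and values remain those of layer 1;
   * *cross* — keys and values come from an external sequence; here two
     extra learned projections of the encoder output supply them, and the
     self-attention output (same parameters) is added elementwise (the
     combination is toggleable via `cross_add_self`);
   * *feature-enhanced* — an auxiliary matrix F (a learned projection of H;
     the API accepts any timestep-aligned matrix) is projected by W_F and
     added to Q, K and V before scoring; 4 stacked blocks, each re-adding
     its own projection of the same F.
   No positional encoding, dropout or masking is used anywhere, so
   self-attention is permutation-equivariant over timesteps — a property
   the tests exploit.
3. **Fusion and second encoder.**  The four outputs are concatenated
   (L × 256, fixed order: standard, hierarchical, cross, feature-enhanced)
   and summarised by a third LSTM layer; its final hidden state H_E ∈ R⁶⁴
   is the shared context of both branches.
4. **Twin branches.**  Reconstruction: H_E repeated L times → LSTM decoder
   (width 64) → per-timestep linear map to F features.  Prediction: relu
   dense (64) → linear dense → H future steps (H = 1 by default; the
   horizon is configurable and logged in every run).

## Training objective

Inputs are corrupted copies x̃ = x + ε, ε ~ N(0, 0.1²) in scaled units;
targets stay clean (denoising autoencoder).  The loss is

    L = 1.0 · MSE(X, X̂) + 0.5 · MSE(X_future, Ŷ) + 0.001 · Σ‖W‖²₂

with the L2 penalty on all LSTM kernels (input and recurrent), reported
separately in the feedback log.  An alternative reduction summing unsquared
per-timestep L2 norms is available behind `loss_reduction="sum_norm"` but
MSE drives the gradients by default.  Optimisation is Adam (lr 1e-3, the
library default; the rate was never part of the published configuration),
batch size 32 (24 is the other sanctioned value), at most 20 epochs with
early stopping after 4 epochs without validation improvement and
restoration of the best-validation weights.  With corruption noise set to
zero the objective degenerates to a plain autoencoding + forecasting loss.

The **feedback log** records, per epoch, the mean reconstruction and
prediction error of every feature plus the train/validation loss
trajectory, mirroring how training dynamics are monitored feature by
feature during a study run.

All network arithmetic is float32 (the conventional precision for this
model class; it also halves memory traffic on the CPU training loop).  The
autodiff tape preserves float64 when analysis code passes float64 arrays,
which is what the attention-identity tests do.  The sequential LSTM time
loop runs through a numba-compiled kernel when numba is installed; the
pure-numpy loop remains as the reference and fallback path, and both are
held to the same finite-difference gradient checks.  Weight initialisation
is Glorot-uniform with the forget-gate bias opened at 1.0, all seeded.

## Preprocessing

Chronological 80/10/10 split (floor sizes; remainder rows go to the test
segment so concatenation always restores the input).  Min–max scaling to
[0, 1] is fitted on the training segment only; validation/test values may
leave the unit interval and are never clipped.  A constant training column
maps to the low end of the range and inverts back to the constant.
Sliding windows use stride 1; corruption is applied after scaling (the
0.1 noise sd is only meaningful on the unit scale) and touches only the
input copies — windows, targets and validation inputs stay clean.

## Detection

Per-timestep, per-feature anomaly score: squared reconstruction error
(x − x̂)², averaged over every sliding window covering the timestep.  The
cutoff is the dynamic threshold

    threshold_t = rolling_mean_t + k · rolling_std_t

over a trailing window of w scores, with the *population* standard
deviation (either convention is defensible; one is fixed and tested).
Defaults w = 288 (one day at 5-minute cadence) and k = 3 are package
choices — the published description fixes neither — and both are recorded
in every report.  The first w−1 positions reuse the first defined
threshold rather than going unscored.  A sample is anomalous when its
error *strictly* exceeds the threshold; thresholds are per-feature.
Flags are invariant to affine rescaling of the error series, and the
anomaly count is non-increasing in k — both tested properties.

## Synthetic barn data

The real barn streams are proprietary, so the `simulate` module generates
series with their documented structure; its defaults are the package's
study conditions and are not tuned per experiment:

* per feature: base level + 24 h sinusoid (afternoon peak) + AR(1)
  residual (φ = 0.8) with innovation sd ≈ 5% of the diurnal amplitude —
  e.g. indoor temperature 22 ± 3 °C with 0.15 °C innovations;
* humidity carries no sinusoid of its own; its diurnal swing enters
  through an explicit negative linear coupling to the temperature anomaly
  (−2.5 %RH/°C), reproducing the strong observed anticorrelation;
* gases are clipped at zero (physical floor);
* outdoor solar is zero at night, a half-sine between 06:00 and 18:00,
  and accumulated solar is its within-day running sum, resetting at each
  day boundary — the characteristic step-like daily pattern;
* anomalies are injected per cell with ground-truth labels: spikes and
  level shifts add `magnitude · σ̂` where σ̂ is the feature's clean
  residual sd (estimated by removing the mean daily cycle), `stuck_at`
  freezes the series, `noise_burst` multiplies the local noise sd.  For a
  freeze the whole event span is labelled anomalous even though the first
  sample numerically equals its clean value.

What the generator does **not** emulate: weather fronts and multi-day
trends, heteroscedastic sensor drift, cross-gas dynamics, irregular or
missing timestamps, and realistic fault shapes of specific hardware.
All channels also share a single diurnal phase, so cross-channel
correlations come out far stronger than in real barns, where only the
temperature–humidity pair is reliably strong.
Passing the synthetic recovery tests therefore demonstrates that the
pipeline is mechanically sound and can separate large point faults from a
smooth diurnal background — not that these operating points transfer to
any particular barn.

## Labelled evaluation protocol

Spikes (1% of cells, 8σ̂, random sign) are injected into the *test*
segment only; training and validation stay clean.  This mimics annotating
a held-out portion of an otherwise unlabelled stream and keeps the
denoising objective honest.  Detection quality is scored per cell
(precision, recall, F1, accuracy; anomaly = positive class), ROC/AUC uses
the error as score, and reconstruction quality is the per-feature R² of
the averaged reconstruction against the clean validation series (R² is
scale-invariant, so scaled units are used).  Degenerate metrics (nothing
flagged, no positives, zero variance) are reported as `None`, never as
silent NaN.

## Problem sizes used by the shipped checks

The end-to-end checks simulate 20 days of 5-minute indoor data (5,760
rows; 4,583 training windows), train for at most 20 epochs with patience
4, and average three seeds; the acceptance script runs the same study at
one seed.  These sizes were chosen as the smallest runs at which the
detector's behaviour is stable seed-to-seed.  Typical results there:
spike recall and precision well above 0.9, mean validation reconstruction
R² ≈ 0.98, mean AUC ≈ 1.0, per-feature flagged rates of 0.5–2%.
Determinism is bit-exact for a fixed seed on a fixed machine (a single
BLAS thread; summation order changes across thread counts).

## Numerical and design notes

* The attention-score scaling divides by √D_k exactly once; a dedicated
  test guards against double scaling.
* One published equation writes the attention output without the key
  matrix; the implementation follows the unambiguous score/softmax
  definitions (QKᵀ scores), treating that line as a typo.
* The per-mechanism layer counts follow the published table (0 — meaning
  a single application — for standard and cross, 4 for hierarchical and
  feature-enhanced).  No layered form is defined anywhere for the
  feature-enhanced variant; stacked blocks that re-add the projected
  features are the implemented reading.
* Each mechanism owns independent projection matrices; nothing in the
  source material indicates parameter sharing across mechanisms.
* The two shared encoders do not share weights with each other; each is
  shared across both branches.
* `stuck_at`/`noise_burst` conventions and the warm-up rule for the first
  rolling window are package decisions, documented above.
* Checkpoints are single `.npz` archives holding every weight plus the
  JSON-encoded configuration; loading cross-checks shapes and feature
  counts and reproduces forward outputs bit-identically.

## Known limitations

* Training is single-process and CPU-bound; ~13 s per epoch at the 20-day
  study size.  The architecture is small by design and the
  budget suffices, but very long series would need window subsampling
  (`stride > 1`).
* The dynamic threshold is causal but not adaptive to regime changes
  faster than w; a fault burst longer than the rolling window inflates
  the local statistics and can mask later faults in the same window.
* H = 1 forecasting is a one-step-ahead convenience; multi-step horizons
  are supported but unexplored.
* With anomaly rates far above a few percent the clean-residual σ̂
  estimate and the scaler would both be contaminated; the pipeline
  assumes anomalies are rare.
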