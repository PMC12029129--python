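# Methods

`nmrquant` studies how well neural networks can quantify metabolite
concentrations directly from 1D ^1^H-NMR spectra of complex mixtures. Because
a supervised quantifier needs far more labelled spectra than any wet-lab
campaign can supply, the package is built around a simulator: reference
spectra of individual metabolites at 1 mM are combined at known
concentrations, distorted with experiment-like variation, and used to train
and evaluate three architectures. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic data do
and do not establish.

## Spectrum model

**Grid.** All spectra live on a shared uniform chemical-shift axis; the
working region is −0.32 to 10.21 ppm with 46,000 points (index 0 at the low
ppm end). Shift arithmetic is done in ppm, couplings and linewidths in Hz,
converted through the spectrometer frequency `f` in MHz (1 ppm = `f` Hz).

**References.** A metabolite's reference spectrum is a sum of absorption-mode
Lorentzians: each chemical environment contributes a first-order multiplet
(singlet/doublet/triplet/quartet with binomial intensity ratios, line spacing
`J` Hz, default FWHM 1.0 Hz). The total area of a multiplet equals
`n_protons × UNIT_PROTON_AREA`, with one global proportionality constant for
the whole library, so integrals encode stoichiometry at the nominal 1 mM.
Lines whose centers fall outside the grid are dropped with a warning (no
wrap-around). Second-order (strong-coupling) distortions are deliberately out
of scope: modelling them requires a quantum-mechanical spin simulator, and
nothing downstream depends on them. Glucose is represented by one combined
reference built from the two anomer references at the aqueous equilibrium
weights 0.36 (alpha) / 0.64 (beta).

**Synthetic libraries.** `default_library(n)` generates reproducible panels
of `n` metabolites (8/44/86 are the standard sizes) that emulate the
statistical structure of real small-molecule spectra: 1–4 multiplets per
metabolite, 1–6 protons per multiplet, J between 2 and 12 Hz, 75% of
resonances crowded into the aliphatic 1–4.5 ppm band and the rest spread over
0.5–9.5 ppm, at least one deliberately overlapping pair for panels of 8+, and
the 9-proton TSP-d4 singlet at 0.0 ppm attached as a non-analyte internal
standard. Placeholder names (`met000`, ...) are used; name parity with any
real metabolite panel is cosmetic and irrelevant to the learning problem.

## Concentration distributions

Concentrations span 0.005–20 mM, the range of aqueous tissue extracts on a
400-MHz instrument. Five samplers are provided:

| kind | definition |
|---|---|
| `uniform` | U(0.005, 20) mM |
| `low_concentration` | even mixture of U(0.005, 0.05), U(0.005, 0.1), U(0.005, 0.2) |
| `mimic_tissue` | 0.75·LogNormal(ln 0.15, 1.0) + 0.25·LogNormal(ln 3.0, 0.8) |
| `high_dynamic` | 0.45·Gamma(1.2, 0.3) + 0.35·Gamma(2.0, 1.5) + 0.20·U(0.005, 20) |
| `combined` | each spectrum assigned one of the four above with probability 1/4 |

The exact log-normal/gamma parameters are package defaults chosen once to
satisfy the documented shape constraints — for `mimic_tissue`, ≥70% of mass
below 1 mM with a tail reaching 20 mM; for the interference law below, mean
0.85 mM with ≥95% of mass under 5 mM — and are user-overridable. Draws are
clipped (not resampled) to the configured range; with defaults the clipped
mass is below 2% (asserted in tests). The `combined` sampler assigns the
source per spectrum, not per analyte, so each mixture is internally coherent.
An "extended range" option raises the ceiling to 24 mM for training-time
range extension experiments. Leave-out schemes zero a random subset of
analytes: `all_present` (none), `half50` (half the spectra keep everything,
the other half drop each analyte with probability 0.5; overall presence 75%)
and `tiered` (thirds at presence 1 / 0.5 / 0.25; overall 58.3%).

## Mixture simulation and augmentation

A mixture is `Σ c_i · reference_i + 0.3 mM · TSP`. The augmentation chain,
applied per spectrum in this fixed order (the order is a package choice;
shifts must precede summation to be per-analyte):

1. **Chemical-shift jitter** — each analyte's reference is translated by a
   uniform draw in ±3.4 ppb, realized as the nearest integer number of grid
   points (≈0.229 ppb/point on the 46,000-point grid, so at most 15 points).
   Sub-point interpolation is rejected because it distorts the lineshape; the
   residual quantization error is ≤0.12 ppb. The TSP reference is never
   shifted — it defines the 0.0-ppm origin.
2. **Line broadening** — one exponential apodization per spectrum, lb ~
   U(0, 1) Hz: inverse FFT to a synthetic FID, multiplication by
   exp(−π·lb·|t|), FFT back. This convolves with a Lorentzian of FWHM lb,
   conserves the integral exactly (the first FID point is untouched) and can
   only lower peak heights. Broadening is per spectrum, not per analyte (a
   single receiver-side apodization is what an experiment would apply).
3. **Interference singlets** — k ~ U{0,1,2,3} generic one-proton Lorentzian
   singlets at uniform random chemical shifts, each scaled by a gamma draw
   with mean 0.85 mM (mostly < 5 mM), emulating unassigned signals.
4. **Noise** — i.i.d. Gaussian with σ = fraction × σ_ref, fraction ~
   U(0.30, 1.15). σ_ref defaults to 7.64 a.u. at 400 MHz, set so that a 1 mM
   nine-proton singlet of 1 Hz width has SNR ≈ 300 (the order of magnitude of
   a modern spectrometer; the analytic peak height of that singlet is
   9·2·400/π ≈ 2292 a.u.). At other field strengths the noise is multiplied
   by (400/f)^{3/2} — SNR scales with the 3/2 power of frequency — giving 8×
   noise at 100 MHz and ÷2.8 at 800 MHz.
5. **Baseline** — a constant offset, uniform in ±5.6% of the in-spectrum TSP
   peak height.

Datasets are normalized by a single dataset-wide maximum (the constant is
stored in the manifest) and split 80:20 into training and validation. Ground
truth is recorded in mM before normalization. Everything is reproducible from
one seed. Two normalization modes exist for test sets: by the test set's own
maximum, or by a supplied (training) constant. The default is per-dataset,
but the headline workflow normalizes its 10-spectrum test set by the training
constant: the maximum of 10 spectra is a noisy scale estimate, and a deployed
quantifier would normalize incoming spectra on the training scale.

SNR is measured as the tallest peak height over the standard deviation of a
signal-free noise window (default 9.6–10.2 ppm), median-subtracted so a
baseline offset does not inflate the estimate; a noise-free spectrum reports
infinite SNR rather than an error.

## Models

All three architectures map a normalized spectrum vector to a concentration
vector in mM and are implemented on a small reverse-mode autodiff engine
written in numpy (`nmrquant.nn`): broadcast arithmetic, batched matmul,
dedicated 1-D convolution/pooling kernels, softmax, layer normalization and
multi-head self-attention, each verified against central finite differences
in the test-suite. Forward passes are vectorized over the batch and
deterministic given fixed weights (no dropout anywhere). Weights are
initialized fan-in-scaled uniform from an explicit seeded generator.

* **MLP** — affine–activation stack; baseline 46,000 → 200 → 44 with ReLU
  (9,209,044 parameters).
* **CNN** — blocks of 1-D convolution + ReLU (+ optional max/average
  pooling), flattened into a two-layer head; baseline: 4 blocks of 42 kernels
  (size 6, stride 2) with 2/2 max pooling, head 200 → 44. The flattened size
  is computed from the config at construction, never hard-coded, and
  geometries that collapse the spatial axis are rejected.
* **Transformer (encoder-only)** — the spectrum is split into contiguous
  bins (zero-padded at the high-ppm end if needed; 46,000/1000 → sequence
  length 46), each bin embedded by one shared linear layer, fixed sinusoidal
  positional encodings added, passed through post-norm encoder blocks
  (self-attention + feedforward, residual + layer norm), then **all**
  positions are flattened into the final linear head (no pooling — each bin
  carries distinct chemical-shift content). Baseline: bin 1000, embedding
  512, 1 layer, 1 head, feedforward 2048.

Six presets ship: the hand-chosen baselines (`mlp-base`, `cnn-base`,
`tx-base`) and the hyperparameter-search winners (`mlp-opt`: 2 hidden layers
222/463, LeakyReLU, lr 2.1e-3, batch 124, reg 9.4e-3; `cnn-opt`: 3 conv
layers, kernel 10, stride 4, 35 channels, no pooling, head 233, lr 2.1e-5,
quantile(0.5) loss; `tx-opt`: bin 500, embedding 512, 16 heads, 1 layer,
feedforward 512, lr 5.0e-4, batch 244, reg 9.6e-3). The optimized values are
shipped as presets, not asserted as reproducible search outcomes — they came
from 100-trial GPU-scale searches.

## Losses

Ten losses cover the high-dynamic-range regression problem (definitions in
`nmrquant.objectives`): RAE and RSE (errors normalized by the error of
predicting the batch-mean target — the batch mean is the standard choice, as
no formula is fixed by convention), MSE, quantile/pinball at q = 0.1/0.5/0.9
(q = 0.5 is exactly half the MAE), LogCosh (evaluated in the stable form
|x| + log1p(e^{−2|x|}) − log 2), MSLE, MAPE (always in percent), and a 50:50
MSE+MAPE combination in which each term is divided by its detached running
mean — raw MSE (mM²) and MAPE (%) are incommensurate, and without
standardization one term dominates. MAPE and MSLE require strictly positive
targets and reject offending indices; RAE/RSE reject constant-target batches.

## Training protocol

AdamW (decoupled weight decay, default regularization constant 0.01), with
each optimizer step's gradient accumulated over 4 sub-batches whose total is
the *effective* batch size (reported batch sizes are effective ones); for
mean-type losses the accumulated gradient equals the full-batch gradient to
1e-6, which the tests assert. For ratio-type losses (RAE/RSE) accumulation is
the standard practical approximation. Batches that do not divide the training
set leave a final short batch (used, not dropped). Early stopping: training
halts after 50 epochs without a new best validation loss, or at the
per-architecture epoch cap (MLP 5000, CNN 500, transformer 1000); the
returned checkpoint is always the best-validation one. No learning-rate
schedule. Seeds govern initialization and shuffling; runs are bit-reproducible
on a fixed platform.

## Evaluation

MAPE is computed per spectrum — relative errors averaged over analytes within
the spectrum first — then summarized as mean ± 95% Student-t interval over
test spectra (t rather than a bootstrap for determinism; a pooled-analytes
mode is also available). Test sets always contain every analyte so MAPE is
defined. Dataset-modification studies report per-spectrum MAPE normalized by
a baseline report on the same test set; a mean below 1 marks improvement.

## Hyperparameter search

`tune` runs seeded train+evaluate trials over the study's search ranges
(layer counts, kernel geometry, binning/embedding sizes; learning rate and
regularization log-uniform) with two pruning rules: a median rule (stop a
trial whose validation loss exceeds the median of earlier trials at the same
epoch) and threshold rules (CNN: loss > 5000 after 15 epochs or > 1000 after
100; transformer: > 1000 after 100 epochs — thresholds are loss-scale
configuration, and the boundary is strict). The search objective is mean MAPE
on a separate all-present validation set (pinball q = 0.5 for the CNN, which
overfits under a MAPE objective). The sampler sits behind a one-method
interface; the package ships seeded uniform random search, and any sequential
model-based sampler with the same `suggest` signature is a drop-in
replacement. The trial table is append-only and serializable; interrupted
searches resume from it, replaying the generator so a resumed search equals
an uninterrupted one.

## Desk-scale headline experiment

The full study trains on 20,000–250,000 spectra of 44–86 metabolites at
46,000 points. The package's reproducible headline experiment
(`workflows.scaled_headline`) keeps the complete pipeline but scales sizes to
a single CPU: an 8-metabolite library on an 11,500-point grid (same ppm
region at one quarter resolution), 5,000 fully augmented
uniform-concentration spectra (4,000 train / 1,000 validation), a compact
transformer (bin 250 → 46 positions, embedding 128, 4 heads, 1 encoder
layer, feedforward 256), RAE loss, AdamW at lr 1e-3, effective batch 64 (4 ×
16), patience 50, capped at 120 epochs. These problem sizes are the package's
chosen desk-scale protocol; the architecture keeps the 46-position sequence
of the full-scale design. Evaluation: mean MAPE over 10 freshly generated
all-present uniform test spectra, with the NNLS quantifier on the same
spectra as the classical baseline. Typical outcome at this scale: transformer
mean MAPE ≈ 1–3% depending on seed, NNLS ≈ 35% (shift jitter and line broadening break the exact
linear model that NNLS relies on; with augmentation disabled NNLS is exact to
machine precision, which the tests use as an end-to-end linearity oracle).

## Numerical choices and degenerate inputs

* Lorentzians are rendered analytically on the grid; at 46,000 points a 1-Hz
  line spans ~11 points. Coarser test grids use wider lines where a width or
  area is asserted.
* Line-broadening via FFT treats the spectrum as circular; edge effects are
  negligible because references place no lines at the grid edges.
* Gradient checks exclude the kinks of absolute-value losses
  (|p − t| < 10·eps) and use float64; training uses float32 end to end.
* Zero-noise SNR returns `inf` with no error; all-zero datasets cannot be
  normalized and are rejected; reversed grids, non-monotone ppm columns and
  non-numeric rows are rejected with the offending line number.
* `leave_out_mask` may produce all-zero spectra under `half50`/`tiered`;
  composition handles zero concentration vectors (TSP only).

## What the synthetic data do not show

The simulator emulates ideal first-order spectra with stationary chemical
shifts. It does not model pH-, temperature- or concentration-dependent shift
changes, metabolite–metabolite interaction shifts, residual protein/lipid
baselines, water suppression artifacts, or second-order multiplet
distortion. Passing tests therefore demonstrate that the pipeline learns and
generalizes within this idealized family of spectra; transfer to
experimentally acquired spectra would additionally require realistic shift
dependencies (or fine-tuning on measured spectra) and is out of scope.
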