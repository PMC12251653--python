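# Methods

`specshift` implements cross-instrument calibration transfer for quantitative
near-infrared (NIR) spectroscopy: a regression model is built on a *master*
spectrometer and adapted to a *slave* spectrometer whose readings of the same
samples differ systematically. This note documents the models, the synthetic
data, the numerical choices, and the places where the design was genuinely
open.

## The regression network

The reference architecture is a 1-D convolutional network operating on a
single-channel absorbance spectrum:

```
stem conv (1 -> 16, k=7)
-> RX-Inception block (16 -> 32, stride 2)
-> RX-Inception block (32 -> 64)
-> RX-Inception block (64 -> 100)
-> adaptive average pool (length P) -> dropout -> flatten
-> FC1 (100*P -> 100) -> ReLU  [the "features"]
-> FC2 (100 -> 1)              [the prediction]
```

Each RX-Inception block runs four parallel depthwise-separable branches with
kernel sizes M1–M4 (depthwise convolution of the block's input, pointwise
projection to a quarter of the output width, ReLU), concatenates them on the
channel axis, fuses with a pointwise convolution, recalibrates channels with
a squeeze-and-excitation (SE) gate (global average pool, bottleneck FC pair
with ReLU then sigmoid, reduction ratio 4), and adds a residual shortcut
(pointwise projection when channel counts differ, average pooling when the
block is strided).

Two stock configurations are provided:

| config   | M1–M4      | dropout | pool length P | FC1 input |
|----------|------------|---------|---------------|-----------|
| `corn`   | 3/5/13/3   | 0.0     | 256           | 25 600    |
| `tablet` | 5/9/15/3   | 0.5     | 25            | 2 500     |

Open wiring choices, resolved once and kept:

* **Block plan.** Three blocks with channels 16→32→64→100. The 100-wide
  final block is forced by the FC1 widths above; the count and intermediate
  widths are a design choice.
* **Downsampling.** Multi-scale "convolutional downsampling" is realised as
  stride 2 on *all four branches* of the first block, with average pooling
  on its residual path. Branch-specific strides are impossible here: the
  branches are concatenated channel-wise, so their lengths must agree.
* **Features for distribution alignment** are the post-ReLU FC1 activations.
* **SE placement**: after the pointwise fusion, before the residual add.

The network, its autodiff engine, and Adam are implemented on numpy
(float32 parameters by default, float64 available via
`ModelConfig(dtype="float64")`). Every operator's gradient is
finite-difference checked in the test suite.

## Input and target conditioning

Before entering the network, a spectrum is centred on the mean spectrum of
the master *training* split and divided by the global standard deviation of
those centred spectra; targets are z-scored on the same split. Both scalers
are learned in `pretrain`, stored in the network handle, applied inside
every forward pass, and inverted at prediction time. Rationale: in realistic
mixture spectra the target-relevant inter-sample variation (~10⁻²–10⁻³ a.u.)
sits on top of a large common absorbance structure; without centring, Adam
at learning rate 10⁻³ spends its budget re-learning the mean spectrum.
Because the *master* scalers are reused on the slave, instrument distortion
shows up as a large input shift — exactly the failure mode calibration
transfer addresses.

## The transfer objective

With source (master) features `Xs`, target (slave) features `Xt`, and model
outputs `Ys`, `Yt`, the distribution-adaptation terms are squared maximum
mean discrepancies,

    MMD²(A, B) = mean K(A,A) + mean K(B,B) − 2 mean K(A,B),

the biased V-statistic of the kernel mean-embedding distance (smooth at 0,
which matters under gradient descent). The fine-tuning objective is

    L = MSE + λ₁·MMD²(Xs, Xt) + λ₁λ₂·MMD²(Ys, Yt).

* **Kernel**: RBF, `k(x,y) = exp(−‖x−y‖²/2σ²)`. The bandwidth follows the
  median heuristic per batch (σ² = median pooled pairwise squared distance);
  a fixed bandwidth is available for exact tests. A linear kernel is also
  provided.
* **Weights**: `LossWeights` defaults to λ₁ = λ₂ = 1. The balance parameter
  is task-dependent by design; for the bundled corn-like benchmark the
  default is λ₁ = 0.1, chosen so the alignment terms (order 0.1–1) do not
  drown the task MSE (order 10⁻²–10⁻³) late in fine-tuning. Both are config
  knobs (`--lambda1/--lambda2`).
* MMD batches are drawn independently from each domain per step, equal batch
  sizes (truncated to the smaller domain), from separate random streams —
  so a λ₁ = 0 run retraces the no-adaptation trajectory bit for bit.

## The six transfer strategies

1. freeze everything (direct testing; zero steps);
2. fine-tune all layers;
3. retrain FC1 only; 4. retrain FC2 only; 5. retrain FC1+FC2;
6. retrain FC1+FC2 with the distribution-adaptation objective above.

Freezing is structural: the optimiser is constructed over the trainable
groups only, and frozen parameters additionally drop off the gradient tape
(which makes head-only fine-tuning ~3× cheaper). Frozen groups are
byte-identical before and after any number of steps.

Training uses Adam (initial learning rate 10⁻³) with a plateau schedule:
the rate is halved when the monitored loss has not strictly improved for 30
consecutive epochs (counter resets after each reduction). The monitored
quantity is the training loss — no validation split is carved out of the
small transfer sets — and this is configurable. Early stopping is not used;
runs go the full epoch budget.

**Desk-scale schedules.** The full-scale study trains 1000 epochs (batch 8)
on grain-type data and 300 epochs (batch 128) on tablet-type data. The
bundled benchmark and acceptance runs use 60 epochs for both pre-training
and fine-tuning at batch 8 — the point where the master model reaches
R² ≈ 0.9 on the simulated data and the strategy ordering is stable — and
`specshift benchmark --paper-epochs` restores the full schedules.
Fine-tuning keeps the pre-training epoch count and optimiser settings.

## Synthetic paired-instrument data

The generator is a linear Beer–Lambert mixture model: nonnegative
sum-of-Gaussian absorptivity profiles per component, uniform concentration
draws, plus a smooth random quadratic baseline and white noise. A slave
instrument reads the same samples through a distortion chain: wavelength
shift (linear interpolation, edges held), Gaussian resolution broadening
(kernel truncated at ±4σ, renormalised to sum 1), global gain and offset,
per-sample multiplicative scatter, and noise. Reference values are copied
unchanged — only the instrument changes, not the sample.

Preset regimes:

* **corn-like** — 80 samples, 700 points (1100–2498 nm, 2 nm step), four
  mixture targets with mass-fraction ranges typical of ground grain
  (moisture 9.4–11 %, oil 3.1–3.9 %, protein 7.7–9.8 %, starch 62–66 %),
  baseline amplitude 0.005 a.u., noise 5·10⁻⁴ a.u., and two strongly
  distorted slaves (±2 nm shift, 4–5 nm broadening, gain 1.05/0.95, offset
  ±0.02 a.u., scatter 1–1.5 %).
* **tablet-like** — 655 samples, 650 points (600–1898 nm), one assay target,
  one mildly distorted slave.

The noise magnitudes were calibrated once so the generator reproduces the
qualitative regime of real paired-instrument studies: a PLS model on the
master tests at R² ≈ 0.99 and the deep model at ≈ 0.9 (desk scale), while
the master model applied directly to a slave collapses (R² < 0), and
head-retraining recovers most of the accuracy. What the synthetic data does
**not** emulate: nonlinear detector response, wavelength-dependent gain,
temperature/humidity covariates, inter-batch chemistry drift, and real
absorptivity band shapes. Passing tests therefore demonstrate correctness
of the algorithms and the qualitative transfer phenomenology, not
performance on any real instrument pair.

## Preprocessing

* **Kennard–Stone**: first pick the lexicographically smallest pair at
  maximum Euclidean distance, then repeatedly the lowest-index sample
  maximising its minimum distance to the selected set (deterministic
  tie-breaks). Train size is `round(ratio·n)` with half-up rounding
  (80 → 64/16; 636 → 509/127 at 0.8).
* **SPXY**: the same procedure on `d_X/max d_X + d_Y/max d_Y`.
* **Outlier screen**: leave-one-out PLS (5 components, unscaled columns);
  samples whose held-out squared error exceeds the cutoff (default 30, in
  squared target units) are removed. Screening precedes splitting.
* **SNV** (sample SD, divisor n−1) and **MSC** (row regressed on the mean
  spectrum; corrected as `(x − b)/a`) are provided; the simulator pipeline
  does not apply them by default.

## Classical transfer baselines

DS solves the ridge least-squares map `F` in `master ≈ slave·F` on transfer
standards (default ridge 10⁻⁶; optional centred mode adds an intercept).
PDS does the same per wavelength over a ±w window (default w = 5), giving a
banded `F`; at full window it coincides with DS. SBC corrects the master
model's *predictions* on the slave by OLS slope and bias. The master model
inside these comparisons is PLS (5 components). Transfer standards default
to the Kennard–Stone training split of the slave, i.e. the same physical
samples measured on both instruments. The stated SVR kernel parameter
`gamma` is inert for a linear kernel; it is accepted and logged, not
reinterpreted.

## Metrics

R² = 1 − SSres/SStot with SStot about the *test-set* mean — so a model worse
than the constant mean predictor scores negative (some chemometrics software
uses the calibration mean instead). RMSE and MAE are reported alongside; a
constant reference vector makes R² undefined and raises an error carrying
the partial (RMSE/MAE) report.

## Degenerate inputs and tie-breaks

All-identical samples: Kennard–Stone falls back to index order; SPXY with
constant X *and* Y is rejected. MMD of two identical batches is clipped to
exactly 0 (the estimator can go ~−10⁻¹⁶ by cancellation). Zero-variance rows
are rejected by SNV/MSC with the row index named. The wavelength-shift
transform rejects shifts at least as large as the grid span.

## Known limitations

* The numpy engine is single-threaded and eager; at the reference
  architecture's size, one batch-8 training step costs ~0.3 s on one CPU,
  which is why the bundled schedules are desk-scale.
* Only single-target regression heads are provided (one model per
  constituent); classification heads are out of scope.
* MMD uses raw model outputs for the conditional term, not pseudo-label
  binned class-conditional variants.
* The MAT-container reader expects the published variable layouts
  (`m5spec/mp5spec/mp6spec/propvals`; `{calibrate,validate,test}_{1,2,Y}`)
  and is exercised in tests only on synthetic stand-in files.
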