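# Methods

`emgtorque` implements an end-to-end surface-EMG-to-joint-torque
estimation pipeline: amplitude extraction from raw multichannel sEMG, a
linear FIR baseline and four windowed deep regressors, cross-joint
transfer learning between an elbow-like source domain and a hand–wrist
target domain, and %MVT RMSE evaluation under two-fold cross-validation.
Because no raw recordings ship with the package, a synthetic-data
generator emulates both recording protocols and provides ground truth for
parameter-recovery tests.

## Synthetic-data model

A trial is generated top-down from a latent torque drive:

* **Drive** `u(t)` (%MVT). Dynamic trials use a bandlimited uniform random
  process: i.i.d. uniform innovations drawn at 2.5× the bandlimit
  (1 Hz source, 0.75 Hz target), sample-held to the recording rate,
  zero-phase lowpassed (4th-order Butterworth at the bandlimit) and
  affinely rescaled to hit ±range exactly. Drawing innovations at the
  bandlimit's own rate keeps the marginal distribution near-uniform, so
  every trial exercises both torque directions across its full range — a
  property the tracking protocol relies on and which a lowpass of
  rate-`fs` white noise does not deliver at realistic trial lengths (with
  a 0.75 Hz bandlimit a 10–40 s trial holds only `2·B·T` ≈ 15–60
  effective samples, and the filtered trace can spend nearly all its time
  on one side of zero, which collapses fold-to-fold generalisation).
  Calibration trials hold ±50 %MVT, MVT trials ±100 %MVT.
* **Latent amplitude** `s_c(t) = g⁺_c·max(u,0)/100 + g⁻_c·max(−u,0)/100 + s₀`.
  Channels alternate preferred direction; agonist gains are ~1 (uniform
  0.7–1.3) and antagonist gains ~0.03–0.12, the resting amplitude `s₀` is
  uniform 0.02–0.05 (raw units).
* **Raw EMG** `x_c = s_c·w_c + line + sensor noise`, with `w_c`
  unit-variance Gaussian noise bandlimited to 15–600 Hz (clipped below
  Nyquist at low desk rates), a power-line sinusoid of amplitude 0.05 with
  random phase per channel, and white sensor noise of SD 0.02.
* **Torque** `T = sat(Σ_c h_c * s_c − offset) + ε` on the 40.96 Hz frame
  grid, then interpolated to the recording rate. Kernels `h_c` are
  gamma-shaped (`t·exp(−t/τ)`, τ uniform 30–80 ms, ≤16 taps ≈ 391 ms
  support), signed by the channel's preferred direction and scaled per DoF
  so a sustained 100 %MVT drive yields a pre-saturation torque of 100
  (the MVT = 100 convention makes %MVT normalisation exact). `sat` is the
  odd soft clip `(100/k)·tanh(k·x/100)` with `k = 2.5` by default — strong
  enough that nonlinear regressors can outperform the linear FIR baseline,
  mild enough that torque still tracks the drive; `ε` has SD 1 %MVT.

What the generator does *not* emulate: motion artifacts,
electrode-impedance drift, fatigue, muscle crosstalk beyond the shared
drive, or inter-subject electrode-placement variability. Passing
direction-only checks on this generator therefore shows the pipeline's
internal consistency and qualitative behaviour, not expected human-data
error levels.

### Identifiability and the identification mode

Under the tracking protocols all channel amplitudes are driven by the same
scalar target, so within a DoF they span a ~3-dimensional space
(`u⁺`, `u⁻`, constant) and per-channel kernels are **not** identifiable
from protocol trials. Kernel-recovery tests therefore use
`synthesize_identification_data`, which excites each channel with
independent nonnegative broadband amplitudes through the same linear
kernel bank — a well-conditioned system with known ground truth. Trials
also carry their latent amplitudes, and `run_cv(features="latent")`
regresses on them directly: a diagnostic mode that removes
envelope-estimation noise (used by the noiseless-linear recovery oracle).

## Amplitude extraction

Per channel, in order: 5th-order Butterworth highpass at 15 Hz; cascade of
2nd-order notches (−3 dB bandwidth ≤1.5 Hz) at the line fundamental and
harmonics below 600 Hz; first-difference whitening; 9th-order Chebyshev I
lowpass at 600 Hz; full-wave rectification; 9th-order Chebyshev I lowpass
at 16 Hz; decimation to 40.96 Hz by keeping every D-th sample
(D = fs/40.96 — 100 at 4096 Hz, 50 at 2048 Hz). Choices the literature
leaves open, fixed here: all filtering is causal (the application is
real-time control; start-up transients are handled by the evaluation
stage's 1 s edge omission); Chebyshev passband ripple is 0.05 dB
(configurable); the 600 Hz stage is skipped when the cutoff reaches
Nyquist (desk-scale rates); torque is conditioned with the same 16 Hz
lowpass + decimation so frames align with the envelope. Normalisation:
per channel by the reciprocal of the larger 50 %MVT calibration RMS of the
two directions; torque to %MVT of the larger direction's MVT, measured as
the median |conditioned torque| over the MVT trial's interior.

## Windowing

Window lengths live on the 40.96 Hz frame grid: `M = round(ms/1000·40.96)`
frames, so the standard lengths 98–781 ms map to 4–32 frames and the 25 ms
increment to 1 frame. Raw-signal windows use the same grid times the
decimation factor — 391 ms is 16 frames, 800 raw samples at 2048 Hz and
1600 at 4096 Hz — so raw images and amplitude windows cover identical time
spans and share end-aligned torque targets (the regression target is the
conditioned torque at the window's final frame; causal, zero-lag). The
naive alternative `round(ms·fs)` would give 801/1602-sample windows and a
51-sample step that drifts off the frame grid.

## Models

**FIR baseline.** Per-channel 15th-order FIR (16 lag taps ≈ 391 ms memory)
from amplitude to torque, no intercept, fitted by SVD least squares with
singular values below 0.005×(largest) truncated (an absolute-tolerance
mode is available). The truncation matters: protocol-trial envelope
regressors are strongly collinear.

**Deep regressors.** Four architectures over sliding windows, each ending
in a scalar regression output:

| arch | input | layers |
|---|---|---|
| MLP | concatenated envelope vector (channel-major, `C·M`) | FC 128 (linear input map) → FC 128 + ReLU → FC 64 + ReLU |
| CNN | raw image `[M·D × C]` | 4 conv blocks (3×3 conv, filters 64/128/128/64, batch-norm on blocks 1–3, ReLU, 2×2 stride-2 average pool) → dropout 0.5 → FC 128 + ReLU |
| LSTM | envelope sequence `[M × C]` | time-distributed FC 128 (linear) → LSTM 100 → FC 64 + ReLU |
| C-LSTM | raw image | the 4 conv blocks → LSTM 500 over the time axis → dropout 0.5 → FC 128 + ReLU |

Pooling uses floor semantics; an axis already collapsed to length 1 passes
through unpooled, which makes the post-convolution feature width (64)
domain-invariant — the property that lets the C-LSTM's LSTM transfer
across domains. Training: Adam, initial LR 0.001 dropped ×0.2 every 10
epochs, mini-batches of 256 shuffled each epoch, Glorot-uniform
initialisation, MSE loss. The epoch budget is not dictated by the
architecture; the default is 30 (three LR plateaus). The layer stack is
implemented directly in NumPy with hand-written backpropagation, verified
against finite differences in the test suite; batch-norm running
statistics use a bias-corrected EMA so evaluation statistics are sensible
even after few updates.

## Transfer learning

Pre-train on aggregated source-domain windows; for MLP/LSTM the first FC
layer (the input transformation matrix) is excluded from the bundle and a
fresh, randomly initialised first layer of the target width is trained
from scratch during fine-tuning. CNN/C-LSTM kernels are fixed-size and
transfer verbatim; the CNN's post-flatten dense layer has different input
widths in the two domains (1600×8 vs 800×16 pool to different time
lengths) and no bridging scheme is published for it, so it is
re-initialised and the adaptation report records per-layer status
(`transferred` / `reinitialized` / `new`). Fine-tuning trains all layers
at LR 0.0005 with the same schedule family; weight bundles are
single-file `.npz` containers with JSON metadata, and every transferred
tensor is bit-identical to the bundle.

## Evaluation

Per subject and DoF: four dynamic trials, fold A trains on {1,2} / tests
{3,4}, fold B the reverse; separate models per DoF. Score: RMSE in %MVT
with the first and last second omitted (filter start-up transients;
applied to raw-input models too, for consistency). Per-subject performance
is the mean over trials × DoFs. Sweep drivers cover the eight window
lengths and the eight training-data sizes (40…5 s per trial), with TL and
non-TL arms paired through a master seed that fans out to
per-(subject, arch, condition) seeds via SHA-256. Inferential statistics
(RANOVA, post hoc t-tests) are out of scope; the tidy CSV reports carry
everything needed to run them externally.

## Desk-scale study conditions

The stochastic direction-only checks (tests and `scripts/acceptance.py`)
run on scaled protocols chosen once (`emgtorque.desk`):

* target: 4 channels at 204.8 Hz (D = 5), one DoF, ±30 %MVT at 0.75 Hz,
  10 s trials, 4 trials; source: 2 channels at 409.6 Hz (D = 10), one DoF,
  ±50 %MVT at 1 Hz, 8 s trials, 2 trials, 10 subjects for pre-training.
  Both keep the cross-domain structure (different channel counts and
  rates, both on the 40.96 Hz grid).
* Raw-image architectures segment with a 150 ms increment (envelope
  architectures use 25–50 ms) to bound convolution cost.
* Training budgets are scaled by optimiser *steps*, not epochs: desk
  batches of 16 keep ~100 steps per LR plateau, matching the full-scale
  regime of 256-sample batches over thousands of windows. Fine-tuning
  runs at half the learning rate, so its desk budget doubles the epochs
  and the LR-drop period (60/20 vs 30/10) to do equal optimisation work —
  at full scale both arms converge within budget and the distinction is
  immaterial, but with tens of steps per plateau an equal-epoch budget
  would handicap the fine-tuned arm for a reason unrelated to transfer.
* Desk data sizes 8 s ("full") and 2.5 s ("scarce") are the quarter-scale
  analogues of ≥30 s and ≤10 s on 40 s trials; the TL and data-size
  checks run at the 391 ms window, as in the full-scale design.
* Direction checks use seeds 1–3 with majority voting, two target
  subjects each.

## Numerical notes and limitations

* The FIR design matrix stacks per-trial lagged blocks, so no lag bleeds
  across trial boundaries.
* `lfilter`-based FIR prediction zero-pads history; the first
  `order` frames are transient and fall inside the omitted edge second.
* Window batches are float32; gradient checks run the layer stack in
  float64.
* The generator's torque noise floor (1 %MVT) plus envelope-estimation
  noise puts desk-scale FIR errors around 5–7 %MVT; absolute values are
  not comparable to human-data errors, only orderings are meaningful.
* `AvgPool` clamping on singleton axes means inputs narrower than 16
  channels collapse earlier; the flatten width then differs between
  domains and the CNN dense layer is re-initialised on transfer (see
  above) — the adaptation report makes this visible per run.
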