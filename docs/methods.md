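# Methods

This note documents the models, algorithms and design choices in
`whiskdecode`: what the synthetic data generator emulates, how the signal
metrics are defined, how the decoding network and its training protocol work,
and the numerical decisions behind them.

## The scientific setting

Extraneural electrodes on the facial-nerve branches that drive the whisker
pad record low-amplitude multi-unit activity whose slow envelope tracks
whisker motion. The decoding problem is a sequence regression: map a single
neural voltage stream sampled at 16 kHz onto the normalized whisker position
sampled at 125 Hz (0–1, rest baseline 0.5, full scale 0–28 mm). Because each
subject has its own gain, noise floor and signal-to-motor latency, a model
trained on a cohort does not transfer directly to a new subject; the package
implements a shared-encoder strategy in which feature extraction is learned
jointly across subjects and only a small subject-specific decoder is retrained
("adapted") for each new individual.

## Synthetic cohorts (`whiskdecode.synth`)

No public recordings exist for this preparation, so every analysis stage is
exercised on synthetic cohorts whose structure mirrors the statistics the
real recordings are reported to have.

**Trajectory.** Whisking bouts arrive as a Poisson process (default
0.25 bouts/s) with exponential durations (mean 1.5 s, clipped to 0.4–4 s),
separated by rest at exactly 0.5. Within a bout the whisker oscillates at the
subject's whisk rate (default 5 Hz — rabbits whisk markedly slower than rats
or mice) under a raised-cosine on/off ramp with a slow amplitude drift. The waveform is protraction-biased
(`0.35 + 0.65 sin`): whisks protract away from rest and return, rather than
swinging symmetrically, which is what makes part of the oscillation
recoverable from an amplitude envelope. Peak excursion defaults to 11.2 mm
of the 0–28 mm laser-micrometer range.

**Neural signal.** A band-limited Gaussian carrier (default 300–1400 Hz)
is amplitude-modulated by the trajectory's movement envelope (|x − 0.5|
low-passed at 10 Hz) advanced by the subject's signal-to-motor latency —
nerve activity leads the movement it drives (default 25 ms). A white+pink
noise floor sits underneath. The modulation gain is calibrated per
realization so that the RMS over movement periods equals the target
(13.31 µV) given the rest floor (5.58 µV); with those defaults the package's default
SNR convention (see below) gives a nominal 3.8 dB movement-over-rest contrast,
and the aligned envelope correlation between neural and trajectory envelopes
is ≈0.97 within movement windows. The generator produces multi-unit
*envelope* structure only — no spike trains — because every downstream
statistic and the decoder consume amplitude information, not spike
identities.

**Off-nerve controls.** Broadband white+pink noise at the rest floor with no
trajectory coupling: SNR ≈ 0 dB, envelope correlation ≈ 0, and a
state-independent in-band power ratio.

**Heterogeneity.** A cohort is drawn around the defaults with one scalar
`heterogeneity` (h) controlling inter-subject spread: log-normal
(multiplicative) on movement RMS (sd 0.5 h in log units), noise floor
(0.3 h), whisk amplitude (h) and frequency (0.25 h), carrier-band placement
(0.4 h — electrode-tissue coupling differs per subject) and bout rate and
duration (0.5 h each — whisking vigor differs per animal), and additive
Gaussian on latency (sd 50 h ms, clipped at 0). The additive latency spread
is deliberate: cross-subject latency differences must span several 8-ms
output samples for there to be anything for a subject-specific decoder to
compensate — that timing compensation, together with output-scale and
duty-cycle matching, is the mechanism by which adaptation beats a fully
shared model. At h = 0 subjects are identical up to their random seeds.

**What the generator does not emulate.** Electrode impedance and motion
artifacts, EMG crosstalk beyond a second modulated channel, spike waveforms
and unit identities, nonstationary gain drift, and behavioral idiosyncrasies
beyond the parameter spreads above (all subjects share the same bout and
whisk waveform family). Real
cross-subject transfer is harder than the synthetic version in ways the
tests cannot certify; passing the synthetic trend checks shows the pipeline
recovers the mechanisms it models, not field performance.

## Signal conditioning (`whiskdecode.sigproc`)

All filters are 4th-order Butterworth applied forward–backward (zero phase),
so envelope timing survives filtering. The neural band-pass (1–1500 Hz) is a
high-pass/low-pass cascade because a single band-pass design with edges three
decades apart is ill-conditioned. A high-pass whose normalized cutoff falls
below 1e-3 (the 1 Hz edge at 16 kHz) is applied in the frequency domain as
the exact zero-phase order-4 Butterworth magnitude response with reflective
padding — the time-domain SOS filtfilt breaks down numerically there.

Envelopes are Hilbert magnitudes smoothed by a 10 Hz low-pass; normalized
trajectories use |x − 0.5| instead (they are unipolar excursions, not
oscillations around zero). Alignment maximizes the normalized
cross-correlation of the two envelopes after resampling to the lower rate;
positive lag means the neural signal leads. Movement segments are detected by
thresholding the smoothed trajectory envelope at 3× a robust rest-noise scale
(MAD-based, floored at 2% of full scale), merging gaps shorter than 100 ms
and dropping bouts shorter than 80 ms. All intervals are half-open
`[start, end)` in seconds with sample index `floor(t·fs)`.

## Quality metrics (`whiskdecode.metrics`)

Sliding-window statistics default to 200 ms windows with 100 ms overlap
(2 s / 1 s for the in-band ratio, 1 s windows for envelope correlation).

* **SNR** is `10·log10(RMS_movement / RMS_rest)` — a factor of 10 applied to
  an amplitude ratio. That convention is implemented as the default because
  it is the definition stated for the analysis this package reproduces;
  `power=True` gives the conventional `20·log10`. The rest floor requires at
  least 10 s of rest data.
* **In-band power ratio**: energy in 10–1500 Hz over total energy above
  10 Hz, after a 50 Hz band-stop, per window, via rFFT.
* **Persistence spectrum**: 256 Hamming-windowed segments at 50% overlap;
  per-segment FFT power in dB discretized into 256 evenly spaced levels
  between the observed minimum and maximum (the discretization range is not
  externally specified; the observed range is the only parameter-free
  choice), accumulated into a (level × frequency) occupancy histogram.
* **CCC** (Lin's concordance correlation):
  `ρ_c = 2ρσ_yσ_ŷ / (σ_y² + σ_ŷ² + (μ_y − μ_ŷ)²)` with population (1/N)
  variances, matching Lin's convention; a `sample_variance` toggle is
  provided. Zero-variance inputs raise rather than returning 0, and a
  zero-variance correlation window is reported as missing (NaN).

## The decoding network (`whiskdecode.model`)

Streaming contract: input windows of `n_pad = 2000` samples with stride
`fs_data/fs_laser = 128`; window *k* covers samples `[128k, 128k + 2000)` and
its output corresponds to trajectory sample `k + 15` (the time of the
window's last sample). One output per trajectory sample, strictly in (0, 1)
via the final sigmoid.

**Handcrafted pathway.** Each window is cut into 16 sub-windows of 125
samples; per sub-window, 10 classic EMG-style time-domain features (MAV,
SSI, AAC, SD, RMS, waveform length, zero crossings, slope-sign changes,
Willison amplitude, variance; deadband 0.01, Willison threshold 0.5 on the
z-scored scale). The exact feature inventory is not externally fixed; this
10-feature set is the package's documented default. Features are z-scored
by per-subject statistics and processed as a 16-step sequence by an LSTM
with hidden size 30 (the "160 × 30" sizing: 16 windows × 10 features in, 30
out), whose final hidden state passes a 30→30 dense layer with ReLU.

**CNN pathway.** The z-scored raw window passes a 1-D convolution (kernel 7,
16 channels, stride 8) with ReLU; the output is arranged as a 16 × 250
channels-by-time image, then 2×2 average pooling → single-channel 3×3 "same"
convolution + ReLU → 2×2 pooling → 3×3 convolution + ReLU, and the resulting
62 four-row columns feed an LSTM (hidden 30). The stride-8 decimation in the
first convolution is a deliberate deviation from a stride-1 design: it cuts
the recurrent stage from ~500 to 62 steps, which is what makes CPU training
tractable, and costs little because the rectified, pooled activations carry
envelope (amplitude) information that survives decimation.

**Decoder.** The two 30-dim latents are fused by a linear dense layer into
F_t ∈ R⁶⁰. A buffer holds the current and previous 15 F vectors
(zero-initialized at sequence start; warm-up outputs are emitted). Shared
dense+ReLU maps give 30-dim key, query and value vectors per buffered entry;
the attention score of slot *i* is `softmax(K_i·Q_i / 4)` over the 16 slots —
the divisor is the fixed constant 4 (= √16), not generalized to √d_k, and
each slot's logit pairs its own key with its own query. The context is the
score-weighted sum of values; a 30→1 dense layer plus sigmoid yields the
output. Key/query/value transforms are shared across lags (standard
self-attention), the reading adopted here since per-lag parameters are not
externally specified.

**NN engine.** The network is implemented on a small in-package
reverse-mode autodiff engine over numpy (`whiskdecode.nn`): broadcasted
arithmetic, matmul, LSTM, strided 1-D convolution, 3×3 "same" convolution
built from shifts, 2×2 average pooling, softmax, and a sliding-buffer
gather, plus Adam. Every primitive's gradient is checked against central
finite differences in the test suite. Training runs in float32; the library
default elsewhere is float64. Model parameters serialize to a single `.npz`
with an embedded JSON manifest (shapes, SHA-256 of the exact float64 bytes);
the hash doubles as the freeze-contract check.

## Training protocol (`whiskdecode.training`)

Per-subject normalization (raw mean/sd and per-feature mean/sd) is computed
from that subject's training split only; for a new subject, from its
adaptation data. Normalization statistics tagged as coming from a test split
are rejected at predict time.

Training minimizes `1 − CCC` over contiguous output sequences (default 125
steps = 1 s) with Adam (default lr 3e-3 shared phase, 5e-3 adaptation). The
variance terms in the differentiable loss carry an ε = 1e-6 guard so a
briefly constant prediction does not divide by zero — a documented deviation
from the exact CCC, used only inside the loss. Sequences are sampled with a
0.75 bias toward movement bouts (the analysis pipeline this mirrors trains
on movement-related activity; the remaining 25% keeps the rest baseline
calibrated). Subjects are visited round-robin within an epoch so encoder
gradients interleave; each subject's private decoder receives only its own
batches. A validation slice (the last 15% of each training recording) is
scored each epoch and the best-scoring parameters are restored at the end.

Adaptation freezes the encoder, computes its latents for the adaptation data
once, and trains a freshly initialized decoder on the cached latents
(default 500 Adam steps) — which is why adapting to a new subject costs
seconds rather than minutes. The adaptation budget is capped at 500 s of
data by contract.

## Evaluation protocol (`whiskdecode.evaluation`)

* **Controls.** `control1`: encoder *and* decoder shared across training
  subjects, applied to the test subject without adaptation (input
  normalization still uses the test subject's own non-test data — input
  scaling is not a learned parameter). `control2`: encoder and decoder
  trained from scratch on the test subject's adaptation data only.
* **LOSO cross-validation**: each subject held out once; seeds 1..n (default
  10) per fold; per-seed CCCs retained, summarized by mean/sd/median/IQR
  (aggregation across seeds by mean, with per-seed values kept).
* **Learning curves**: the subject's recording is cut into n (default 5)
  contiguous folds; each fold holds one block out for testing and
  adapts/trains on growing prefixes of the remainder. `data_to_90pct` is the
  smallest grid length whose CCC reaches 90% of that fold's maximum (with a
  1e-12 tolerance against float rounding of `0.9·max`).

## Problem sizes in the shipped checks

The synthetic-recovery checks and the acceptance script run a cohort of
4 training subjects plus one held-out subject, 120 s each, heterogeneity
0.3, with 8-epoch shared training (320 optimization steps), 500-step
decoder-only adaptation on 60 s of data, 60 s of test data, and 3-point
learning-curve grids over 5 folds at 2-epoch budgets. These sizes are the package's chosen desk-scale
study conditions; larger cohorts and longer recordings only improve the
trained models.

## Known limitations

* The attention decoder's output is a score-weighted sum over the 16-slot
  buffer in which a slot's score depends only on that slot's own content —
  the output is invariant to the temporal order of the buffered vectors.
  When the scores are close to uniform this behaves like a causal 128 ms
  moving average, which strongly attenuates rhythmic components near
  1/0.128 s ≈ 7.8 Hz. Decoding quality therefore depends on the whisk rate:
  single-subject experiments in this package reach CCC ≈ 0.95 at 4-5 Hz
  whisking but only ≈ 0.6 at 8 Hz, even though a linear oracle on the same
  inputs is frequency-independent (≈ 0.97). The 5 Hz rabbit default operates
  the architecture where it works; faster whiskers would need a
  positional-aware decoder, which is out of scope.
* The synthetic task bounds achievable CCC below 1: the within-bout
  oscillation phase is only partially encoded in the envelope, so even an
  ideal decoder cannot reproduce the trajectory exactly.
* Single neural channel only; no multi-channel fusion.
* The attention divisor, buffer length, window sizes and feature set are
  fixed architecture constants; no hyperparameter search is included by design.
* Training at the shipped problem sizes is deliberately short; the absolute
  CCC values it reaches are not comparable to fully converged training.
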