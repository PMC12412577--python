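# whiskdecode

Cross-subject decoding of whisker trajectories from extraneural facial-nerve
recordings: a tested, reusable implementation of the full analysis pipeline —
synthetic multi-subject cohorts, electrophysiology signal-quality metrics, an
encoder/attention-decoder regression network trained with a concordance-
correlation loss, the shared-encoder / per-subject-decoder transfer strategy,
and the cross-subject evaluation protocol around it.

## The problem

Electrodes on the facial-nerve branches that drive the whisker pad pick up
low-amplitude multi-unit activity whose slow envelope tracks whisker motion.
Decoding is a sequence regression from a 16 kHz neural stream to the
normalized whisker position at 125 Hz: windows of N_pad = 2000 samples slide
with stride f_data/f_laser = 128, and each window yields one output
y[n] ∈ (0, 1) (rest baseline 0.5, full scale 0–28 mm).

The model (an encoder with a handcrafted-feature pathway and a CNN pathway,
each refined by an LSTM, followed by a temporal self-attention decoder over
the last 16 fused feature vectors) is trained and evaluated with Lin's
concordance correlation coefficient

    rho_c = 2 rho sigma_y sigma_yhat / (sigma_y^2 + sigma_yhat^2 + (mu_y - mu_yhat)^2)

both as the loss (1 − rho_c over 1-s output sequences) and as the evaluation
metric. Because subjects differ in gain, noise floor and signal-to-motor
latency, the encoder is trained jointly across subjects (shared parameters
W_Enc) while each subject keeps a private decoder W_Dec^i; a new subject gets
a freshly initialized decoder trained on limited adaptation data with the
encoder frozen. Two controls bracket the strategy: a fully shared model with
no adaptation, and a fully individual model trained from scratch.

No recordings of this preparation are public, so the package ships a
calibrated synthetic generator (movement-period RMS 13.31 µV over a 5.58 µV
rest floor, sub-1500 Hz carrier, envelope-coupled trajectories, per-subject
latency/gain/noise heterogeneity) that every stage is tested against. See
`docs/methods.md` for the model and generator details.

## Worked example

```python
import numpy as np
from whiskdecode import synth, metrics, sigproc
from whiskdecode.training import WhiskerNetRegressor
from whiskdecode.evaluation import evaluate_on

# a 5-subject synthetic cohort, 120 s each, moderate heterogeneity
cohort = synth.make_cohort(5, duration_s=120.0, base_seed=7, heterogeneity=0.3)
train, test = cohort[:4], cohort[4]

# recording quality of the held-out subject
segs = sigproc.extract_movement_segments(test.trajectory)
snr = metrics.trial_snr(test.neural, segs, segs.complement(test.duration_s))
corr = metrics.neural_trajectory_envelope_correlation(test.neural, test.trajectory)
print(f"movement bouts: {len(segs)},  SNR {snr.mean():.2f} dB,  "
      f"envelope correlation {np.nanmean(corr.values):.2f}")

# shared-encoder training, then adaptation on 60 s of the new subject
est = WhiskerNetRegressor(epochs=10, learning_rate=3e-3, seed=1).fit(train)
est.adapt(test.slice_s(0, 60.0))
ccc = evaluate_on(est, test.slice_s(60.0, 120.0))
print(f"adapted test CCC: {ccc:.2f}")
```

Output from this exact script:

```
movement bouts: 32,  SNR 4.53 dB,  envelope correlation 0.99
adapted test CCC: 0.95
```

The SNR is the movement-over-rest RMS contrast in the
`10·log10(RMS_S/RMS_N)` convention (see `docs/methods.md`); the envelope correlation is the mean
per-window Pearson r between the aligned neural and trajectory envelopes
during movement; the CCC is the agreement between the decoded and actual
trajectory on the held-out minute, after adapting only the decoder.

A command-line interface mirrors the library
(`whiskdecode simulate|preprocess|metrics|train|adapt|predict|evaluate|curve|demo`);
`whiskdecode demo` runs a miniature end-to-end pipeline.

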