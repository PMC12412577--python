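"""Signal conditioning, temporal alignment and movement-segment extraction.

All filters are 4th-order Butterworth applied forward-backward
(``scipy.signal.filtfilt``), i.e. zero-phase, so that envelope timing is
preserved for the cross-correlation alignment step.

Conventions
-----------
* intervals are half-open ``[start_s, end_s)`` in seconds; the sample index of
  time ``t`` is ``floor(t * fs)``.
* a positive alignment lag means the neural signal *leads* the movement.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import signal as sps

from .recording import DataError, IntervalSet, ParameterError, Recording

__all__ = [
    "bandpass_neural",
    "highpass_emg",
    "bandstop_50",
    "envelope",
    "align_by_envelope_xcorr",
    "extract_movement_segments",
    "gather_movement_signal",
    "movement_envelope",
]

NEURAL_BAND_HZ = (1.0, 1500.0)
EMG_HIGHPASS_HZ = 10.0
NOTCH_BAND_HZ = (48.0, 52.0)
FILTER_ORDER = 4


def _sos_filtfilt(rec: Recording, sos: np.ndarray) -> Recording:
    if len(rec) < 50:
        raise DataError("recording too short to filter")
    return rec.replace(sps.sosfiltfilt(sos, rec.samples))


def _highpass(rec: Recording, cutoff_hz: float) -> Recording:
    """Zero-phase high-pass that stays well-conditioned for near-DC edges.

    A Butterworth high-pass whose normalized cutoff is below ~1e-3 is
    numerically unusable (the forward-backward initial-condition solve breaks
    down), so for such edges the sub-cutoff trend is estimated by low-pass
    filtering a decimated copy of the signal and subtracted instead.
    """
    if cutoff_hz / rec.fs_hz >= 1e-3:
        sos = sps.butter(FILTER_ORDER, cutoff_hz, btype="highpass", fs=rec.fs_hz, output="sos")
        return _sos_filtfilt(rec, sos)
    # frequency-domain application of the zero-phase (forward-backward)
    # order-4 Butterworth magnitude response, with reflective padding to
    # suppress circular-boundary effects
    n = rec.samples.size
    pad = int(min(n, 2.0 * rec.fs_hz / cutoff_hz))
    x = np.pad(rec.samples, pad, mode="reflect")
    freqs = np.fft.rfftfreq(x.size, d=1.0 / rec.fs_hz)
    ratio = (freqs / cutoff_hz) ** (2 * FILTER_ORDER)
    h = ratio / (1.0 + ratio)  # |H_hp|^2 of an order-4 Butterworth
    y = np.fft.irfft(np.fft.rfft(x) * h, x.size)
    return rec.replace(y[pad : pad + n])


def bandpass_neural(rec: Recording, band_hz=NEURAL_BAND_HZ) -> Recording:
    """Zero-phase band-pass, default 1-1500 Hz, for raw neural recordings.

    Implemented as a high-pass / low-pass cascade: a single band-pass design
    with edges three decades apart is numerically ill-conditioned at these
    sampling rates.
    """
    lo, hi = band_hz
    nyq = rec.fs_hz / 2.0
    if hi >= nyq:
        raise ParameterError(f"band edge {hi} Hz at or above Nyquist {nyq} Hz")
    sos_lp = sps.butter(FILTER_ORDER, hi, btype="lowpass", fs=rec.fs_hz, output="sos")
    return _sos_filtfilt(_highpass(rec, lo), sos_lp)


def highpass_emg(rec: Recording, cutoff_hz: float = EMG_HIGHPASS_HZ) -> Recording:
    """Zero-phase high-pass, default 10 Hz, for EMG recordings."""
    if cutoff_hz >= rec.fs_hz / 2.0:
        raise ParameterError("cutoff at or above Nyquist")
    return _highpass(rec, cutoff_hz)


def bandstop_50(rec: Recording, band_hz=NOTCH_BAND_HZ) -> Recording:
    """Zero-phase band-stop around 50 Hz (mains)."""
    lo, hi = band_hz
    if hi >= rec.fs_hz / 2.0:
        raise ParameterError("stop band at or above Nyquist")
    sos = sps.butter(FILTER_ORDER, [lo, hi], btype="bandstop", fs=rec.fs_hz, output="sos")
    return _sos_filtfilt(rec, sos)


def envelope(rec: Recording, smooth_hz: Optional[float] = 10.0) -> Recording:
    """Amplitude envelope: |analytic signal| then optional low-pass smoothing.

    The Hilbert magnitude tracks the instantaneous amplitude of oscillatory
    activity; the default 10 Hz low-pass yields the slow envelope that couples
    multi-unit nerve activity to the whisker trajectory. The result is clipped
    at zero (the smoothing filter can slightly undershoot).
    """
    if len(rec) < 64:
        raise DataError("recording too short for envelope estimation")
    env = np.abs(sps.hilbert(rec.samples))
    if smooth_hz is not None and smooth_hz < rec.fs_hz / 2.0:
        sos = sps.butter(FILTER_ORDER, smooth_hz, btype="lowpass", fs=rec.fs_hz, output="sos")
        env = sps.sosfiltfilt(sos, env)
    return rec.replace(np.maximum(env, 0.0))


def movement_envelope(traj: Recording, smooth_hz: Optional[float] = 10.0) -> Recording:
    """Envelope of a normalized trajectory: |x - 0.5|, optionally smoothed.

    Trajectories are unipolar excursions from the 0.5 rest baseline, so the
    rectified deviation (not the Hilbert magnitude) is the natural envelope.
    """
    env = np.abs(traj.samples - 0.5)
    if smooth_hz is not None and smooth_hz < traj.fs_hz / 2.0:
        sos = sps.butter(FILTER_ORDER, smooth_hz, btype="lowpass", fs=traj.fs_hz, output="sos")
        env = np.maximum(sps.sosfiltfilt(sos, env), 0.0)
    return traj.replace(env, unit="normalized")


def _resample_to(rec: Recording, fs_hz: float) -> np.ndarray:
    if abs(rec.fs_hz - fs_hz) < 1e-9:
        return rec.samples
    n_out = int(round(len(rec) * fs_hz / rec.fs_hz))
    return sps.resample_poly(
        rec.samples, up=int(round(fs_hz)), down=int(round(rec.fs_hz))
    )[:n_out]


def align_by_envelope_xcorr(
    neural: Recording,
    target: Recording,
    max_lag_s: float = 0.5,
    smooth_hz: float = 10.0,
) -> float:
    """Lag (s) between a neural recording and a movement trajectory.

    Both envelopes are resampled to the lower of the two sampling rates, mean
    is removed, and the normalized cross-correlation is maximized over lags in
    ``[-max_lag_s, +max_lag_s]``. Positive lag = neural leads the movement.
    """
    fs = min(neural.fs_hz, target.fs_hz)
    env_n = envelope(neural, smooth_hz) if neural.kind != "trajectory" else movement_envelope(neural, smooth_hz)
    env_t = movement_envelope(target, smooth_hz) if target.kind == "trajectory" else envelope(target, smooth_hz)
    a = _resample_to(env_n, fs)
    b = _resample_to(env_t, fs)
    n = min(a.size, b.size)
    a = a[:n] - a[:n].mean()
    b = b[:n] - b[:n].mean()
    if a.std() == 0 or b.std() == 0:
        raise DataError("flat envelope: alignment undefined")
    max_lag = int(round(max_lag_s * fs))
    xc = sps.correlate(a, b, mode="full")
    lags = sps.correlation_lags(n, n, mode="full")
    keep = np.abs(lags) <= max_lag
    best = lags[keep][np.argmax(xc[keep])]
    # correlate(a, b) peaks at positive lag when a is delayed w.r.t. b; the
    # neural signal leading the movement means its envelope peaks *earlier*,
    # i.e. the trajectory b is the delayed copy.
    return float(-best) / fs


def extract_movement_segments(
    traj: Recording,
    threshold: Optional[float] = None,
    min_gap_s: float = 0.1,
    min_duration_s: float = 0.08,
    smooth_hz: float = 10.0,
) -> IntervalSet:
    """Movement bouts of a normalized (0-1, rest 0.5) whisker trajectory.

    Onset-to-cessation intervals around excursions of the smoothed movement
    envelope above ``threshold``. When no threshold is given it is set to
    ``3 x`` a robust rest-noise scale (median absolute deviation of the
    envelope below its median, floored at 1% full scale). Gaps shorter than
    ``min_gap_s`` are merged; bouts shorter than ``min_duration_s`` dropped.
    """
    env = movement_envelope(traj, smooth_hz).samples
    fs = traj.fs_hz
    if threshold is None:
        rest_level = np.median(env)
        dev = np.median(np.abs(env[env <= rest_level] - 0.0)) if np.any(env <= rest_level) else 0.0
        threshold = max(3.0 * max(dev, 1e-3), 0.02)
    above = env > threshold
    if not above.any():
        return IntervalSet([])
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    seg_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    seg_ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    merged = []
    for s, e in zip(seg_starts, seg_ends):
        if merged and (s - merged[-1][1]) / fs < min_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = [(s / fs, e / fs) for s, e in merged if (e - s) / fs >= min_duration_s]
    return IntervalSet(out)


def gather_movement_signal(rec: Recording, intervals: IntervalSet) -> Recording:
    """Concatenate the in-interval samples of ``rec`` in temporal order."""
    chunks = []
    for a, b in intervals:
        i0 = int(np.floor(a * rec.fs_hz))
        i1 = int(np.floor(b * rec.fs_hz))
        chunks.append(rec.samples[i0:i1])
    samples = np.concatenate(chunks) if chunks else np.empty(0)
    out = Recording.__new__(Recording)
    out.samples = np.asarray(samples, dtype=np.float64)
    out.fs_hz = rec.fs_hz
    out.unit = rec.unit
    out.kind = rec.kind
    return out
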