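"""Trial-by-trial signal-quality statistics and the concordance correlation.

Sliding-window RMS / peak-to-peak / SNR / in-band power ratio / envelope
correlation, the persistence spectrum (an occupancy histogram over frequency
and discretized power level), and Lin's concordance correlation coefficient
(CCC), which doubles as the training criterion.

SNR convention: ``10 * log10(RMS_S / RMS_N)`` — a factor of 10 applied to an
amplitude ratio. ``power=True`` switches to the conventional
``20 * log10`` amplitude-ratio definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .recording import (
    DataError,
    IntervalSet,
    ParameterError,
    Recording,
    WindowSpec,
)
from .sigproc import bandstop_50

__all__ = [
    "SlidingSeries",
    "PersistenceSpectrum",
    "CCCResult",
    "sliding_rms",
    "sliding_vpp",
    "snr_db",
    "trial_snr",
    "persistence_spectrum",
    "in_band_power_ratio",
    "envelope_correlation",
    "neural_trajectory_envelope_correlation",
    "concordance_cc",
]


@dataclass
class SlidingSeries:
    """Per-window statistic values with their window geometry."""

    values: np.ndarray
    window: WindowSpec
    t_centers_s: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.t_centers_s = np.asarray(self.t_centers_s, dtype=np.float64)
        if self.values.shape != self.t_centers_s.shape:
            raise ParameterError("values and centers must align")

    def __len__(self) -> int:
        return self.values.size

    def mean(self) -> float:
        return float(np.nanmean(self.values))


@dataclass
class PersistenceSpectrum:
    """Occupancy histogram over (frequency bin, discretized power level)."""

    freq_bins_hz: np.ndarray
    level_edges_db: np.ndarray  # 257 edges bounding 256 levels
    counts: np.ndarray  # (n_levels, n_freqs)
    n_segments: int


@dataclass
class CCCResult:
    """Lin's concordance correlation coefficient and its components."""

    rho_c: float
    rho: float
    sigma_y: float
    sigma_yhat: float
    mu_y: float
    mu_yhat: float


def _window_starts(n: int, fs: float, w: WindowSpec):
    width = int(round(w.width_s * fs))
    hop = int(round(w.hop_s * fs))
    if width < 1 or hop < 1:
        raise ParameterError("window width/hop too small for sampling rate")
    if n < width:
        return width, hop, np.empty(0, dtype=int)
    starts = np.arange(0, n - width + 1, hop)
    return width, hop, starts


def _sliding_apply(rec: Recording, w: WindowSpec, fn) -> SlidingSeries:
    width, hop, starts = _window_starts(len(rec), rec.fs_hz, w)
    if starts.size == 0:
        return SlidingSeries(np.empty(0), w, np.empty(0))
    view = np.lib.stride_tricks.sliding_window_view(rec.samples, width)[::hop]
    values = fn(view)
    centers = (starts + width / 2.0) / rec.fs_hz
    return SlidingSeries(values, w, centers)


def sliding_rms(rec: Recording, w: WindowSpec = WindowSpec(0.2, 0.1)) -> SlidingSeries:
    """Per-window root-mean-square voltage (default 200 ms / 100 ms overlap)."""
    return _sliding_apply(rec, w, lambda v: np.sqrt(np.mean(v**2, axis=1)))


def sliding_vpp(rec: Recording, w: WindowSpec = WindowSpec(0.2, 0.1)) -> SlidingSeries:
    """Per-window peak-to-peak voltage (max minus min)."""
    return _sliding_apply(rec, w, lambda v: v.max(axis=1) - v.min(axis=1))


def snr_db(signal_rms: float, noise_rms: float, power: bool = False) -> float:
    """SNR in dB from RMS values: ``10*log10(RMS_S/RMS_N)`` (or 20* with
    ``power=True``)."""
    if signal_rms <= 0 or noise_rms <= 0:
        raise ParameterError("RMS values must be positive")
    factor = 20.0 if power else 10.0
    return float(factor * np.log10(signal_rms / noise_rms))


MIN_REST_S = 10.0


def trial_snr(
    rec: Recording,
    move: IntervalSet,
    rest: IntervalSet,
    w: WindowSpec = WindowSpec(0.2, 0.1),
    power: bool = False,
) -> SlidingSeries:
    """Per-window SNR over movement periods against the rest noise floor.

    The noise floor is the mean sliding RMS over rest periods, which must
    total at least 10 s. Movement windows are windows fully inside a movement
    interval.
    """
    if rest.total_s < MIN_REST_S:
        raise DataError(
            f"need >= {MIN_REST_S:.0f} s of rest to establish a noise floor, "
            f"got {rest.total_s:.1f} s"
        )
    rest_rms = []
    for a, b in rest:
        s = sliding_rms(rec.slice_s(a, b), w)
        rest_rms.extend(s.values)
    noise_floor = float(np.mean(rest_rms))
    vals, centers = [], []
    for a, b in move:
        s = sliding_rms(rec.slice_s(a, b), w)
        for v, c in zip(s.values, s.t_centers_s):
            vals.append(snr_db(max(v, 1e-12), noise_floor, power=power))
            centers.append(a + c)
    return SlidingSeries(np.asarray(vals), w, np.asarray(centers))


def persistence_spectrum(
    rec: Recording, n_segments: int = 256, n_levels: int = 256
) -> PersistenceSpectrum:
    """Occupancy of (frequency, power level) across overlapping FFT segments.

    The signal is divided into ``n_segments`` Hamming-windowed segments with
    50% overlap; each segment's FFT power spectrum (in dB) is discretized into
    ``n_levels`` evenly spaced levels between the minimum and maximum observed
    power, and the per-(frequency, level) occurrence counts are accumulated.
    """
    n = len(rec)
    if n < 2 * n_segments:
        raise DataError("signal too short for the requested segmentation")
    # L*(n_segments+1)/2 <= n for 50% overlap
    seg_len = int(2 * n // (n_segments + 1))
    hop = seg_len // 2
    seg_len = hop * 2
    if seg_len < 4:
        raise DataError("signal too short for the requested segmentation")
    window = np.hamming(seg_len)
    starts = np.arange(n_segments) * hop
    segs = np.lib.stride_tricks.sliding_window_view(rec.samples, seg_len)[starts]
    spec = np.abs(np.fft.rfft(segs * window, axis=1)) ** 2
    power_db = 10.0 * np.log10(np.maximum(spec, 1e-300))
    lo, hi = power_db.min(), power_db.max()
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_levels + 1)
    levels = np.clip(np.digitize(power_db, edges) - 1, 0, n_levels - 1)
    n_freqs = spec.shape[1]
    counts = np.zeros((n_levels, n_freqs), dtype=np.int64)
    for f in range(n_freqs):
        counts[:, f] = np.bincount(levels[:, f], minlength=n_levels)
    freqs = np.fft.rfftfreq(seg_len, d=1.0 / rec.fs_hz)
    return PersistenceSpectrum(freqs, edges, counts, n_segments)


IN_BAND_HZ = (10.0, 1500.0)


def in_band_power_ratio(
    rec: Recording,
    w: WindowSpec = WindowSpec(2.0, 1.0),
    band_hz=IN_BAND_HZ,
    notch: bool = True,
) -> SlidingSeries:
    """Energy in 10-1500 Hz over total energy above 10 Hz, after a 50 Hz
    band-stop, per sliding window (default 2 s width, 1 s overlap)."""
    if rec.fs_hz <= 3000:
        raise ParameterError("in-band ratio requires fs > 3 kHz")
    filtered = bandstop_50(rec) if notch else rec
    lo, hi = band_hz
    fs = rec.fs_hz

    def ratio(view: np.ndarray) -> np.ndarray:
        spec = np.abs(np.fft.rfft(view, axis=1)) ** 2
        freqs = np.fft.rfftfreq(view.shape[1], d=1.0 / fs)
        above = freqs > lo
        inband = above & (freqs <= hi)
        total = spec[:, above].sum(axis=1)
        return np.where(total > 0, spec[:, inband].sum(axis=1) / np.maximum(total, 1e-300), np.nan)

    return _sliding_apply(filtered, w, ratio)


def envelope_correlation(
    env_a: Recording, env_b: Recording, w: WindowSpec = WindowSpec(0.2, 0.1)
) -> SlidingSeries:
    """Per-window Pearson correlation between two equal-rate envelopes.

    Windows where either envelope has zero variance yield NaN (missing), not
    zero.
    """
    if abs(env_a.fs_hz - env_b.fs_hz) > 1e-9:
        raise ParameterError("envelopes must share a sampling rate")
    n = min(len(env_a), len(env_b))
    a, b = env_a.samples[:n], env_b.samples[:n]
    width, hop, starts = _window_starts(n, env_a.fs_hz, w)
    if starts.size == 0:
        return SlidingSeries(np.empty(0), w, np.empty(0))
    va = np.lib.stride_tricks.sliding_window_view(a, width)[::hop]
    vb = np.lib.stride_tricks.sliding_window_view(b, width)[::hop]
    va = va - va.mean(axis=1, keepdims=True)
    vb = vb - vb.mean(axis=1, keepdims=True)
    sa = np.sqrt((va**2).sum(axis=1))
    sb = np.sqrt((vb**2).sum(axis=1))
    denom = sa * sb
    r = np.where(denom > 0, (va * vb).sum(axis=1) / np.maximum(denom, 1e-300), np.nan)
    centers = (starts + width / 2.0) / env_a.fs_hz
    return SlidingSeries(r, w, centers)


def neural_trajectory_envelope_correlation(
    neural: Recording,
    traj: Recording,
    w: WindowSpec = WindowSpec(1.0, 0.0),
    align: bool = True,
    movement_only: bool = True,
    smooth_hz: float = 10.0,
) -> SlidingSeries:
    """Sliding Pearson correlation between the neural-activity envelope and
    the whisker-movement envelope, after latency alignment.

    The neural envelope is resampled to the trajectory rate; the signal-motor
    latency is removed by envelope cross-correlation (``align=True``), and by
    default only windows centred inside movement bouts are returned — resting
    windows pair a noise envelope with a flat trajectory and carry no signal.
    """
    from .sigproc import align_by_envelope_xcorr, envelope, extract_movement_segments, movement_envelope

    env_n = envelope(neural, smooth_hz)
    t_lo = np.arange(int(neural.duration_s * traj.fs_hz)) / traj.fs_hz
    env_n_lo = np.interp(t_lo, env_n.times_s, env_n.samples)
    env_t = movement_envelope(traj, smooth_hz).samples
    n = min(env_n_lo.size, env_t.size)
    env_n_lo, env_t = env_n_lo[:n], env_t[:n]
    k = 0
    if align:
        lag_s = align_by_envelope_xcorr(neural, traj)
        k = int(round(lag_s * traj.fs_hz))
    # neural leads by k samples: pair env_n[t] with env_t[t + k]
    if k > 0:
        env_n_lo, env_t = env_n_lo[: n - k], env_t[k:]
    elif k < 0:
        env_n_lo, env_t = env_n_lo[-k:], env_t[: n + k]
    rec_n = Recording(env_n_lo, traj.fs_hz, "uV", "neural")
    rec_t = Recording(env_t, traj.fs_hz, "normalized", "trajectory")
    series = envelope_correlation(rec_n, rec_t, w)
    if movement_only:
        segs = extract_movement_segments(Recording(env_t + 0.5, traj.fs_hz, "normalized", "trajectory"))
        keep = np.array(
            [any(a <= c < b for a, b in segs) for c in series.t_centers_s], dtype=bool
        )
        series = SlidingSeries(series.values[keep], w, series.t_centers_s[keep])
    return series


def concordance_cc(
    y: Sequence[float], yhat: Sequence[float], sample_variance: bool = False
) -> CCCResult:
    """Lin's concordance correlation coefficient.

    rho_c = 2 rho sigma_y sigma_yhat / (sigma_y^2 + sigma_yhat^2 + (mu_y - mu_yhat)^2)

    Population (1/N) variances by default, per Lin's convention;
    ``sample_variance=True`` switches to 1/(N-1).
    """
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape or y.ndim != 1 or y.size < 2:
        raise ParameterError("need two equal-length 1-D sequences of length >= 2")
    ddof = 1 if sample_variance else 0
    mu_y, mu_h = y.mean(), yhat.mean()
    var_y, var_h = y.var(ddof=ddof), yhat.var(ddof=ddof)
    if var_y == 0 or var_h == 0:
        raise DataError("CCC undefined for zero-variance input")
    cov = ((y - mu_y) * (yhat - mu_h)).sum() / (y.size - ddof)
    rho = cov / np.sqrt(var_y * var_h)
    rho_c = 2 * cov / (var_y + var_h + (mu_y - mu_h) ** 2)
    return CCCResult(
        rho_c=float(rho_c),
        rho=float(rho),
        sigma_y=float(np.sqrt(var_y)),
        sigma_yhat=float(np.sqrt(var_h)),
        mu_y=float(mu_y),
        mu_yhat=float(mu_h),
    )
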