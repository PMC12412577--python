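"""Synthetic multi-subject whisker/nerve cohorts.

Generates paired recordings with the statistical structure the downstream
analysis assumes: whisking bouts separated by rest, multi-unit nerve activity
whose slow envelope tracks the movement envelope with a subject-specific
signal-to-motor latency (nerve leads movement), a calibrated movement-period
RMS over a stable rest noise floor, and energy concentrated in a sub-1500 Hz
carrier band. Off-nerve (control) recordings are broadband noise with no
trajectory coupling.

The neural carrier is band-limited Gaussian noise amplitude-modulated by the
movement envelope; multi-unit envelopes, not sorted spikes, are what every
downstream statistic consumes, so no spiking model is needed.

Default cohort parameters (see ``DEFAULT_PROFILE_KW``): movement-period RMS
13.31 uV over a 5.58 uV rest floor, 25 ms signal-to-motor latency, whisking
bouts at 5 Hz (rabbits whisk markedly slower than rats or mice) lasting
~1.5 s arriving at 0.25 /s, carrier band 300-1400 Hz, peak whisk excursion
11.2 mm of the 0-28 mm laser-micrometer range.
Trajectories are normalized to 0-1 with rest baseline 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal as sps

from .recording import ParameterError, Recording, SubjectDataset
from .sigproc import extract_movement_segments, movement_envelope

__all__ = [
    "SubjectProfile",
    "DEFAULT_PROFILE_KW",
    "make_profile",
    "draw_profiles",
    "make_cohort",
    "synthesize_trajectory",
    "synthesize_neural",
    "synthesize_offnerve",
    "synthesize_subject",
]

NEURAL_FS_HZ = 16000.0
TRAJ_FS_HZ = 125.0
EMG_FS_HZ = 4000.0
FULL_SCALE_MM = 28.0

#: fraction of the whisk oscillation that is a sustained protraction offset
#: (whisks protract from rest and return, rather than swinging symmetrically)
PROTRACTION_BIAS = 0.35


@dataclass
class SubjectProfile:
    """Generative parameters of one synthetic subject."""

    subject_id: str
    neural_gain: Optional[float]  # uV per unit movement envelope; None = calibrate
    motor_latency_ms: float  # nerve leads movement by this much
    noise_rms_uv: float  # resting noise floor RMS
    movement_rms_uv: float  # target RMS during movement
    bout_rate_hz: float  # expected bouts per second
    bout_duration_s: float  # mean bout length
    whisk_freq_hz: float  # protraction/retraction rate within a bout
    band_edges_hz: Tuple[float, float]  # neural carrier band
    traj_amplitude_mm: float  # peak whisk excursion
    rng_seed: int

    def __post_init__(self) -> None:
        if self.noise_rms_uv >= self.movement_rms_uv:
            raise ParameterError("noise floor must lie below movement RMS")
        lo, hi = self.band_edges_hz
        if not (0 < lo < hi < NEURAL_FS_HZ / 2):
            raise ParameterError("band edges must lie within (0, Nyquist)")
        if self.motor_latency_ms < 0:
            raise ParameterError("motor latency must be >= 0")


DEFAULT_PROFILE_KW = dict(
    neural_gain=None,
    motor_latency_ms=25.0,
    noise_rms_uv=5.58,
    movement_rms_uv=13.31,
    bout_rate_hz=0.25,
    bout_duration_s=1.5,
    whisk_freq_hz=5.0,
    band_edges_hz=(300.0, 1400.0),
    traj_amplitude_mm=11.2,
)


def make_profile(subject_id: str = "S0", rng_seed: int = 0, **overrides) -> SubjectProfile:
    """A SubjectProfile with cohort-default parameters plus overrides."""
    kw = dict(DEFAULT_PROFILE_KW)
    kw.update(overrides)
    return SubjectProfile(subject_id=subject_id, rng_seed=rng_seed, **kw)


def synthesize_trajectory(profile: SubjectProfile, duration_s: float) -> Recording:
    """Normalized whisker trajectory: rest at 0.5, whisking bouts in between.

    Bout onsets follow a Poisson process at ``bout_rate_hz`` (non-overlapping;
    onsets during an ongoing bout are dropped); bout lengths are exponential
    around ``bout_duration_s`` clipped to [0.4 s, 4 s]. Within a bout the
    whisker oscillates at ``whisk_freq_hz`` with a protraction-biased waveform
    under a smooth (raised-cosine ramp) amplitude envelope whose plateau level
    varies slowly between whisks.
    """
    if duration_s <= 0:
        raise ParameterError("duration must be positive")
    rng = np.random.default_rng(profile.rng_seed)
    fs = TRAJ_FS_HZ
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    amp_env = np.zeros(n)

    if profile.bout_rate_hz > 0:
        # candidate onsets from a Poisson process; enforce non-overlap
        expected = duration_s * profile.bout_rate_hz
        n_cand = rng.poisson(expected * 1.5) + 1
        onsets = np.sort(rng.uniform(0.2, max(duration_s - 0.5, 0.3), size=n_cand))
        cursor = -np.inf
        ramp_s = 0.25
        for onset in onsets:
            if onset < cursor + 0.4:  # refractory gap after previous bout
                continue
            dur = float(np.clip(rng.exponential(profile.bout_duration_s), 0.4, 4.0))
            dur = min(dur, duration_s - onset)
            if dur < 0.4:
                continue
            i0, i1 = int(onset * fs), int((onset + dur) * fs)
            seg = np.ones(i1 - i0)
            nr = max(int(ramp_s * fs), 1)
            nr = min(nr, seg.size // 2)
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
            seg[:nr] *= ramp
            seg[seg.size - nr:] *= ramp[::-1]
            # slow within-bout amplitude drift
            drift = 1.0 + 0.25 * np.sin(
                2 * np.pi * rng.uniform(0.2, 0.6) * (t[i0:i1] - onset) + rng.uniform(0, 2 * np.pi)
            )
            amp_env[i0:i1] = np.maximum(amp_env[i0:i1], seg * drift * rng.uniform(0.7, 1.0))
            cursor = onset + dur

    amp_norm = profile.traj_amplitude_mm / FULL_SCALE_MM
    phase = 2 * np.pi * profile.whisk_freq_hz * t + rng.uniform(0, 2 * np.pi)
    waveform = PROTRACTION_BIAS + (1 - PROTRACTION_BIAS) * np.sin(phase)
    traj = 0.5 + amp_norm * amp_env * waveform
    traj = np.clip(traj, 0.0, 1.0)
    return Recording(traj, fs_hz=fs, unit="normalized", kind="trajectory")


def _band_noise(rng: np.random.Generator, n: int, fs: float, band: Tuple[float, float]) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` (zero-phase filter)."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    return x / max(x.std(), 1e-12)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / max(x.std(), 1e-12)


def _modulation_envelope(trajectory: Recording, fs_out: float) -> np.ndarray:
    """Smoothed movement envelope of a trajectory, upsampled to ``fs_out``."""
    env = movement_envelope(trajectory, smooth_hz=10.0).samples
    n_out = int(round(len(env) * fs_out / trajectory.fs_hz))
    t_in = np.arange(env.size) / trajectory.fs_hz
    t_out = np.arange(n_out) / fs_out
    return np.interp(t_out, t_in, env)


def synthesize_neural(
    profile: SubjectProfile,
    trajectory: Recording,
    fs_hz: float = NEURAL_FS_HZ,
) -> Recording:
    """Extraneural signal whose envelope tracks the trajectory envelope.

    Band-limited Gaussian carrier amplitude-modulated by the trajectory's
    movement envelope advanced by ``motor_latency_ms`` (nerve activity leads
    the movement it drives), over a white+pink noise floor of
    ``noise_rms_uv``. If ``neural_gain`` is None the modulation gain is
    calibrated so that the RMS over movement periods equals
    ``movement_rms_uv``.
    """
    tmin, tmax = trajectory.samples.min(), trajectory.samples.max()
    if tmin < -1e-9 or tmax > 1 + 1e-9:
        raise ParameterError("trajectory must be normalized to 0-1")
    lat_s = profile.motor_latency_ms / 1000.0
    if lat_s >= trajectory.duration_s:
        raise ParameterError("latency exceeds recording duration")
    rng = np.random.default_rng(profile.rng_seed + 1)
    n = int(round(trajectory.duration_s * fs_hz))
    env = _modulation_envelope(trajectory, fs_hz)[:n]
    # advance the envelope: neural activity at t reflects movement at t + lat
    shift = int(round(lat_s * fs_hz))
    env_lead = np.concatenate((env[shift:], np.full(shift, env[-1]))) if shift else env

    gain = profile.neural_gain
    if gain is None:
        segs = extract_movement_segments(trajectory)
        mask = np.zeros(n, dtype=bool)
        for a, b in segs:
            mask[int(a * fs_hz): int(b * fs_hz)] = True
        env_rms = np.sqrt(np.mean(env_lead[mask] ** 2)) if mask.any() else 0.0
        if env_rms > 0:
            target_mod = np.sqrt(
                max(profile.movement_rms_uv**2 - profile.noise_rms_uv**2, 0.0)
            )
            gain = target_mod / env_rms
        else:
            gain = 0.0

    carrier = _band_noise(rng, n, fs_hz, profile.band_edges_hz)
    noise = profile.noise_rms_uv * (
        0.8 * rng.standard_normal(n) + 0.6 * _pink_noise(rng, n)
    )
    x = gain * env_lead * carrier + noise
    return Recording(x, fs_hz=fs_hz, unit="uV", kind="neural")


def synthesize_emg(profile: SubjectProfile, trajectory: Recording) -> Recording:
    """Whisker-pad EMG: a second modulated channel at 4 kHz, shorter latency."""
    emg_profile = replace(
        profile,
        rng_seed=profile.rng_seed + 2,
        motor_latency_ms=max(profile.motor_latency_ms - 15.0, 0.0),
        band_edges_hz=(20.0, 450.0),
        noise_rms_uv=profile.noise_rms_uv * 2.0,
        movement_rms_uv=profile.movement_rms_uv * 6.0,
        neural_gain=None if profile.neural_gain is None else profile.neural_gain * 6.0,
    )
    rec = synthesize_neural(emg_profile, trajectory, fs_hz=EMG_FS_HZ)
    return rec.replace(rec.samples, kind="emg")


def synthesize_offnerve(profile: SubjectProfile, duration_s: float) -> Recording:
    """Off-nerve control: broadband noise, no trajectory coupling."""
    if duration_s <= 0:
        raise ParameterError("duration must be positive")
    rng = np.random.default_rng(profile.rng_seed + 3)
    n = int(round(duration_s * NEURAL_FS_HZ))
    x = profile.noise_rms_uv * (
        0.8 * rng.standard_normal(n) + 0.6 * _pink_noise(rng, n)
    )
    return Recording(x, fs_hz=NEURAL_FS_HZ, unit="uV", kind="neural")


def synthesize_subject(
    profile: SubjectProfile, duration_s: float, with_emg: bool = False
) -> SubjectDataset:
    """Paired trajectory + neural (+ EMG) recordings for one profile."""
    traj = synthesize_trajectory(profile, duration_s)
    neural = synthesize_neural(profile, traj)
    emg = synthesize_emg(profile, traj) if with_emg else None
    return SubjectDataset(
        subject_id=profile.subject_id,
        neural=neural,
        trajectory=traj,
        emg=emg,
        ground_truth_latency_ms=profile.motor_latency_ms,
    )


def draw_profiles(
    n_subjects: int, base_seed: int, heterogeneity: float = 0.3
) -> List[SubjectProfile]:
    """Subject profiles drawn around the cohort defaults.

    ``heterogeneity`` scales the inter-subject spread: multiplicative
    (log-normal) on neural gain (via the movement-RMS target), noise floor,
    whisk amplitude/frequency, carrier-band placement (electrode-tissue
    coupling differs per subject) and bout statistics (whisking vigor differs
    per animal), and additive on the signal-to-motor latency
    (sd = heterogeneity x 50 ms) — latency differences across subjects must
    span several trajectory samples for there to be anything for a
    subject-specific decoder to compensate. At heterogeneity 0 all profiles
    are identical except for their RNG seeds.
    """
    if n_subjects < 1:
        raise ParameterError("need at least one subject")
    ss = np.random.SeedSequence(base_seed)
    subject_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_subjects)]
    meta_rng = np.random.default_rng(ss.spawn(1)[0])
    h = float(heterogeneity)
    profiles = []
    for i, seed in enumerate(subject_seeds):
        z = meta_rng.standard_normal(8)
        band_scale = np.exp(h * 0.4 * z[5])
        lo, hi = DEFAULT_PROFILE_KW["band_edges_hz"]
        profiles.append(
            make_profile(
                subject_id=f"S{i}",
                rng_seed=seed,
                movement_rms_uv=DEFAULT_PROFILE_KW["movement_rms_uv"] * np.exp(h * 0.5 * z[0]),
                noise_rms_uv=DEFAULT_PROFILE_KW["noise_rms_uv"] * np.exp(h * 0.3 * z[1]),
                motor_latency_ms=float(
                    max(DEFAULT_PROFILE_KW["motor_latency_ms"] + h * 50.0 * z[2], 0.0)
                ),
                traj_amplitude_mm=float(
                    np.clip(
                        DEFAULT_PROFILE_KW["traj_amplitude_mm"] * np.exp(h * z[3]), 2.0, 14.0
                    )
                ),
                whisk_freq_hz=DEFAULT_PROFILE_KW["whisk_freq_hz"] * np.exp(h * 0.25 * z[4]),
                band_edges_hz=(
                    float(np.clip(lo * band_scale, 50.0, 800.0)),
                    float(np.clip(hi * band_scale, 900.0, 2500.0)),
                ),
                bout_rate_hz=DEFAULT_PROFILE_KW["bout_rate_hz"] * np.exp(h * 0.5 * z[6]),
                bout_duration_s=float(
                    np.clip(DEFAULT_PROFILE_KW["bout_duration_s"] * np.exp(h * 0.5 * z[7]), 0.5, 3.5)
                ),
            )
        )
    return profiles


def make_cohort(
    n_subjects: int,
    duration_s: float,
    base_seed: int,
    heterogeneity: float = 0.3,
    with_emg: bool = False,
) -> List[SubjectDataset]:
    """A cohort of synthetic subjects drawn around the default profile."""
    if duration_s < 10:
        raise ParameterError("duration must be >= 10 s")
    profiles = draw_profiles(n_subjects, base_seed, heterogeneity)
    return [synthesize_subject(p, duration_s, with_emg=with_emg) for p in profiles]
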