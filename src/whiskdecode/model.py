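"""The whisker-decoding network: streaming windows, handcrafted features,
a two-pathway encoder and a temporal self-attention decoder.

Streaming contract
------------------
The network consumes a neural stream sampled at ``fs_data`` and emits one
normalized whisker position (0-1, rest 0.5) per trajectory sample at
``fs_laser``. Input windows are ``n_pad = 2000`` samples long with a stride of
``fs_data / fs_laser`` (128 samples for 16 kHz / 125 Hz); window ``k`` covers
neural samples ``[k*stride, k*stride + n_pad)`` and its output corresponds to
trajectory sample ``k + (n_pad - 1) // stride`` (the time of the window's last
neural sample).

Encoder
-------
* handcrafted pathway: the 2000-sample window is cut into 16 sub-windows of
  125 samples; 10 classic time-domain features per sub-window, z-scored by
  per-subject feature statistics, run through an LSTM (hidden 30) whose final
  state passes a 30->30 dense layer.
* CNN pathway: the z-scored raw window passes a 1-D convolution producing 16
  channels (kernel 7, stride 8 for temporal decimation), is arranged as a
  channels-x-time image, then two rounds of 2x2 average pooling and
  single-channel 3x3 convolution, and the resulting columns feed an LSTM
  (hidden 30).

Decoder
-------
The two 30-dim latents are fused by a dense layer into a 60-dim feature F_t;
a buffer keeps the last 16 F vectors (zero-initialized). Shared dense+ReLU
maps give 30-dim key/query/value per buffered vector; attention scores are
``softmax(K_i . Q_i / 4)`` over the 16 slots, the context is the score-weighted
sum of values, and a many-to-one dense layer plus sigmoid yields the output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .nn.autodiff import (
    Tensor,
    avgpool2d,
    concat,
    conv1d,
    conv2d_3x3_same,
    no_grad,
    sliding_buffer,
    softmax,
)
from .nn.layers import ParamStore, dense, init_dense, init_lstm, lstm
from .recording import DataError, ParameterError, Recording

__all__ = [
    "StreamSpec",
    "NormalizationParams",
    "ModelConfig",
    "AttentionBuffer",
    "stream_windows",
    "window_target_offset",
    "extract_handcrafted",
    "compute_norm_params",
    "init_encoder_params",
    "init_decoder_params",
    "encoder_forward",
    "decoder_forward",
    "attention_step",
    "decode_step",
    "forward",
    "params_hash",
    "save_params",
    "load_params",
    "FEATURE_NAMES",
    "FULL_SCALE_MM",
]

N_PAD = 2000
FEATURE_WIN = 125
N_FEATURE_WINDOWS = N_PAD // FEATURE_WIN  # 16
N_FEATURES = 10
LATENT_DIM = 30
FUSED_DIM = 60
KQV_DIM = 30
BUFFER_LEN = 16
ATTN_DIVISOR = 4.0  # fixed scaling constant (= sqrt of the 16-slot buffer length)
CONV1D_CHANNELS = 16
CONV1D_KERNEL = 7
CONV1D_STRIDE = 8
FULL_SCALE_MM = 28.0

FEATURE_NAMES = (
    "mav",  # mean absolute value
    "ssi",  # simple square integral
    "aac",  # average amplitude change
    "std",  # standard deviation
    "rms",  # root mean square
    "wl",  # waveform length
    "zc",  # zero crossings
    "ssc",  # slope sign changes
    "wamp",  # Willison amplitude
    "var",  # variance
)
ZC_DEADBAND = 0.01
WAMP_THRESHOLD = 0.5  # on the z-scored raw scale


@dataclass(frozen=True)
class StreamSpec:
    """Streaming geometry of the decoder input/output."""

    fs_data: float = 16000.0
    fs_laser: float = 125.0
    n_pad: int = N_PAD

    def __post_init__(self) -> None:
        ratio = self.fs_data / self.fs_laser
        if abs(ratio - round(ratio)) > 1e-9:
            raise ParameterError("fs_data must be an integer multiple of fs_laser")
        if self.n_pad < int(round(ratio)):
            raise ParameterError("n_pad must be at least one stride")

    @property
    def stride(self) -> int:
        return int(round(self.fs_data / self.fs_laser))

    def n_windows(self, n_samples: int) -> int:
        if n_samples < self.n_pad:
            return 0
        return (n_samples - self.n_pad) // self.stride + 1


def window_target_offset(spec: StreamSpec) -> int:
    """Trajectory-sample index of window 0's output (warm-up offset)."""
    return (spec.n_pad - 1) // spec.stride


def stream_windows(x, spec: StreamSpec = StreamSpec()) -> np.ndarray:
    """View of all input windows, shape (n_windows, n_pad)."""
    samples = x.samples if isinstance(x, Recording) else np.asarray(x)
    if samples.size < spec.n_pad:
        raise DataError(
            f"input of {samples.size} samples shorter than one window ({spec.n_pad})"
        )
    n = spec.n_windows(samples.size)
    view = np.lib.stride_tricks.sliding_window_view(samples, spec.n_pad)
    return view[:: spec.stride][:n]


# -- handcrafted features -----------------------------------------------------

def _features_of_subwindows(sub: np.ndarray) -> np.ndarray:
    """Feature block for sub-windows shaped (..., n_sub, win)."""
    d = np.diff(sub, axis=-1)
    mav = np.abs(sub).mean(axis=-1)
    ssi = (sub**2).sum(axis=-1)
    aac = np.abs(d).mean(axis=-1)
    std = sub.std(axis=-1)
    rms = np.sqrt((sub**2).mean(axis=-1))
    wl = np.abs(d).sum(axis=-1)
    zc = (
        (sub[..., :-1] * sub[..., 1:] < 0)
        & (np.abs(d) > ZC_DEADBAND)
    ).sum(axis=-1).astype(np.float64)
    ssc = (
        (d[..., :-1] * d[..., 1:] < 0)
        & ((np.abs(d[..., :-1]) > ZC_DEADBAND) | (np.abs(d[..., 1:]) > ZC_DEADBAND))
    ).sum(axis=-1).astype(np.float64)
    wamp = (np.abs(d) > WAMP_THRESHOLD).sum(axis=-1).astype(np.float64)
    var = sub.var(axis=-1)
    return np.stack([mav, ssi, aac, std, rms, wl, zc, ssc, wamp, var], axis=-1)


def extract_handcrafted(
    windows: np.ndarray, norm: Optional["NormalizationParams"] = None
) -> np.ndarray:
    """10 features per 125-sample sub-window of each 2000-sample input window.

    ``windows`` is (B, 2000) of *raw-normalized* samples. Returns
    (B, 16, 10); if ``norm`` is given each feature is z-scored by its stored
    per-feature statistics.
    """
    windows = np.atleast_2d(np.asarray(windows, dtype=np.float64))
    if windows.shape[-1] != N_PAD:
        raise ParameterError(f"windows must have {N_PAD} samples")
    sub = windows.reshape(windows.shape[0], N_FEATURE_WINDOWS, FEATURE_WIN)
    feats = _features_of_subwindows(sub)
    if norm is not None:
        feats = (feats - norm.feature_means) / norm.feature_stds
    return feats


@dataclass
class NormalizationParams:
    """Per-subject z-scoring statistics for raw samples and features."""

    raw_mean: float
    raw_std: float
    feature_means: np.ndarray
    feature_stds: np.ndarray
    source_duration_s: float
    source_tag: str = "train"

    def __post_init__(self) -> None:
        self.feature_means = np.asarray(self.feature_means, dtype=np.float64)
        self.feature_stds = np.asarray(self.feature_stds, dtype=np.float64)
        if self.raw_std <= 0 or np.any(self.feature_stds <= 0):
            raise DataError("normalization stds must be positive")

    def normalize_raw(self, x: np.ndarray) -> np.ndarray:
        return (x - self.raw_mean) / self.raw_std


def compute_norm_params(
    data: Recording,
    spec: StreamSpec = StreamSpec(),
    max_windows: int = 2000,
    source_tag: str = "train",
) -> NormalizationParams:
    """Normalization statistics from a subject's own (training) data.

    Raw mean/std over the samples; per-feature mean/std over the handcrafted
    features of (up to ``max_windows`` evenly spaced) raw-normalized windows.
    """
    x = data.samples
    mu, sd = float(x.mean()), float(x.std())
    if sd == 0:
        raise DataError("zero-variance input: normalization undefined")
    wins = stream_windows(data, spec)
    if wins.shape[0] > max_windows:
        sel = np.linspace(0, wins.shape[0] - 1, max_windows).astype(int)
        wins = wins[sel]
    feats = extract_handcrafted((wins - mu) / sd)
    fmu = feats.reshape(-1, N_FEATURES).mean(axis=0)
    fsd = feats.reshape(-1, N_FEATURES).std(axis=0)
    fsd = np.maximum(fsd, 1e-6)
    return NormalizationParams(mu, sd, fmu, fsd, data.duration_s, source_tag)


# -- parameters ---------------------------------------------------------------

@dataclass
class ModelConfig:
    stream: StreamSpec = field(default_factory=StreamSpec)
    n_features: int = N_FEATURES
    latent_dim: int = LATENT_DIM
    fused_dim: int = FUSED_DIM
    kqv_dim: int = KQV_DIM
    buffer_len: int = BUFFER_LEN


def _cnn_shape() -> Tuple[int, int]:
    """(rows, columns) of the CNN pathway output before the recurrent stage."""
    t1 = (N_PAD - CONV1D_KERNEL) // CONV1D_STRIDE + 1  # conv1d time axis
    h, w = CONV1D_CHANNELS // 2, t1 // 2  # first pool
    h, w = h // 2, w // 2  # second pool
    return h, w


def init_encoder_params(rng: np.random.Generator, dtype=np.float64) -> ParamStore:
    p: ParamStore = {}
    init_lstm(p, "enc.hand_lstm", N_FEATURES, LATENT_DIM, rng)
    init_dense(p, "enc.hand_fc", LATENT_DIM, LATENT_DIM, rng)
    scale = 1.0 / np.sqrt(CONV1D_KERNEL)
    p["enc.conv1.W"] = Tensor(
        rng.uniform(-scale, scale, size=(CONV1D_CHANNELS, CONV1D_KERNEL)), requires_grad=True
    )
    p["enc.conv1.b"] = Tensor(np.zeros(CONV1D_CHANNELS), requires_grad=True)
    for name in ("enc.c2d1", "enc.c2d2"):
        p[f"{name}.k"] = Tensor(rng.uniform(-1 / 3, 1 / 3, size=(3, 3)), requires_grad=True)
        p[f"{name}.b"] = Tensor(np.zeros(()), requires_grad=True)
    rows, _ = _cnn_shape()
    init_lstm(p, "enc.cnn_lstm", rows, LATENT_DIM, rng)
    return _cast_params(p, dtype)


def init_decoder_params(rng: np.random.Generator, dtype=np.float64) -> ParamStore:
    p: ParamStore = {}
    init_dense(p, "dec.fuse", FUSED_DIM, FUSED_DIM, rng)
    for name in ("dec.key", "dec.query", "dec.value"):
        init_dense(p, name, FUSED_DIM, KQV_DIM, rng)
    init_dense(p, "dec.out", KQV_DIM, 1, rng)
    return _cast_params(p, dtype)


def _cast_params(p: ParamStore, dtype) -> ParamStore:
    for k in p:
        p[k].data = p[k].data.astype(dtype, copy=False)
    return p


def params_dtype(p: ParamStore):
    return next(iter(p.values())).data.dtype


# -- forward passes -----------------------------------------------------------

def encoder_forward(params: ParamStore, raw_windows: np.ndarray, features: np.ndarray) -> Tensor:
    """Both encoder pathways; returns fused-input latents (B, 60)."""
    feat_t = Tensor(features)
    hand = lstm(params, "enc.hand_lstm", feat_t)
    hand = dense(params, "enc.hand_fc", hand).relu()

    x = Tensor(raw_windows)
    c = conv1d(x, params["enc.conv1.W"], params["enc.conv1.b"], stride=CONV1D_STRIDE).relu()
    c = avgpool2d(c, 2)
    c = conv2d_3x3_same(c, params["enc.c2d1.k"], params["enc.c2d1.b"]).relu()
    c = avgpool2d(c, 2)
    c = conv2d_3x3_same(c, params["enc.c2d2.k"], params["enc.c2d2.b"]).relu()
    seq = c.transpose(0, 2, 1)  # (B, time, rows)
    cnn = lstm(params, "enc.cnn_lstm", seq)
    return concat([hand, cnn], axis=1)


def decoder_forward(params: ParamStore, latents: Tensor) -> Tensor:
    """Attention decoder over latent sequences (S, L, 60) -> outputs (S, L)."""
    F = dense(params, "dec.fuse", latents)  # linear fusion
    buf = sliding_buffer(F, BUFFER_LEN)  # (S, L, 16, 60)
    K = dense(params, "dec.key", buf).relu()
    Q = dense(params, "dec.query", buf).relu()
    V = dense(params, "dec.value", buf).relu()
    logits = (K * Q).sum(axis=-1) / ATTN_DIVISOR  # (S, L, 16)
    s = softmax(logits, axis=-1)
    S_, L_, B_, D_ = V.shape
    ctx = (s.reshape(S_, L_, B_, 1) * V).sum(axis=2)  # (S, L, 30)
    y = dense(params, "dec.out", ctx).sigmoid()
    return y.reshape(S_, L_)


class AttentionBuffer:
    """Fixed-capacity (16) buffer of fused feature vectors, zero-initialized."""

    def __init__(self, capacity: int = BUFFER_LEN, dim: int = FUSED_DIM):
        self.capacity = capacity
        self.dim = dim
        self._slots = np.zeros((capacity, dim))

    def push(self, f: np.ndarray) -> None:
        self._slots = np.concatenate([self._slots[1:], np.asarray(f).reshape(1, self.dim)])

    @property
    def slots(self) -> np.ndarray:
        """(capacity, dim); slot -1 is the current F_t, slot 0 the oldest."""
        return self._slots.copy()


def attention_step(buffer: AttentionBuffer, params: ParamStore) -> Tuple[np.ndarray, np.ndarray]:
    """One attention evaluation over a full buffer.

    Returns ``(scores, context)``: 16 scores summing to 1 and the 30-dim
    score-weighted combination of the value vectors.
    """
    with no_grad():
        buf = Tensor(buffer.slots[None, None])  # (1, 1, 16, 60)
        K = dense(params, "dec.key", buf).relu().data[0, 0]
        Q = dense(params, "dec.query", buf).relu().data[0, 0]
        V = dense(params, "dec.value", buf).relu().data[0, 0]
    logits = (K * Q).sum(axis=-1).astype(np.float64) / ATTN_DIVISOR
    z = logits - logits.max()
    s = np.exp(z) / np.exp(z).sum()
    return s, s @ V.astype(np.float64)


def decode_step(
    hand_latent: np.ndarray,
    cnn_latent: np.ndarray,
    buffer: AttentionBuffer,
    params: ParamStore,
) -> float:
    """One streaming decoder step; pushes F_t into the buffer, returns y in (0,1)."""
    with no_grad():
        lat = Tensor(np.concatenate([hand_latent, cnn_latent]).reshape(1, -1))
        f_t = dense(params, "dec.fuse", lat).data[0]
        buffer.push(f_t)
        _, ctx = attention_step(buffer, params)
        y = dense(params, "dec.out", Tensor(ctx.reshape(1, -1))).sigmoid().data
    return float(y.ravel()[0])


def forward(
    x: Recording,
    encoder: ParamStore,
    decoder: ParamStore,
    norm: NormalizationParams,
    spec: StreamSpec = StreamSpec(),
    mm: bool = False,
    chunk: int = 4096,
) -> Recording:
    """Full streaming forward pass: neural recording -> decoded trajectory.

    Output is at ``fs_laser``; sample ``k`` corresponds to trajectory index
    ``k + window_target_offset(spec)`` of a co-recorded trajectory. ``mm=True``
    scales the normalized output by the 28 mm full range.
    """
    wins = stream_windows(x, spec)
    dtype = params_dtype(encoder)
    with no_grad():
        lats = []
        for i in range(0, wins.shape[0], chunk):
            block = wins[i : i + chunk]
            raw = norm.normalize_raw(block)
            feats = extract_handcrafted(raw, norm).astype(dtype)
            lats.append(encoder_forward(encoder, raw.astype(dtype), feats).data)
        latents = Tensor(np.concatenate(lats)[None])  # (1, T, 60)
        y = decoder_forward(decoder, latents).data[0].astype(np.float64)
    if mm:
        y = y * FULL_SCALE_MM
    return Recording(y, fs_hz=spec.fs_laser, unit="mm" if mm else "normalized", kind="trajectory")


# -- serialization ------------------------------------------------------------

def params_hash(params: ParamStore) -> str:
    """SHA-256 over parameter names and exact float64 bytes."""
    h = hashlib.sha256()
    for name in sorted(params):
        h.update(name.encode())
        h.update(np.ascontiguousarray(params[name].data, dtype=np.float64).tobytes())
    return h.hexdigest()


def save_params(params: ParamStore, path, extra_manifest: Optional[Dict] = None) -> None:
    """Single portable .npz with an embedded JSON manifest."""
    arrays = {name: params[name].data for name in params}
    manifest = {
        "layers": {name: list(params[name].data.shape) for name in sorted(params)},
        "hash": params_hash(params),
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    np.savez(path, __manifest__=np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8), **arrays)


def load_params(path) -> Tuple[ParamStore, Dict]:
    with np.load(path) as data:
        manifest = json.loads(bytes(data["__manifest__"]).decode())
        params = {
            name: Tensor(data[name].copy(), requires_grad=True)
            for name in data.files
            if name != "__manifest__"
        }
    if params_hash(params) != manifest["hash"]:
        raise DataError("model file hash mismatch")
    return params, manifest
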