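"""CCC-loss sequence-to-sequence training with shared-encoder adaptation.

Three phases:

1. *Parameter sharing* — one encoder is trained jointly on all training
   subjects while each subject keeps a private decoder (``fit``).
2. *Adaptation* — for a new subject, a freshly initialized decoder is trained
   on a limited amount of that subject's data while the encoder stays frozen
   (``adapt``). Because the encoder is frozen, its latents for the adaptation
   data are computed once and cached, which makes adaptation cheap.
3. *Testing* — a pure forward pass with the frozen encoder and the adapted
   decoder (``predict``).

The training criterion is ``1 - CCC`` computed over contiguous output
sequences (default 125 steps = 1 s), minimized with Adam. Training sequences
are sampled with a bias toward movement bouts, mirroring an analysis pipeline
that concatenates movement-related activity; a fraction of purely resting
sequences keeps the rest baseline calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from sklearn.base import BaseEstimator

from . import model as M
from .metrics import concordance_cc
from .nn.autodiff import Tensor, no_grad
from .nn.layers import ParamStore
from .nn.optim import Adam
from .recording import DataError, ParameterError, Recording, SubjectDataset
from .sigproc import extract_movement_segments

__all__ = [
    "TrainConfig",
    "ccc_loss",
    "WhiskerNetRegressor",
    "SharedDecoderRegressor",
    "IndividualRegressor",
    "SharedModel",
    "fit_shared",
    "adapt",
    "predict_test",
    "compute_norm_params",
]

MAX_ADAPTATION_S = 500.0
TRAIN_DTYPE = np.float32  # single precision for the optimization loops


@dataclass
class TrainConfig:
    """Hyperparameters of the shared-encoder training procedure."""

    epochs: int = 6
    learning_rate: float = 2e-3
    sequence_length_steps: int = 125  # outputs per training sequence (1 s)
    batch_size: int = 4  # sequences per optimization step
    batches_per_subject: int = 10  # optimization steps per subject per epoch
    seed: int = 0
    adaptation_data_s: float = 60.0
    adaptation_steps: int = 300
    adaptation_lr: float = 5e-3
    normalization_source_s: float = 1000.0
    train_fraction: float = 0.85  # rest of the training split is validation
    movement_bias: float = 0.75  # fraction of sequences sampled inside bouts
    eps: float = 1e-6  # variance guard in the differentiable loss

    def __post_init__(self) -> None:
        if self.adaptation_data_s > MAX_ADAPTATION_S:
            raise ParameterError(
                f"adaptation data capped at {MAX_ADAPTATION_S:.0f} s"
            )


def compute_norm_params(
    data: Recording, features: bool = True, source_tag: str = "train"
) -> M.NormalizationParams:
    """Normalization statistics from a subject's own data (thin wrapper)."""
    del features  # feature statistics are always computed alongside raw stats
    return M.compute_norm_params(data, source_tag=source_tag)


def ccc_loss(y, yhat) -> float:
    """``1 - rho_c`` (minimization form of the concordance correlation)."""
    return 1.0 - concordance_cc(y, yhat).rho_c


def _ccc_loss_t(y_pred: Tensor, y_true: np.ndarray, eps: float) -> Tensor:
    """Differentiable mean (1 - CCC) over sequence rows (S, L)."""
    y_true = np.asarray(y_true, dtype=y_pred.data.dtype)
    S, L = y_true.shape
    mu_t = y_true.mean(axis=1, keepdims=True)
    var_t = y_true.var(axis=1)  # population variance
    mu_p = y_pred.mean(axis=1, keepdims=True)
    dp = y_pred - mu_p
    var_p = (dp * dp).mean(axis=1)
    cov = (dp * Tensor(y_true - mu_t)).mean(axis=1)
    dmu = (mu_p - Tensor(mu_t)).reshape(S)
    rho_c = (2.0 * cov) / (var_p + Tensor(var_t) + dmu * dmu + eps)
    return (1.0 - rho_c).mean()


# -- per-subject training data ------------------------------------------------

class _SubjectData:
    """Windows, aligned targets and movement-aware sequence starts."""

    def __init__(self, ds: SubjectDataset, cfg: TrainConfig, spec: M.StreamSpec,
                 norm: Optional[M.NormalizationParams] = None, tag: str = "train"):
        self.subject_id = ds.subject_id
        self.spec = spec
        if norm is None:
            norm = M.compute_norm_params(ds.neural, spec, source_tag=tag)
        self.norm = norm
        self.windows = M.stream_windows(ds.neural, spec)  # view
        offset = M.window_target_offset(spec)
        n_out = self.windows.shape[0]
        traj = ds.trajectory.samples
        self.targets = traj[offset : offset + n_out].astype(np.float64)
        n_out = min(n_out, self.targets.size)
        self.n_steps = n_out
        L = cfg.sequence_length_steps
        if n_out < L:
            raise DataError("recording shorter than one training sequence")
        # movement-aware start-step candidates
        segs = extract_movement_segments(ds.trajectory)
        move = np.zeros(n_out, dtype=bool)
        fs = ds.trajectory.fs_hz
        for a, b in segs:
            i0 = max(int(a * fs) - offset, 0)
            i1 = max(int(b * fs) - offset, 0)
            move[i0:i1] = True
        valid = np.arange(n_out - L + 1)
        overlap = np.convolve(move.astype(float), np.ones(L), mode="full")[L - 1 : L - 1 + valid.size]
        self.move_starts = valid[overlap >= 0.2 * L]
        self.all_starts = valid
        if self.move_starts.size == 0:
            self.move_starts = valid

    def sample_batch(self, rng: np.random.Generator, cfg: TrainConfig):
        L = cfg.sequence_length_steps
        starts = []
        for _ in range(cfg.batch_size):
            pool = self.move_starts if rng.random() < cfg.movement_bias else self.all_starts
            starts.append(int(pool[rng.integers(pool.size)]))
        raw = np.concatenate([self.windows[s : s + L] for s in starts])
        raw = self.norm.normalize_raw(raw)
        feats = M.extract_handcrafted(raw, self.norm).astype(TRAIN_DTYPE)
        targets = np.stack([self.targets[s : s + L] for s in starts])
        return raw.astype(TRAIN_DTYPE), feats, targets

    def eval_slice(self, max_steps: int = 1500):
        """A contiguous evaluation stretch (capped) for validation CCC."""
        n = min(self.n_steps, max_steps)
        raw = self.norm.normalize_raw(np.asarray(self.windows[:n]))
        feats = M.extract_handcrafted(raw, self.norm).astype(TRAIN_DTYPE)
        return raw.astype(TRAIN_DTYPE), feats, self.targets[:n]


def _forward_batch(encoder: ParamStore, decoder: ParamStore, raw, feats, n_seq: int):
    latents = M.encoder_forward(encoder, raw, feats)
    L = raw.shape[0] // n_seq
    latents = latents.reshape(n_seq, L, M.FUSED_DIM)
    return M.decoder_forward(decoder, latents)


def _eval_ccc(encoder: ParamStore, decoder: ParamStore, subj: _SubjectData) -> float:
    raw, feats, targets = subj.eval_slice()
    with no_grad():
        y = _forward_batch(encoder, decoder, raw, feats, 1).data[0]
    try:
        return concordance_cc(targets, y).rho_c
    except DataError:
        return float("nan")


def _clone_params(params: ParamStore) -> ParamStore:
    return {k: Tensor(params[k].data.copy(), requires_grad=True) for k in params}


# -- estimators ---------------------------------------------------------------

class _BaseTrainer(BaseEstimator):
    """Shared machinery: round-robin CCC-loss training over subjects."""

    def _cfg(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            sequence_length_steps=self.sequence_length_steps,
            batch_size=self.batch_size,
            batches_per_subject=self.batches_per_subject,
            seed=self.seed,
            adaptation_data_s=self.adaptation_data_s,
            adaptation_steps=self.adaptation_steps,
            adaptation_lr=self.adaptation_lr,
            train_fraction=self.train_fraction,
            movement_bias=self.movement_bias,
            eps=self.eps,
        )

    def _train_loop(
        self,
        subjects: List[_SubjectData],
        encoder: ParamStore,
        decoders: Dict[str, ParamStore],
        decoder_of,  # subject_id -> decoder key
        cfg: TrainConfig,
        rng: np.random.Generator,
        train_encoder: bool = True,
        val_subjects: Optional[List[_SubjectData]] = None,
    ):
        enc_opt = Adam(encoder, lr=cfg.learning_rate) if train_encoder else None
        dec_opts = {k: Adam(decoders[k], lr=cfg.learning_rate) for k in decoders}
        history = []
        best = None
        for epoch in range(cfg.epochs):
            epoch_losses = []
            for _ in range(cfg.batches_per_subject):
                for subj in subjects:
                    raw, feats, targets = subj.sample_batch(rng, cfg)
                    dec_key = decoder_of(subj.subject_id)
                    decoder = decoders[dec_key]
                    y = _forward_batch(encoder, decoder, raw, feats, cfg.batch_size)
                    loss = _ccc_loss_t(y, targets, cfg.eps)
                    if enc_opt:
                        enc_opt.zero_grad()
                    dec_opts[dec_key].zero_grad()
                    loss.backward()
                    if enc_opt:
                        enc_opt.step()
                    dec_opts[dec_key].step()
                    epoch_losses.append(float(loss.data))
            entry = {"epoch": epoch, "loss": float(np.mean(epoch_losses))}
            if val_subjects:
                vals = [
                    _eval_ccc(encoder, decoders[decoder_of(s.subject_id)], s)
                    for s in val_subjects
                ]
                entry["val_ccc"] = float(np.nanmean(vals))
                if best is None or entry["val_ccc"] > best[0]:
                    best = (
                        entry["val_ccc"],
                        _clone_params(encoder),
                        {k: _clone_params(v) for k, v in decoders.items()},
                    )
            history.append(entry)
        if best is not None:
            _, enc_best, dec_best = best
            for k in encoder:
                encoder[k].data = enc_best[k].data
            for dk in decoders:
                for k in decoders[dk]:
                    decoders[dk][k].data = dec_best[dk][k].data
        return history

    def _split(self, ds: SubjectDataset, cfg: TrainConfig):
        t_train = ds.duration_s * cfg.train_fraction
        return ds.slice_s(0, t_train), ds.slice_s(t_train, ds.duration_s)

    # -- shared prediction helpers -------------------------------------------
    def _predict_rec(self, neural: Recording, decoder: ParamStore, norm) -> Recording:
        return M.forward(neural, self.encoder_, decoder, norm)

    def score_dataset(self, ds: SubjectDataset, decoder: ParamStore,
                      norm: M.NormalizationParams) -> float:
        """CCC between the decoded and actual trajectory of a dataset."""
        y = self._predict_rec(ds.neural, decoder, norm)
        offset = M.window_target_offset(M.StreamSpec())
        target = ds.trajectory.samples[offset : offset + len(y)]
        n = min(target.size, len(y))
        return concordance_cc(target[:n], y.samples[:n]).rho_c


class WhiskerNetRegressor(_BaseTrainer):
    """Shared-encoder / per-subject-decoder whisker decoder.

    ``fit`` trains the shared encoder plus one private decoder per training
    subject; ``adapt`` trains a fresh decoder for a new subject against the
    frozen encoder; ``predict`` runs the streaming forward pass.

    Fitted attributes: ``encoder_``, ``decoders_`` (subject_id -> params),
    ``norms_`` (subject_id -> NormalizationParams), ``history_``.
    """

    def __init__(
        self,
        epochs: int = 6,
        learning_rate: float = 2e-3,
        sequence_length_steps: int = 125,
        batch_size: int = 4,
        batches_per_subject: int = 10,
        seed: int = 0,
        adaptation_data_s: float = 60.0,
        adaptation_steps: int = 300,
        adaptation_lr: float = 5e-3,
        train_fraction: float = 0.85,
        movement_bias: float = 0.75,
        eps: float = 1e-6,
    ):
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.sequence_length_steps = sequence_length_steps
        self.batch_size = batch_size
        self.batches_per_subject = batches_per_subject
        self.seed = seed
        self.adaptation_data_s = adaptation_data_s
        self.adaptation_steps = adaptation_steps
        self.adaptation_lr = adaptation_lr
        self.train_fraction = train_fraction
        self.movement_bias = movement_bias
        self.eps = eps

    def fit(self, cohort: List[SubjectDataset], y=None) -> "WhiskerNetRegressor":
        cfg = self._cfg()
        if len(cohort) < 2:
            import warnings

            warnings.warn("single-subject cohort: parameter sharing is degenerate")
        rng = np.random.default_rng(cfg.seed)
        self.encoder_ = M.init_encoder_params(rng, dtype=TRAIN_DTYPE)
        self.decoders_ = {}
        self.norms_ = {}
        train_subj, val_subj = [], []
        spec = M.StreamSpec()
        for ds in cohort:
            tr, va = self._split(ds, cfg)
            sd = _SubjectData(tr, cfg, spec, tag="train")
            train_subj.append(sd)
            self.norms_[ds.subject_id] = sd.norm
            self.decoders_[ds.subject_id] = M.init_decoder_params(rng, dtype=TRAIN_DTYPE)
            if va.duration_s * spec.fs_laser > cfg.sequence_length_steps + spec.n_pad / spec.stride:
                val_subj.append(_SubjectData(va, cfg, spec, norm=sd.norm, tag="train"))
        self.history_ = self._train_loop(
            train_subj,
            self.encoder_,
            self.decoders_,
            lambda sid: sid,
            cfg,
            rng,
            train_encoder=True,
            val_subjects=val_subj or None,
        )
        return self

    # -- adaptation -----------------------------------------------------------
    def adapt(
        self,
        new_subject: SubjectDataset,
        seconds: Optional[float] = None,
        seed: Optional[int] = None,
    ) -> ParamStore:
        """Train a freshly initialized decoder for ``new_subject``.

        Uses at most ``seconds`` (default ``adaptation_data_s``) of the
        subject's data, taken from the start of the recording; the encoder is
        frozen throughout. Returns the adapted decoder parameters and stores
        them under ``adapted_`` / ``adapted_norm_``.
        """
        cfg = self._cfg()
        seconds = cfg.adaptation_data_s if seconds is None else float(seconds)
        if seconds > MAX_ADAPTATION_S:
            raise ParameterError(f"adaptation data capped at {MAX_ADAPTATION_S:.0f} s")
        adapt_ds = new_subject.slice_s(0, seconds)
        spec = M.StreamSpec()
        if adapt_ds.duration_s * spec.fs_laser < cfg.sequence_length_steps + spec.n_pad / spec.stride:
            raise DataError("adaptation data shorter than one training sequence")
        rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
        subj = _SubjectData(adapt_ds, cfg, spec, tag="adapt")
        decoder = M.init_decoder_params(rng, dtype=M.params_dtype(self.encoder_))
        self._adapt_decoder(decoder, subj, cfg, rng)
        self.adapted_ = decoder
        self.adapted_norm_ = subj.norm
        return decoder

    def _adapt_decoder(self, decoder: ParamStore, subj: _SubjectData,
                       cfg: TrainConfig, rng: np.random.Generator) -> None:
        """Decoder-only training on cached (frozen-encoder) latents."""
        raw = subj.norm.normalize_raw(np.asarray(subj.windows)).astype(
            M.params_dtype(self.encoder_)
        )
        feats = M.extract_handcrafted(raw, subj.norm).astype(raw.dtype)
        with no_grad():
            lat_chunks = []
            for i in range(0, raw.shape[0], 4096):
                lat_chunks.append(
                    M.encoder_forward(self.encoder_, raw[i : i + 4096], feats[i : i + 4096]).data
                )
        latents = np.concatenate(lat_chunks)
        L = cfg.sequence_length_steps
        opt = Adam(decoder, lr=cfg.adaptation_lr)
        n_start = latents.shape[0] - L + 1
        for _ in range(cfg.adaptation_steps):
            starts = []
            for _ in range(cfg.batch_size):
                pool = subj.move_starts if rng.random() < cfg.movement_bias else subj.all_starts
                starts.append(min(int(pool[rng.integers(pool.size)]), n_start - 1))
            lat = Tensor(np.stack([latents[s : s + L] for s in starts]))
            targets = np.stack([subj.targets[s : s + L] for s in starts])
            y = M.decoder_forward(decoder, lat)
            loss = _ccc_loss_t(y, targets, cfg.eps)
            opt.zero_grad()
            loss.backward()
            opt.step()

    def predict(
        self,
        X,
        decoder: Optional[ParamStore] = None,
        norm: Optional[M.NormalizationParams] = None,
        subject_id: Optional[str] = None,
        mm: bool = False,
    ) -> Recording:
        """Decode a trajectory from a neural Recording or SubjectDataset."""
        neural = X.neural if isinstance(X, SubjectDataset) else X
        if decoder is None:
            if subject_id is not None:
                decoder, norm = self.decoders_[subject_id], self.norms_[subject_id]
            elif hasattr(self, "adapted_"):
                decoder, norm = self.adapted_, self.adapted_norm_
            else:
                raise ParameterError("no decoder selected: adapt() first or pass one")
        if norm is None:
            raise ParameterError("normalization parameters required")
        if norm.source_tag == "test":
            raise DataError("normalization statistics must not come from the test split")
        return M.forward(neural, self.encoder_, decoder, norm, mm=mm)

    def score(self, ds: SubjectDataset, y=None) -> float:
        """CCC of the adapted decoder on a dataset."""
        return self.score_dataset(ds, self.adapted_, self.adapted_norm_)


class SharedDecoderRegressor(_BaseTrainer):
    """Control variant: encoder *and* a single decoder shared across all
    subjects, applied to new subjects without adaptation."""

    def __init__(
        self,
        epochs: int = 6,
        learning_rate: float = 2e-3,
        sequence_length_steps: int = 125,
        batch_size: int = 4,
        batches_per_subject: int = 10,
        seed: int = 0,
        adaptation_data_s: float = 60.0,
        adaptation_steps: int = 300,
        adaptation_lr: float = 5e-3,
        train_fraction: float = 0.85,
        movement_bias: float = 0.75,
        eps: float = 1e-6,
    ):
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.sequence_length_steps = sequence_length_steps
        self.batch_size = batch_size
        self.batches_per_subject = batches_per_subject
        self.seed = seed
        self.adaptation_data_s = adaptation_data_s
        self.adaptation_steps = adaptation_steps
        self.adaptation_lr = adaptation_lr
        self.train_fraction = train_fraction
        self.movement_bias = movement_bias
        self.eps = eps

    def fit(self, cohort: List[SubjectDataset], y=None) -> "SharedDecoderRegressor":
        cfg = self._cfg()
        rng = np.random.default_rng(cfg.seed)
        self.encoder_ = M.init_encoder_params(rng, dtype=TRAIN_DTYPE)
        self.decoder_ = M.init_decoder_params(rng, dtype=TRAIN_DTYPE)
        spec = M.StreamSpec()
        train_subj, val_subj = [], []
        self.norms_ = {}
        for ds in cohort:
            tr, va = self._split(ds, cfg)
            sd = _SubjectData(tr, cfg, spec, tag="train")
            train_subj.append(sd)
            self.norms_[ds.subject_id] = sd.norm
            if va.duration_s * spec.fs_laser > cfg.sequence_length_steps + spec.n_pad / spec.stride:
                val_subj.append(_SubjectData(va, cfg, spec, norm=sd.norm, tag="train"))
        self.history_ = self._train_loop(
            train_subj,
            self.encoder_,
            {"shared": self.decoder_},
            lambda sid: "shared",
            cfg,
            rng,
            train_encoder=True,
            val_subjects=val_subj or None,
        )
        return self

    def predict(self, X, norm: Optional[M.NormalizationParams] = None, mm: bool = False) -> Recording:
        neural = X.neural if isinstance(X, SubjectDataset) else X
        if norm is None:
            raise ParameterError("normalization parameters required")
        return M.forward(neural, self.encoder_, self.decoder_, norm, mm=mm)

    def score(self, ds: SubjectDataset, norm: M.NormalizationParams) -> float:
        return self.score_dataset(ds, self.decoder_, norm)


class IndividualRegressor(WhiskerNetRegressor):
    """Control variant: encoder + decoder trained from scratch on the test
    subject's adaptation data only (no parameters shared with anyone)."""

    def fit(self, new_subject: SubjectDataset, y=None) -> "IndividualRegressor":
        cfg = self._cfg()
        rng = np.random.default_rng(cfg.seed)
        self.encoder_ = M.init_encoder_params(rng, dtype=TRAIN_DTYPE)
        decoder = M.init_decoder_params(rng, dtype=TRAIN_DTYPE)
        spec = M.StreamSpec()
        ds = new_subject if not isinstance(new_subject, list) else new_subject[0]
        subj = _SubjectData(ds, cfg, spec, tag="adapt")
        self.norms_ = {ds.subject_id: subj.norm}
        self.decoders_ = {ds.subject_id: decoder}
        self.history_ = self._train_loop(
            [subj],
            self.encoder_,
            {ds.subject_id: decoder},
            lambda sid: sid,
            cfg,
            rng,
            train_encoder=True,
        )
        self.adapted_ = decoder
        self.adapted_norm_ = subj.norm
        return self


# -- functional convenience wrappers ------------------------------------------

@dataclass
class SharedModel:
    """Encoder shared across subjects plus per-subject decoders."""

    encoder: ParamStore
    decoders: Dict[str, ParamStore]
    norms: Dict[str, M.NormalizationParams] = field(default_factory=dict)
    estimator: Optional[WhiskerNetRegressor] = None


def fit_shared(cohort: List[SubjectDataset], cfg: TrainConfig) -> SharedModel:
    """Train the shared encoder and per-subject decoders (wrapper)."""
    est = WhiskerNetRegressor(**_cfg_to_kwargs(cfg)).fit(cohort)
    return SharedModel(est.encoder_, est.decoders_, est.norms_, est)


def adapt(model: SharedModel, new_subject: SubjectDataset, cfg: TrainConfig) -> ParamStore:
    """Adapt a fresh decoder to a new subject with the encoder frozen."""
    est = model.estimator or _estimator_from(model, cfg)
    return est.adapt(new_subject, seconds=cfg.adaptation_data_s)


def predict_test(
    encoder: ParamStore,
    decoder: ParamStore,
    x_test: Recording,
    norm: M.NormalizationParams,
) -> Recording:
    """Pure forward pass (no parameter mutation)."""
    if norm.source_tag == "test":
        raise DataError("normalization statistics must not come from the test split")
    return M.forward(x_test, encoder, decoder, norm)


def _cfg_to_kwargs(cfg: TrainConfig) -> dict:
    return dict(
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        sequence_length_steps=cfg.sequence_length_steps,
        batch_size=cfg.batch_size,
        batches_per_subject=cfg.batches_per_subject,
        seed=cfg.seed,
        adaptation_data_s=cfg.adaptation_data_s,
        adaptation_steps=cfg.adaptation_steps,
        adaptation_lr=cfg.adaptation_lr,
        train_fraction=cfg.train_fraction,
        movement_bias=cfg.movement_bias,
        eps=cfg.eps,
    )


def _estimator_from(model: SharedModel, cfg: TrainConfig) -> WhiskerNetRegressor:
    est = WhiskerNetRegressor(**_cfg_to_kwargs(cfg))
    est.encoder_ = model.encoder
    est.decoders_ = model.decoders
    est.norms_ = model.norms
    model.estimator = est
    return est
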