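"""Cross-subject evaluation: control models, leave-one-subject-out
cross-validation, adaptation-data learning curves and the 90%-of-maximum
data-efficiency benchmark.

Variants
--------
* ``whiskernet`` — shared encoder, per-subject decoders, adapted to the test
  subject on limited data.
* ``control1`` — encoder *and* decoder shared across training subjects,
  applied to the test subject without adaptation.
* ``control2`` — encoder and decoder trained from scratch on the test
  subject's adaptation data only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import model as M
from .metrics import concordance_cc
from .recording import DataError, ParameterError, Recording, SubjectDataset
from .training import (
    IndividualRegressor,
    SharedDecoderRegressor,
    TrainConfig,
    WhiskerNetRegressor,
    _cfg_to_kwargs,
)

__all__ = [
    "EvaluationReport",
    "LearningCurve",
    "build_control1",
    "build_control2",
    "loso_crossval",
    "learning_curve",
    "data_to_90pct",
    "compare_data_efficiency",
    "evaluate_on",
]


@dataclass
class EvaluationReport:
    """Per-fold, per-seed CCC values plus summary statistics."""

    model_variant: str
    per_fold: Dict[str, List[float]]  # test subject_id -> per-seed CCC
    seeds: List[int]
    summary: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.summary and self.per_fold:
            vals = np.array([v for fold in self.per_fold.values() for v in fold])
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            self.summary = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "median": float(med),
                "iqr_low": float(q1),
                "iqr_high": float(q3),
            }


@dataclass
class LearningCurve:
    """CCC as a function of adaptation-data length, per CV fold."""

    adaptation_lengths_s: np.ndarray  # strictly increasing grid
    ccc_by_length: np.ndarray  # (n_folds, n_lengths)
    data_to_90pct_by_fold: np.ndarray  # (n_folds,), values from the grid

    def __post_init__(self) -> None:
        self.adaptation_lengths_s = np.asarray(self.adaptation_lengths_s, dtype=float)
        if np.any(np.diff(self.adaptation_lengths_s) <= 0):
            raise ParameterError("lengths must be strictly increasing")

    @property
    def data_to_90pct_s(self) -> float:
        """Mean over folds of the smallest length reaching 90% of the fold's
        maximum CCC."""
        return float(np.mean(self.data_to_90pct_by_fold))

    def mean_curve(self) -> np.ndarray:
        return self.ccc_by_length.mean(axis=0)


def data_to_90pct(lengths_s: Sequence[float], ccc: Sequence[float]) -> float:
    """Smallest grid length whose CCC reaches 90% of the curve's maximum."""
    lengths_s = np.asarray(lengths_s, dtype=float)
    ccc = np.asarray(ccc, dtype=float)
    target = 0.9 * np.nanmax(ccc)
    idx = np.flatnonzero(ccc >= target - 1e-12)
    return float(lengths_s[idx[0]])


def _ccc_of(pred: Recording, ds: SubjectDataset) -> float:
    offset = M.window_target_offset(M.StreamSpec())
    target = ds.trajectory.samples[offset : offset + len(pred)]
    n = min(target.size, len(pred))
    return concordance_cc(target[:n], pred.samples[:n]).rho_c


def evaluate_on(est, test_ds: SubjectDataset, norm=None) -> float:
    """CCC of an estimator's prediction on a held-out dataset slice."""
    if isinstance(est, SharedDecoderRegressor):
        pred = est.predict(test_ds, norm=norm)
    else:
        pred = est.predict(test_ds)
    return _ccc_of(pred, test_ds)


def build_control1(cohort: List[SubjectDataset], cfg: TrainConfig) -> SharedDecoderRegressor:
    """Fully shared encoder+decoder model, no adaptation at test time."""
    return SharedDecoderRegressor(**_cfg_to_kwargs(cfg)).fit(cohort)


def build_control2(new_subject: SubjectDataset, cfg: TrainConfig) -> IndividualRegressor:
    """Per-subject model trained from scratch on adaptation data only."""
    adapt_ds = new_subject.slice_s(0, min(cfg.adaptation_data_s, new_subject.duration_s))
    return IndividualRegressor(**_cfg_to_kwargs(cfg)).fit(adapt_ds)


def _run_fold(
    cohort: List[SubjectDataset],
    test_idx: int,
    seed: int,
    cfg: TrainConfig,
    variant: str,
) -> float:
    """Train on all subjects but ``test_idx``; return CCC on the held-out
    subject's test split."""
    test_ds = cohort[test_idx]
    train_cohort = [d for i, d in enumerate(cohort) if i != test_idx]
    kw = _cfg_to_kwargs(cfg)
    kw["seed"] = seed
    adapt_end = min(cfg.adaptation_data_s, test_ds.duration_s / 2)
    adapt_slice = test_ds.slice_s(0, adapt_end)
    test_slice = test_ds.slice_s(adapt_end, test_ds.duration_s)
    if variant == "whiskernet":
        est = WhiskerNetRegressor(**kw).fit(train_cohort)
        est.adapt(adapt_slice)
        return evaluate_on(est, test_slice)
    if variant == "control1":
        est = SharedDecoderRegressor(**kw).fit(train_cohort)
        # input normalization still uses the test subject's own (non-test) data
        norm = M.compute_norm_params(adapt_slice.neural, source_tag="adapt")
        return evaluate_on(est, test_slice, norm=norm)
    if variant == "control2":
        est = IndividualRegressor(**kw).fit(adapt_slice)
        return evaluate_on(est, test_slice)
    raise ParameterError(f"unknown variant {variant!r}")


def loso_crossval(
    cohort: List[SubjectDataset],
    cfg: TrainConfig,
    n_seeds: int = 10,
    variant: str = "whiskernet",
    run_fold=_run_fold,
) -> EvaluationReport:
    """Leave-one-subject-out cross-validation.

    Each subject serves once as the test subject; for every fold the model is
    retrained on the remaining subjects with seeds 1..n_seeds and the CCC on
    the held-out subject's test split is recorded per seed.
    """
    if len(cohort) < 2:
        raise DataError("LOSO requires at least two subjects")
    seeds = list(range(1, n_seeds + 1))
    per_fold: Dict[str, List[float]] = {}
    for i, ds in enumerate(cohort):
        per_fold[ds.subject_id] = [
            run_fold(cohort, i, seed, cfg, variant) for seed in seeds
        ]
    return EvaluationReport(model_variant=variant, per_fold=per_fold, seeds=seeds)


def learning_curve(
    model: Optional[WhiskerNetRegressor],
    new_subject: SubjectDataset,
    lengths_s: Sequence[float],
    cfg: TrainConfig,
    n_folds: int = 5,
    variant: str = "whiskernet",
) -> LearningCurve:
    """CCC versus adaptation-data length under n-fold cross-validation.

    The subject's recording is cut into ``n_folds`` contiguous blocks; each
    fold holds one block out for testing and adapts (``whiskernet``, against
    ``model``'s frozen encoder) or trains from scratch (``control2``) on the
    first ``length`` seconds of the remaining data.
    """
    lengths_s = np.asarray(sorted(lengths_s), dtype=float)
    T = new_subject.duration_s
    edges = np.linspace(0.0, T, n_folds + 1)
    ccc = np.zeros((n_folds, lengths_s.size))
    for f in range(n_folds):
        a, b = edges[f], edges[f + 1]
        test_slice = new_subject.slice_s(a, b)
        # adaptation pool: the recording with the test block removed,
        # concatenated in time order
        before = new_subject.slice_s(0.0, a) if a > 0 else None
        after = new_subject.slice_s(b, T) if b < T else None
        pool = _concat_datasets([d for d in (before, after) if d is not None and d.duration_s > 1.0])
        for j, length in enumerate(lengths_s):
            length = min(length, pool.duration_s)
            adapt_slice = pool.slice_s(0, length)
            kw = _cfg_to_kwargs(cfg)
            kw["seed"] = cfg.seed + f
            if variant == "whiskernet":
                est = WhiskerNetRegressor(**kw)
                est.encoder_ = model.encoder_
                est.adapt(adapt_slice, seconds=min(length, cfg.adaptation_data_s))
                ccc[f, j] = evaluate_on(est, test_slice)
            elif variant == "control2":
                est = IndividualRegressor(**kw).fit(adapt_slice)
                ccc[f, j] = evaluate_on(est, test_slice)
            else:
                raise ParameterError(f"unknown variant {variant!r}")
    d90 = np.array([data_to_90pct(lengths_s, ccc[f]) for f in range(n_folds)])
    return LearningCurve(lengths_s, ccc, d90)


def _concat_datasets(parts: List[SubjectDataset]) -> SubjectDataset:
    if not parts:
        raise DataError("no adaptation data left outside the test block")
    if len(parts) == 1:
        return parts[0]
    neural = np.concatenate([p.neural.samples for p in parts])
    traj = np.concatenate([p.trajectory.samples for p in parts])
    first = parts[0]
    return SubjectDataset(
        subject_id=first.subject_id,
        neural=Recording(neural, first.neural.fs_hz, first.neural.unit, "neural"),
        trajectory=Recording(traj, first.trajectory.fs_hz, first.trajectory.unit, "trajectory"),
        ground_truth_latency_ms=first.ground_truth_latency_ms,
    )


def compare_data_efficiency(curve_a: LearningCurve, curve_b: LearningCurve) -> float:
    """Signed difference (seconds) ``a - b`` of the mean data-to-90% benchmark;
    negative means ``a`` needs less adaptation data."""
    return curve_a.data_to_90pct_s - curve_b.data_to_90pct_s
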