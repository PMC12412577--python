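"""CCC loss, normalization hygiene, and the share/adapt/freeze contracts.

The training runs here are deliberately miniature (tens of optimization
steps) — they check contracts and directions, not final decoding quality;
the full-scale checks live in test_acceptance.py.
"""

import numpy as np
import pytest

import whiskdecode.model as M
from whiskdecode import training as T
from whiskdecode.metrics import concordance_cc
from whiskdecode.recording import DataError, ParameterError
from whiskdecode.evaluation import evaluate_on


TINY = dict(
    epochs=1,
    batches_per_subject=3,
    adaptation_steps=30,
    adaptation_data_s=25.0,
    seed=0,
)


@pytest.fixture(scope="module")
def tiny_fitted(tiny_cohort):
    return T.WhiskerNetRegressor(**TINY).fit(tiny_cohort)


class TestCCCLoss:
    def test_perfect_prediction(self):
        y = np.array([0.1, 0.4, 0.8, 0.3])
        assert T.ccc_loss(y, y) == pytest.approx(0.0, abs=1e-12)

    def test_shifted_worked_case(self):
        y = np.arange(5.0)
        assert T.ccc_loss(y, y + 1.0) == pytest.approx(0.2, abs=1e-12)

    def test_bounds(self, rng):
        for _ in range(5):
            y = rng.standard_normal(30)
            z = rng.standard_normal(30)
            assert 0.0 <= T.ccc_loss(y, z) <= 2.0

    def test_consistency_with_metric(self, rng):
        y = rng.standard_normal(100)
        z = 0.5 * y + rng.standard_normal(100)
        assert 1.0 - T.ccc_loss(y, z) == pytest.approx(
            concordance_cc(y, z).rho_c, abs=1e-9
        )

    def test_differentiable_form_matches(self, rng):
        from whiskdecode.nn.autodiff import Tensor

        y = rng.uniform(0, 1, (3, 50))
        z = rng.uniform(0, 1, (3, 50))
        loss = float(T._ccc_loss_t(Tensor(z), y, eps=0.0).data)
        brute = np.mean([T.ccc_loss(y[i], z[i]) for i in range(3)])
        assert loss == pytest.approx(brute, abs=1e-9)


class TestTrainConfig:
    def test_adaptation_cap(self):
        with pytest.raises(ParameterError):
            T.TrainConfig(adaptation_data_s=600.0)


class TestFitShared:
    def test_decoder_per_subject(self, tiny_fitted, tiny_cohort):
        assert set(tiny_fitted.decoders_) == {d.subject_id for d in tiny_cohort}
        assert set(tiny_fitted.norms_) == {d.subject_id for d in tiny_cohort}

    def test_training_improves_over_untrained(self, tiny_fitted, tiny_cohort):
        ds = tiny_cohort[0]
        trained = evaluate_on_subject(tiny_fitted, ds)
        fresh = T.WhiskerNetRegressor(**TINY)
        rng = np.random.default_rng(99)
        fresh.encoder_ = M.init_encoder_params(rng)
        fresh.decoders_ = {ds.subject_id: M.init_decoder_params(rng)}
        fresh.norms_ = tiny_fitted.norms_
        untrained = evaluate_on_subject(fresh, ds)
        assert trained > untrained

    def test_seeded_determinism(self, tiny_cohort):
        a = T.WhiskerNetRegressor(**TINY).fit(tiny_cohort)
        b = T.WhiskerNetRegressor(**TINY).fit(tiny_cohort)
        assert [h["loss"] for h in a.history_] == [h["loss"] for h in b.history_]
        assert M.params_hash(a.encoder_) == M.params_hash(b.encoder_)

    def test_single_subject_warns_but_runs(self, tiny_cohort):
        with pytest.warns(UserWarning):
            est = T.WhiskerNetRegressor(**TINY).fit(tiny_cohort[:1])
        assert len(est.decoders_) == 1


def evaluate_on_subject(est, ds):
    pred = est.predict(ds, subject_id=ds.subject_id)
    offset = M.window_target_offset(M.StreamSpec())
    target = ds.trajectory.samples[offset : offset + len(pred)]
    n = min(target.size, len(pred))
    return concordance_cc(target[:n], pred.samples[:n]).rho_c


class TestAdapt:
    def test_encoder_frozen(self, tiny_fitted, tiny_cohort):
        before = M.params_hash(tiny_fitted.encoder_)
        tiny_fitted.adapt(tiny_cohort[1], seconds=25.0)
        assert M.params_hash(tiny_fitted.encoder_) == before

    def test_adaptation_improves_over_random_decoder(self, tiny_fitted, tiny_cohort):
        ds = tiny_cohort[1]
        test_slice = ds.slice_s(25.0, 40.0)
        tiny_fitted.adapt(ds.slice_s(0.0, 25.0), seconds=25.0)
        adapted = evaluate_on(tiny_fitted, test_slice)
        rand_dec = M.init_decoder_params(np.random.default_rng(123))
        pred = tiny_fitted.predict(test_slice, decoder=rand_dec, norm=tiny_fitted.adapted_norm_)
        offset = M.window_target_offset(M.StreamSpec())
        target = test_slice.trajectory.samples[offset : offset + len(pred)]
        n = min(target.size, len(pred))
        unadapted = concordance_cc(target[:n], pred.samples[:n]).rho_c
        assert adapted > unadapted

    def test_reinitialized_decoder_depends_on_seed_not_training(self, tiny_fitted, tiny_cohort):
        ds = tiny_cohort[1].slice_s(0.0, 25.0)
        d1 = tiny_fitted.adapt(ds, seconds=25.0, seed=1)
        d2 = tiny_fitted.adapt(ds, seconds=25.0, seed=2)
        assert M.params_hash(d1) != M.params_hash(d2)
        for dec in tiny_fitted.decoders_.values():
            assert M.params_hash(d1) != M.params_hash(dec)

    def test_too_little_data_errors(self, tiny_fitted, tiny_cohort):
        with pytest.raises((DataError, ParameterError)):
            tiny_fitted.adapt(tiny_cohort[1].slice_s(0.0, 1.0), seconds=1.0)

    def test_adaptation_cap_enforced(self, tiny_fitted, tiny_cohort):
        with pytest.raises(ParameterError):
            tiny_fitted.adapt(tiny_cohort[1], seconds=600.0)


class TestPredictTest:
    def test_pure_forward_no_mutation(self, tiny_fitted, tiny_cohort):
        ds = tiny_cohort[0]
        dec = tiny_fitted.decoders_[ds.subject_id]
        h_enc = M.params_hash(tiny_fitted.encoder_)
        h_dec = M.params_hash(dec)
        out = T.predict_test(
            tiny_fitted.encoder_, dec, ds.neural, tiny_fitted.norms_[ds.subject_id]
        )
        assert M.params_hash(tiny_fitted.encoder_) == h_enc
        assert M.params_hash(dec) == h_dec
        assert len(out) == M.StreamSpec().n_windows(len(ds.neural))

    def test_test_split_normalization_rejected(self, tiny_fitted, tiny_cohort):
        ds = tiny_cohort[0]
        bad = M.compute_norm_params(ds.neural, source_tag="test")
        with pytest.raises(DataError):
            T.predict_test(
                tiny_fitted.encoder_, tiny_fitted.decoders_[ds.subject_id], ds.neural, bad
            )


class TestNormWrapper:
    def test_compute_norm_params(self, tiny_cohort):
        p = T.compute_norm_params(tiny_cohort[0].neural)
        z = p.normalize_raw(tiny_cohort[0].neural.samples)
        assert abs(z.mean()) < 1e-9 and abs(z.std() - 1) < 1e-9
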