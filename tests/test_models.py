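"""Model zoo: training contracts, determinism, family-specific wiring."""

import numpy as np
import pytest

from hfreadmit.encoding import EncodedSequence
from hfreadmit.models import (ModelConfig, ReadmissionModel,
                              TrainingDivergedError, load_results,
                              save_results, ss_probability)
from hfreadmit.objectives import LossSpec


def separable_sequences(n, rng, d=6, noise=0.0):
    """Sequences whose first feature equals each event's label: any
    family can reach AUC ~1 on the last event."""
    seqs = []
    for i in range(n):
        T = int(rng.integers(1, 4))
        y = rng.integers(0, 2, T)
        X = rng.normal(scale=0.3, size=(T, d))
        X[:, 0] = y + noise * rng.normal(size=T)
        seqs.append(EncodedSequence(
            patient_id=f"P{i}", X=X, labels=y,
            is_hf=np.ones(T, dtype=bool), last_hf_index=T - 1))
    return seqs


FAMILY_CASES = [
    ("MLP", {}),
    ("RNN", {}),
    ("RNNSS", {}),
    ("CRF_only", {"potential_variant": "unary"}),
    ("CRF_only", {"potential_variant": "pairwise"}),
    ("NeuralCRF", {"potential_variant": "unary"}),
    ("RNNCRF", {"potential_variant": "pairwise"}),
    ("CNN", {}),
    ("CNN_Wide", {"cnn_kernel_heights": (2, 3)}),
    ("LR", {}),
]


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(77)
    return separable_sequences(260, rng), separable_sequences(80, rng)


class TestSchedules:
    def test_linear_starts_at_one(self):
        assert ss_probability("linear", 0, rate=0.01) == 1.0

    def test_exponential_closed_form(self):
        assert ss_probability("exponential", 2, gamma=0.9) == \
            pytest.approx(0.81)

    def test_inverse_sigmoid_offset_start(self):
        c = 5.0
        assert ss_probability("inverse_sigmoid", 0, c=c) == \
            pytest.approx(c / (c + 1))

    @pytest.mark.parametrize("schedule", ["linear", "exponential",
                                          "inverse_sigmoid"])
    def test_all_schedules_non_increasing(self, schedule):
        eps = [ss_probability(schedule, k) for k in range(40)]
        assert all(a >= b for a, b in zip(eps, eps[1:]))
        assert all(0.0 <= e <= 1.0 for e in eps)

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            ss_probability("exponential", 1, gamma=1.5)
        with pytest.raises(ValueError):
            ss_probability("inverse_sigmoid", 1, c=0.5)
        with pytest.raises(ValueError):
            ss_probability("linear", -1)


class TestConfigValidation:
    def test_unknown_family(self):
        with pytest.raises(ValueError):
            ModelConfig(family="Transformer")

    def test_nonpositive_step_size(self):
        with pytest.raises(ValueError):
            ModelConfig(lr=0.0)

    @pytest.mark.parametrize("family", ["CNN", "CNN_Wide", "MLP"])
    def test_event_view_families_last_hf_only(self, family):
        with pytest.raises(ValueError):
            ModelConfig(family=family, loss=LossSpec("Uniform_HF"))

    def test_bad_potential_variant(self):
        with pytest.raises(ValueError):
            ModelConfig(family="RNNCRF", potential_variant="ternary")


class TestFitContract:
    @pytest.mark.parametrize("family,extra", FAMILY_CASES)
    def test_separable_data_reaches_high_auc(self, separable, family,
                                             extra):
        train, valid = separable
        cfg = ModelConfig(family=family, epochs=30, optimizer="adam",
                          lr=0.03, hidden_size=16, fc_size=16,
                          batch_size=64, seed=1, lr_C=10.0, **extra)
        res = ReadmissionModel(cfg).fit(train, valid)
        from sklearn.metrics import roc_auc_score
        y = [s.last_label for s in valid]
        assert roc_auc_score(y, res.predict_proba(valid)) >= 0.99

    def test_same_seed_identical_parameters(self, separable):
        train, valid = separable
        cfg = ModelConfig(family="RNN", epochs=3, seed=9,
                          optimizer="adam", lr=0.02)
        a = ReadmissionModel(cfg).fit(train[:100], valid[:30])
        b = ReadmissionModel(cfg).fit(train[:100], valid[:30])
        for k in a.params:
            np.testing.assert_array_equal(a.params[k].data,
                                          b.params[k].data)
        np.testing.assert_array_equal(a.predict_proba(valid),
                                      b.predict_proba(valid))

    def test_zero_epochs_flagged_untrained(self, separable):
        train, valid = separable
        cfg = ModelConfig(family="MLP", epochs=0)
        res = ReadmissionModel(cfg).fit(train, valid)
        assert res.untrained
        assert "initialization" in res.summary()

    def test_predictions_in_unit_interval(self, separable):
        train, valid = separable
        for family, extra in [("RNN", {}), ("NeuralCRF", {}),
                              ("CNN_Wide", {"cnn_kernel_heights": (2,)})]:
            cfg = ModelConfig(family=family, epochs=2, optimizer="adam",
                              lr=0.02, **extra)
            res = ReadmissionModel(cfg).fit(train[:80], valid[:30])
            p = res.predict_proba(valid)
            assert np.isfinite(p).all() and p.min() >= 0 and p.max() <= 1

    def test_single_class_training_set_rejected(self, separable):
        train, _ = separable
        pos = [s for s in train if s.last_label == 1]
        with pytest.raises(ValueError):
            ReadmissionModel(ModelConfig(family="MLP")).fit(pos)

    def test_divergence_raises_named_error(self, separable):
        train, valid = separable
        cfg = ModelConfig(family="CNN_Wide", epochs=12, optimizer="sgd",
                          lr=1e60, clip_norm=0.0, batch_size=260,
                          cnn_kernel_heights=(2,))
        with np.errstate(all="ignore"):
            with pytest.raises(TrainingDivergedError, match="epoch"):
                ReadmissionModel(cfg).fit(train, valid)


class TestScheduledSampling:
    def test_rnnss_with_full_teacher_forcing_matches_rnn_at_init(
            self, separable):
        """With eps = 1 and zero-initialized feedback weights the
        first full-batch training loss coincides with plain RNN."""
        train, valid = separable
        common = dict(epochs=1, batch_size=len(train), lr=1e-9,
                      optimizer="sgd", seed=4)
        rnn = ReadmissionModel(ModelConfig(family="RNN", **common))\
            .fit(train, valid)
        ss = ReadmissionModel(ModelConfig(
            family="RNNSS", ss_schedule="linear", ss_rate=0.0,
            **common)).fit(train, valid)
        assert rnn.history.train_loss[0] == pytest.approx(
            ss.history.train_loss[0], rel=1e-12)

    def test_feedback_weights_start_zero(self, separable):
        train, valid = separable
        cfg = ModelConfig(family="RNNSS", epochs=0)
        res = ReadmissionModel(cfg).fit(train, valid)
        # the two label-feedback input rows of the cell weight matrix
        assert not res.params["Wx_cell"].data[-2:].any()


class TestCnnWide:
    def test_pooling_reduces_each_map_to_scalar(self, separable):
        """Max-over-time pooling: penultimate width equals the number
        of kernels (filters x kernel heights)."""
        train, valid = separable
        cfg = ModelConfig(family="CNN_Wide", epochs=1, optimizer="adam",
                          lr=0.01, cnn_kernel_heights=(2, 3),
                          cnn_filters=4)
        res = ReadmissionModel(cfg).fit(train[:60], valid[:20])
        assert res.params["Wfc"].data.shape[0] == 4 * 2


class TestLogisticRegression:
    def test_strong_l1_gives_intercept_only(self, separable):
        train, valid = separable
        cfg = ModelConfig(family="LR", lr_penalty="l1", lr_C=1e-4)
        res = ReadmissionModel(cfg).fit(train, valid)
        assert np.abs(res.coef_).max() == 0.0

    def test_l1_zeroes_irrelevant_constant_noise_feature(self):
        rng = np.random.default_rng(3)
        n, d = 4000, 5
        X = rng.normal(size=(n, d))
        X[:, 4] = 0.01 * rng.normal(size=n)     # irrelevant
        w = np.array([1.5, -1.0, 0.5, 0.8, 0.0])
        p = 1 / (1 + np.exp(-(X @ w)))
        y = (rng.random(n) < p).astype(int)
        seqs = [EncodedSequence(f"P{i}", X[i:i + 1], y[i:i + 1],
                                np.array([True]), 0) for i in range(n)]
        cfg = ModelConfig(family="LR", lr_penalty="l1", lr_C=0.05)
        res = ReadmissionModel(cfg).fit(seqs)
        assert res.coef_[4] == 0.0
        assert np.abs(res.coef_[:4]).min() > 0

    def test_coefficient_recovery_on_clean_logit_data(self):
        rng = np.random.default_rng(8)
        n = 20_000
        X = rng.normal(size=(n, 3))
        w = np.array([1.0, -0.7, 0.4])
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ w)))).astype(int)
        seqs = [EncodedSequence(f"P{i}", X[i:i + 1], y[i:i + 1],
                                np.array([True]), 0) for i in range(n)]
        cfg = ModelConfig(family="LR", lr_penalty="l2", lr_C=1e4)
        res = ReadmissionModel(cfg).fit(seqs)
        np.testing.assert_allclose(res.coef_, w, rtol=0.05)


class TestPersistence:
    @pytest.mark.parametrize("family,extra", [("RNN", {}), ("LR", {}),
                                              ("RNNCRF", {})])
    def test_save_load_roundtrip_predictions(self, tmp_path, separable,
                                             family, extra):
        train, valid = separable
        cfg = ModelConfig(family=family, epochs=2, optimizer="adam",
                          lr=0.02, **extra)
        res = ReadmissionModel(cfg).fit(train[:80], valid[:30])
        path = tmp_path / "model.bin"
        save_results(res, path)
        back = load_results(path)
        np.testing.assert_allclose(back.predict_proba(valid),
                                   res.predict_proba(valid))
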