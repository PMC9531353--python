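import numpy as np
import pytest
from sklearn.base import clone

from promoterlstm.model import (
    BiLSTMPromoterClassifier,
    ModelConfig,
    TrainConfig,
    bce_loss,
    predict,
    train,
    train_val_test_split,
)
from promoterlstm.sequence_io import DnaSequence, LabelledDataset
from .conftest import random_dna

TINY = dict(
    vocab_size=65,
    embed_dim=8,
    hidden_dim=6,
    seq_len=10,
    fc1_dim=8,
    max_epochs=5,
    batch_size=8,
    random_state=0,
)


def separable_toy(n_per_class=16, seq_len=10, seed=0):
    """Positives are all-AAA windows (index 1), negatives all-TTT (64)."""
    gen = np.random.default_rng(seed)
    X_pos = np.ones((n_per_class, seq_len), dtype=np.int64)
    X_neg = np.full((n_per_class, seq_len), 64, dtype=np.int64)
    X = np.vstack([X_pos, X_neg])
    y = np.r_[np.ones(n_per_class, int), np.zeros(n_per_class, int)]
    order = gen.permutation(len(y))
    return X[order], y[order]


class TestModelConfig:
    def test_default_flattened_dimension(self):
        assert ModelConfig().flattened_dim == 76288

    def test_rejects_non_positive_dimension(self):
        with pytest.raises(ValueError):
            ModelConfig(hidden_dim=0)

    def test_single_recurrent_layer_only(self):
        with pytest.raises(ValueError, match="single"):
            ModelConfig(n_lstm_layers=2)


class TestBceLoss:
    def test_perfect_prediction_is_near_zero(self):
        assert bce_loss([1, 0], [1.0, 0.0]) == pytest.approx(0.0, abs=1e-6)

    def test_coin_flip_closed_form(self):
        assert bce_loss([1], [0.5]) == pytest.approx(np.log(2), rel=1e-9)

    def test_hand_computed_example(self):
        # mean of -ln(0.9) twice
        assert bce_loss([1, 0], [0.9, 0.1]) == pytest.approx(0.105360516, rel=1e-6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            bce_loss([1, 0], [0.5])

    def test_strictly_decreasing_in_p_for_positive_label(self):
        losses = [bce_loss([1], [p]) for p in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a > b for a, b in zip(losses, losses[1:]))


class TestEstimatorContract:
    def test_get_set_params_and_clone(self):
        est = BiLSTMPromoterClassifier(**TINY)
        params = est.get_params()
        assert params["hidden_dim"] == 6
        est2 = clone(est).set_params(hidden_dim=4)
        assert est2.hidden_dim == 4 and est.hidden_dim == 6

    def test_fit_learns_separable_toy_and_tracks_best_epoch(self):
        X, y = separable_toy()
        est = BiLSTMPromoterClassifier(**TINY).fit(X, y)
        hist = est.history_
        assert len(hist["train_loss"]) == len(hist["val_loss"]) == 5
        assert est.best_epoch_ == int(np.argmin(hist["val_loss"])) + 1
        # strict improvement over the first epoch on a separable toy
        assert hist["val_loss"][est.best_epoch_ - 1] < hist["val_loss"][0]
        assert (est.predict(X) == y).all()
        proba = est.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_single_epoch_best_epoch_is_one(self):
        X, y = separable_toy()
        est = BiLSTMPromoterClassifier(**{**TINY, "max_epochs": 1}).fit(X, y)
        assert est.best_epoch_ == 1

    def test_fit_is_deterministic_given_seeds(self):
        X, y = separable_toy()
        h1 = BiLSTMPromoterClassifier(**TINY).fit(X, y).history_
        h2 = BiLSTMPromoterClassifier(**TINY).fit(X, y).history_
        assert h1 == h2

    def test_explicit_validation_data_drives_selection(self):
        X, y = separable_toy(16)
        Xv, yv = separable_toy(8, seed=1)
        est = BiLSTMPromoterClassifier(**TINY).fit(X, y, validation_data=(Xv, yv))
        assert len(est.history_["val_loss"]) == 5

    @pytest.mark.parametrize("bad_y", [[2, 0], [1, -1]])
    def test_non_binary_labels_rejected(self, bad_y):
        X = np.ones((2, 10), dtype=int)
        with pytest.raises(ValueError, match="binary"):
            BiLSTMPromoterClassifier(**TINY).fit(X, bad_y)

    def test_empty_fit_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            BiLSTMPromoterClassifier(**TINY).fit(
                np.empty((0, 10), dtype=int), np.empty(0, dtype=int)
            )


@pytest.fixture(scope="module")
def fitted():
    X, y = separable_toy()
    return BiLSTMPromoterClassifier(**TINY).fit(X, y)


class TestPredict:

    def test_threshold_tie_classifies_positive(self, fitted):
        probs = np.array([0.7, 0.5, 0.3])
        # exercise the documented >= rule through the module function
        class Stub:
            def decision_function(self, batch):
                return probs

        p, labels = predict(Stub(), None, threshold=0.5)
        assert labels.tolist() == [1, 1, 0]

    def test_threshold_above_one_yields_all_negative(self, fitted):
        X, _ = separable_toy()
        _, labels = predict(fitted, X, threshold=1.01)
        assert (labels == 0).all()

    def test_checkpoint_round_trip(self, fitted, tmp_path):
        X, _ = separable_toy()
        path = tmp_path / "model.ckpt"
        fitted.save(path)
        loaded = BiLSTMPromoterClassifier.load(path)
        np.testing.assert_allclose(
            loaded.decision_function(X), fitted.decision_function(X), rtol=1e-6
        )
        assert loaded.best_epoch_ == fitted.best_epoch_
        assert loaded.history_ == fitted.history_


class TestTrainWrapper:
    def make_dataset(self, n, tag, seed, length=12):
        gen = np.random.default_rng(seed)
        records = []
        for i in range(n):
            records.append((random_dna(gen, length, f"{tag}_pos{i}"), 1))
            records.append((random_dna(gen, length, f"{tag}_neg{i}"), 0))
        return LabelledDataset(records=records, split_tag=tag)

    def test_trains_from_labelled_datasets(self):
        cfg = ModelConfig(embed_dim=8, hidden_dim=6, seq_len=10, fc1_dim=8)
        train_set = self.make_dataset(8, "train", 0)
        val_set = self.make_dataset(4, "validation", 1)
        est = train(cfg, train_set, val_set, TrainConfig(max_epochs=2, batch_size=8))
        assert est.best_epoch_ in (1, 2)

    def test_overlapping_ids_rejected(self):
        cfg = ModelConfig(embed_dim=8, hidden_dim=6, seq_len=10, fc1_dim=8)
        ds = self.make_dataset(4, "train", 0)
        val = LabelledDataset(records=list(ds.records), split_tag="validation")
        with pytest.raises(ValueError, match="overlap"):
            train(cfg, ds, val, TrainConfig(max_epochs=1))


class TestSplit:
    def balanced_dataset(self, n_per_class, seed=0):
        gen = np.random.default_rng(seed)
        records = []
        for i in range(n_per_class):
            records.append((random_dna(gen, 10, f"pos{i}"), 1))
            records.append((random_dna(gen, 10, f"neg{i}"), 0))
        return LabelledDataset(records=records)

    def test_801010_split_keeps_balance(self):
        ds = self.balanced_dataset(500)
        tr, va, te = train_val_test_split(ds, (0.8, 0.1, 0.1), seed=1)
        assert (len(tr), len(va), len(te)) == (800, 100, 100)
        assert tr.is_balanced() and va.is_balanced() and te.is_balanced()
        ids = [s.id for d in (tr, va, te) for s in d.sequences]
        assert len(ids) == len(set(ids)) == 1000

    def test_fractions_must_sum_to_one(self):
        ds = self.balanced_dataset(10)
        with pytest.raises(ValueError, match="sum to 1"):
            train_val_test_split(ds, (0.8, 0.05, 0.05), seed=0)

    def test_deterministic_membership(self):
        ds = self.balanced_dataset(50)
        a = train_val_test_split(ds, seed=42)
        b = train_val_test_split(ds, seed=42)
        for x, y in zip(a, b):
            assert [s.id for s in x.sequences] == [s.id for s in y.sequences]

    def test_empty_class_in_a_split_is_an_error(self):
        ds = self.balanced_dataset(3)
        with pytest.raises(ValueError, match="no members"):
            train_val_test_split(ds, (0.9, 0.05, 0.05), seed=0)
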