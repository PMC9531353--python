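"""The promoter classifier as a scikit-learn estimator, plus training helpers.

:class:`BiLSTMPromoterClassifier` follows the scikit-learn estimator
contract (``fit`` / ``predict`` / ``predict_proba``, ``get_params`` /
``set_params``, fitted attributes with a trailing underscore) so it
composes with pipelines and model selection.  ``fit`` runs mini-batch
Adam for ``max_epochs`` epochs, records training and validation loss per
epoch, and restores the parameter state from the epoch with minimum
validation loss (ties break to the earliest epoch).

The module-level :func:`train` / :func:`predict` functions are thin
wrappers over the estimator for users working with
:class:`~promoterlstm.sequence_io.LabelledDataset` objects.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._nn import Adam, SeqvecNet, bce_from_logits, sigmoid
from .encoding import DEFAULT_TABLE, encode_batch
from .sequence_io import DnaSequence, LabelledDataset


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults reproduce the published geometry: a vocabulary of 65
    (64 triplets + unknown/pad), embedding size 64, one bidirectional
    LSTM layer with hidden dimension 128 per direction over 298
    positions, a 76288-wide flatten, and a 128-unit fully connected
    layer before the sigmoid output.
    """

    vocab_size: int = 65
    embed_dim: int = 64
    hidden_dim: int = 128
    seq_len: int = 298
    fc1_dim: int = 128
    leaky_slope: float = 0.01
    n_lstm_layers: int = 1

    def __post_init__(self) -> None:
        if min(
            self.vocab_size,
            self.embed_dim,
            self.hidden_dim,
            self.seq_len,
            self.fc1_dim,
        ) < 1:
            raise ValueError("all dimensions must be positive")
        if self.n_lstm_layers != 1:
            raise ValueError(
                "only a single bidirectional LSTM layer is supported "
                "(the depth consistent with the 298 x 256 recurrent output)"
            )

    @property
    def flattened_dim(self) -> int:
        return self.seq_len * 2 * self.hidden_dim


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule: Adam, mini-batches of 64, up to 50 epochs."""

    max_epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    shuffle_each_epoch: bool = True

    def __post_init__(self) -> None:
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


#: probability clipping bound used by :func:`bce_loss`
BCE_EPS = 1e-7


def bce_loss(labels: Sequence[float], probs: Sequence[float]) -> float:
    """Mean binary cross-entropy, ``-mean(y log p + (1-y) log(1-p))``.

    Probabilities are clipped to ``[BCE_EPS, 1 - BCE_EPS]`` before the
    logarithm.
    """
    y = np.asarray(labels, dtype=np.float64)
    p = np.asarray(probs, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: labels {y.shape} vs probs {p.shape}")
    p = np.clip(p, BCE_EPS, 1.0 - BCE_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


class BiLSTMPromoterClassifier(ClassifierMixin, BaseEstimator):
    """Bidirectional-LSTM promoter classifier over triplet index vectors.

    Parameters
    ----------
    vocab_size, embed_dim, hidden_dim, seq_len, fc1_dim, leaky_slope
        Architecture; see :class:`ModelConfig` for the defaults.
    max_epochs, batch_size, learning_rate, shuffle_each_epoch
        Training schedule; see :class:`TrainConfig`.
    validation_fraction
        Fraction of the training data held out for epoch selection when
        ``fit`` is not given an explicit validation set.
    threshold
        Decision threshold; a probability >= threshold is class 1.
    clip_grad_norm
        Global gradient-norm clip; ``None`` disables clipping.
    random_state
        Seeds parameter initialization, shuffling and the internal
        validation split.

    Attributes
    ----------
    net_ : SeqvecNet
        Fitted network, restored to the best epoch.
    history_ : dict with keys "train_loss" and "val_loss"
        Per-epoch mean training loss and full-validation loss.
    best_epoch_ : int
        1-based epoch of minimum validation loss.
    classes_ : ndarray
        ``[0, 1]``.
    """

    def __init__(
        self,
        vocab_size: int = 65,
        embed_dim: int = 64,
        hidden_dim: int = 128,
        seq_len: int = 298,
        fc1_dim: int = 128,
        leaky_slope: float = 0.01,
        max_epochs: int = 50,
        batch_size: int = 64,
        learning_rate: float = 1e-3,
        shuffle_each_epoch: bool = True,
        validation_fraction: float = 0.1,
        threshold: float = 0.5,
        clip_grad_norm: Optional[float] = 5.0,
        random_state: int = 0,
    ) -> None:
        self.vocab_size = vocab_size
        self.embed_dim = embed_dim
        self.hidden_dim = hidden_dim
        self.seq_len = seq_len
        self.fc1_dim = fc1_dim
        self.leaky_slope = leaky_slope
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.shuffle_each_epoch = shuffle_each_epoch
        self.validation_fraction = validation_fraction
        self.threshold = threshold
        self.clip_grad_norm = clip_grad_norm
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            vocab_size=self.vocab_size,
            embed_dim=self.embed_dim,
            hidden_dim=self.hidden_dim,
            seq_len=self.seq_len,
            fc1_dim=self.fc1_dim,
            leaky_slope=self.leaky_slope,
        )

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-dimensional, got shape {X.shape}")
        if X.shape[1] != self.seq_len:
            raise ValueError(
                f"X has row width {X.shape[1]}, expected seq_len={self.seq_len}"
            )
        if not np.issubdtype(X.dtype, np.integer):
            if not np.all(np.mod(X, 1) == 0):
                raise ValueError("X must contain integer triplet indices")
            X = X.astype(np.int64)
        if X.size and (X.min() < 0 or X.max() >= self.vocab_size):
            raise ValueError(f"indices must lie in [0, {self.vocab_size - 1}]")
        return X

    @staticmethod
    def _validate_y(y) -> np.ndarray:
        y = np.asarray(y)
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        return y.astype(np.float64)

    # ------------------------------------------------------------------
    def fit(
        self,
        X,
        y,
        validation_data: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    ) -> "BiLSTMPromoterClassifier":
        """Train on an (n, seq_len) index matrix with binary labels.

        ``validation_data`` — an ``(X_val, y_val)`` pair — drives epoch
        selection; without it a stratified ``validation_fraction`` of
        the training data is held out.
        """
        self._model_config()  # validates the architecture early
        X = self._validate_X(X)
        y = self._validate_y(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of samples")
        if X.shape[0] == 0:
            raise ValueError("cannot fit on an empty dataset")

        rng = np.random.default_rng(self.random_state)
        if validation_data is not None:
            X_val = self._validate_X(validation_data[0])
            y_val = self._validate_y(validation_data[1])
        else:
            idx = _stratified_holdout(y, self.validation_fraction, rng)
            X_val, y_val = X[idx], y[idx]
            keep = np.setdiff1d(np.arange(X.shape[0]), idx, assume_unique=True)
            X, y = X[keep], y[keep]
        if X_val.shape[0] == 0:
            raise ValueError("validation set is empty")

        net = SeqvecNet(
            vocab_size=self.vocab_size,
            embed_dim=self.embed_dim,
            hidden_dim=self.hidden_dim,
            seq_len=self.seq_len,
            fc1_dim=self.fc1_dim,
            leaky_slope=self.leaky_slope,
            seed=self.random_state,
        )
        opt = Adam(net, lr=self.learning_rate, clip_norm=self.clip_grad_norm)

        n = X.shape[0]
        history: Dict[str, List[float]] = {"train_loss": [], "val_loss": []}
        best_loss = np.inf
        best_state = net.state_dict()
        best_epoch = 1
        order = np.arange(n)
        for epoch in range(1, self.max_epochs + 1):
            if self.shuffle_each_epoch:
                order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                logits = net.forward(X[batch], training=True)
                loss, dz = bce_from_logits(logits, y[batch])
                grads = net.backward(dz)
                opt.step(grads)
                epoch_loss += loss * batch.size
            history["train_loss"].append(epoch_loss / n)
            val_probs = net.predict_proba(X_val, batch_size=self.batch_size)
            val_loss = bce_loss(y_val, val_probs)
            history["val_loss"].append(val_loss)
            if val_loss < best_loss:
                best_loss = val_loss
                best_state = net.state_dict()
                best_epoch = epoch

        net.load_state_dict(best_state)
        self.net_ = net
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = self.seq_len
        return self

    # ------------------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        """Class-membership probabilities, shape (n, 2)."""
        check_is_fitted(self, "net_")
        X = self._validate_X(X)
        p1 = self.net_.predict_proba(X, batch_size=max(self.batch_size, 1))
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X) -> np.ndarray:
        """Probability of the promoter class, shape (n,)."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        """Binary labels; 1 iff probability >= threshold (ties positive)."""
        return (self.decision_function(X) >= self.threshold).astype(np.int64)

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Serialize config, parameters, best epoch and history to .npz."""
        check_is_fitted(self, "net_")
        meta = {
            "params": self.get_params(),
            "best_epoch": int(self.best_epoch_),
            "history": self.history_,
        }
        arrays = {f"state__{k}": v for k, v in self.net_.state_dict().items()}
        # write through a handle so numpy never appends an .npz suffix
        with open(path, "wb") as handle:
            np.savez(
                handle,
                __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                **arrays,
            )

    @classmethod
    def load(cls, path) -> "BiLSTMPromoterClassifier":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            state = {
                k[len("state__"):]: archive[k]
                for k in archive.files
                if k.startswith("state__")
            }
        est = cls(**meta["params"])
        est.net_ = SeqvecNet(
            vocab_size=est.vocab_size,
            embed_dim=est.embed_dim,
            hidden_dim=est.hidden_dim,
            seq_len=est.seq_len,
            fc1_dim=est.fc1_dim,
            leaky_slope=est.leaky_slope,
            seed=est.random_state,
        )
        est.net_.load_state_dict(state)
        est.best_epoch_ = meta["best_epoch"]
        est.history_ = meta["history"]
        est.classes_ = np.array([0, 1])
        est.n_features_in_ = est.seq_len
        return est


# ----------------------------------------------------------------------
def _stratified_holdout(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a class-stratified holdout of the given fraction."""
    if not 0 < fraction < 1:
        raise ValueError("validation_fraction must be in (0, 1)")
    idx = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        k = max(1, int(round(fraction * members.size)))
        idx.append(rng.choice(members, size=k, replace=False))
    return np.sort(np.concatenate(idx))


def _dataset_to_arrays(
    dataset: LabelledDataset, seq_len: int
) -> Tuple[np.ndarray, np.ndarray]:
    X = encode_batch(dataset.sequences, DEFAULT_TABLE, pad_to=seq_len)
    y = np.asarray(dataset.labels, dtype=np.int64)
    return X, y


def train(
    model_config: ModelConfig,
    train_set: LabelledDataset,
    val_set: LabelledDataset,
    train_config: TrainConfig = TrainConfig(),
) -> BiLSTMPromoterClassifier:
    """Fit the classifier on labelled sequence datasets.

    Sequences are triplet-encoded to the configured width; the
    validation set drives best-epoch selection.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    train_ids = {s.id for s in train_set.sequences}
    val_ids = {s.id for s in val_set.sequences}
    overlap = train_ids & val_ids
    if overlap:
        raise ValueError(f"train/validation ids overlap: {sorted(overlap)[:5]}")
    arch = asdict(model_config)
    arch.pop("n_lstm_layers")  # fixed to 1; not an estimator parameter
    est = BiLSTMPromoterClassifier(
        **arch,
        max_epochs=train_config.max_epochs,
        batch_size=train_config.batch_size,
        learning_rate=train_config.learning_rate,
        shuffle_each_epoch=train_config.shuffle_each_epoch,
        random_state=train_config.seed,
    )
    X, y = _dataset_to_arrays(train_set, model_config.seq_len)
    Xv, yv = _dataset_to_arrays(val_set, model_config.seq_len)
    return est.fit(X, y, validation_data=(Xv, yv))


def predict(
    model: BiLSTMPromoterClassifier,
    batch: np.ndarray,
    threshold: float = 0.5,
) -> Tuple[np.ndarray, np.ndarray]:
    """(probabilities, binary labels) for an index matrix.

    A probability exactly equal to the threshold classifies positive.
    """
    probs = model.decision_function(batch)
    return probs, (probs >= threshold).astype(np.int64)


def train_val_test_split(
    dataset: LabelledDataset,
    fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> Tuple[LabelledDataset, LabelledDataset, LabelledDataset]:
    """Stratified holdout split into train/validation/test datasets.

    Fractions must be positive and sum to 1; stratification keeps a
    balanced input balanced in every split.  Deterministic given seed.
    """
    f_train, f_val, f_test = fractions
    if min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be positive and sum to 1, got {fractions}")
    y = np.asarray(dataset.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both classes")
    rng = np.random.default_rng(seed)
    buckets: Dict[str, List[Tuple[DnaSequence, int]]] = {
        "train": [],
        "validation": [],
        "test": [],
    }
    for cls in (0, 1):
        members = np.flatnonzero(y == cls)
        members = rng.permutation(members)
        n = members.size
        n_train = int(round(f_train * n))
        n_val = int(round(f_val * n))
        n_train = min(n_train, n)
        n_val = min(n_val, n - n_train)
        parts = {
            "train": members[:n_train],
            "validation": members[n_train : n_train + n_val],
            "test": members[n_train + n_val :],
        }
        for tag, idx in parts.items():
            if idx.size == 0:
                raise ValueError(
                    f"split {tag!r} would receive no members of class {cls}"
                )
            buckets[tag].extend(dataset.records[i] for i in np.sort(idx))
    return (
        LabelledDataset(records=buckets["train"], split_tag="train"),
        LabelledDataset(records=buckets["validation"], split_tag="validation"),
        LabelledDataset(records=buckets["test"], split_tag="test"),
    )
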