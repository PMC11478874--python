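"""Shallow tanh network classifier and leave-one-subject-out evaluation.

The classifier is a three-layer feed-forward network — one input, one hidden,
one output layer — with twice as many hidden nodes as inputs, hyperbolic
tangent hidden activation, and a 2-node output trained with softmax
cross-entropy by plain mini-batch SGD (batch 16, learning rate 0.01, at most
100 epochs; 50 for the small slap-shot dataset).  For the canonical feature
layouts this gives (1200, 2400, 2) node counts unilaterally and
(2400, 4800, 2) bilaterally.

Evaluation is leave-one-subject-out: one fold per participant, trained on
everyone else, tested on the held-out participant's complete dataset;
per-participant accuracies n_p / N_p * 100 are averaged across folds.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

CANONICAL_INPUT_DIMS = (1200, 2400)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ShallowTanhClassifier(ClassifierMixin, BaseEstimator):
    """One-hidden-layer tanh network trained with mini-batch SGD.

    Parameters
    ----------
    hidden_factor : hidden nodes per input node (architecture rule: 2).
    learning_rate, batch_size, max_epochs, momentum : SGD hyperparameters.
    validation_fraction : fraction of the training data held out to monitor
        validation loss; used for early stopping only when ``early_stopping``.
    early_stopping, patience : stop when validation loss has not improved for
        ``patience`` epochs (off by default; training runs to ``max_epochs``).
    random_state : seed controlling initialization, shuffling and the
        validation split; fits are bit-reproducible under a fixed seed.

    Attributes (after fit)
    ----------------------
    classes_ : label for each output node (first class = index 0).
    coefs_ : [W1 (input x hidden), W2 (hidden x 2)].
    intercepts_ : [b1, b2].
    loss_curve_ : training loss per epoch.
    """

    def __init__(
        self,
        hidden_factor: int = 2,
        learning_rate: float = 0.01,
        batch_size: int = 16,
        max_epochs: int = 100,
        momentum: float = 0.0,
        validation_fraction: float = 0.1,
        early_stopping: bool = False,
        patience: int = 10,
        random_state: int | None = None,
    ):
        self.hidden_factor = hidden_factor
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.momentum = momentum
        self.validation_fraction = validation_fraction
        self.early_stopping = early_stopping
        self.patience = patience
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        H = np.tanh(X @ self.coefs_[0] + self.intercepts_[0])
        return H, H @ self.coefs_[1] + self.intercepts_[1]

    def _init_weights(self, n_in: int, n_hidden: int, n_out: int, rng) -> None:
        lim1 = np.sqrt(6.0 / (n_in + n_hidden))
        lim2 = np.sqrt(6.0 / (n_hidden + n_out))
        self.coefs_ = [
            rng.uniform(-lim1, lim1, size=(n_in, n_hidden)),
            rng.uniform(-lim2, lim2, size=(n_hidden, n_out)),
        ]
        self.intercepts_ = [np.zeros(n_hidden), np.zeros(n_out)]

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"exactly 2 classes required; got {list(self.classes_)}"
            )
        if self.learning_rate < 0 or self.batch_size < 1:
            raise ValueError("learning_rate must be >= 0 and batch_size >= 1")
        self.n_features_in_ = X.shape[1]
        n_hidden = self.hidden_factor * self.n_features_in_
        rng = np.random.default_rng(self.random_state)
        self._init_weights(self.n_features_in_, n_hidden, len(self.classes_), rng)

        Y = (y[:, None] == self.classes_[None, :]).astype(float)
        n = len(X)
        n_val = int(round(self.validation_fraction * n)) if self.early_stopping else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, Ytr = X[tr_idx], Y[tr_idx]

        vel = [np.zeros_like(w) for w in self.coefs_] + [
            np.zeros_like(b) for b in self.intercepts_
        ]
        self.loss_curve_ = []
        best_val, since_best = np.inf, 0
        for _epoch in range(self.max_epochs):
            order = rng.permutation(len(Xtr))
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(Xtr), self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = Xtr[idx], Ytr[idx]
                H, scores = self._forward(xb)
                P = _softmax(scores)
                loss = -np.mean(np.sum(yb * np.log(P + 1e-300), axis=1))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss at epoch {_epoch})"
                    )
                epoch_loss += loss
                n_batches += 1
                dscores = (P - yb) / len(xb)
                gW2 = H.T @ dscores
                gb2 = dscores.sum(axis=0)
                dH = dscores @ self.coefs_[1].T * (1.0 - H**2)
                gW1 = xb.T @ dH
                gb1 = dH.sum(axis=0)
                grads = [gW1, gW2, gb1, gb2]
                params = [
                    self.coefs_[0],
                    self.coefs_[1],
                    self.intercepts_[0],
                    self.intercepts_[1],
                ]
                for v, g, p in zip(vel, grads, params):
                    v *= self.momentum
                    v -= self.learning_rate * g
                    p += v
            self.loss_curve_.append(epoch_loss / max(n_batches, 1))
            if self.early_stopping and n_val:
                _, vs = self._forward(X[val_idx])
                vp = _softmax(vs)
                vloss = -np.mean(np.sum(Y[val_idx] * np.log(vp + 1e-300), axis=1))
                if vloss < best_val - 1e-12:
                    best_val, since_best = vloss, 0
                else:
                    since_best += 1
                    if since_best >= self.patience:
                        break
        return self

    def decision_function(self, X) -> np.ndarray:
        """Pre-softmax output scores (the quantities relevance is propagated from)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self._forward(X)[1]

    def predict_proba(self, X) -> np.ndarray:
        return _softmax(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        ties = scores[:, 0] == scores[:, 1]
        if np.any(ties):
            warnings.warn(
                f"{int(ties.sum())} tied score(s); breaking toward the first class",
                stacklevel=2,
            )
        return self.classes_[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# Thin functional wrappers and the LOSO protocol


def init_model(
    input_dim: int, seed: int, allow_nonstandard: bool = False
) -> ShallowTanhClassifier:
    """Build (untrained, weight-initialized) the canonical architecture."""
    if input_dim not in CANONICAL_INPUT_DIMS and not allow_nonstandard:
        raise ValueError(
            f"input_dim {input_dim} is not one of the canonical layouts "
            f"{CANONICAL_INPUT_DIMS}; pass allow_nonstandard=True for experiments"
        )
    clf = ShallowTanhClassifier(random_state=seed)
    rng = np.random.default_rng(seed)
    clf.n_features_in_ = input_dim
    clf._init_weights(input_dim, 2 * input_dim, 2, rng)
    clf.classes_ = np.array(["Equipment", "NoEquipment"])
    return clf


def train(model: ShallowTanhClassifier, X, y, **overrides) -> ShallowTanhClassifier:
    if overrides:
        model.set_params(**overrides)
    return model.fit(X, y)


def predict_class(model: ShallowTanhClassifier, x) -> tuple[str, np.ndarray]:
    scores = model.decision_function(np.atleast_2d(x))[0]
    if scores[0] == scores[1]:
        warnings.warn("tied class scores; choosing the first class", stacklevel=2)
    return str(model.classes_[int(np.argmax(scores))]), scores


def fold_seed(global_seed: int, participant_id: str) -> int:
    """Deterministic per-fold seed derived from the global seed (below 2^31)."""
    return zlib.crc32(f"{global_seed}:{participant_id}".encode()) & 0x7FFFFFFF


@dataclass
class FoldResult:
    participant_id: str
    accuracy: float          # percent
    n_correct: int
    n_total: int
    model: ShallowTanhClassifier
    predictions: np.ndarray
    test_indices: np.ndarray


@dataclass
class EvaluationResult:
    folds: dict[str, FoldResult]
    mean_accuracy: float     # arithmetic mean of per-participant accuracies, %
    confusion: np.ndarray    # 2x2, rows = true class, cols = predicted
    classes: np.ndarray
    seed: int

    @property
    def per_participant(self) -> dict[str, float]:
        return {p: f.accuracy for p, f in self.folds.items()}


def loso_evaluate(
    X,
    y,
    participants,
    seed: int = 0,
    clf_params: dict | None = None,
) -> EvaluationResult:
    """Leave-one-subject-out evaluation: one fold per participant.

    Each fold trains a fresh network (fold seed derived from the global seed)
    on all other participants and classifies the held-out participant's
    complete set of movements.  All fold models are retained for the
    relevance stage.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    participants = np.asarray(participants)
    pids = sorted(set(participants.tolist()))
    if len(pids) < 3:
        raise ValueError(f"LOSO needs >= 3 participants, got {len(pids)}")
    classes = np.unique(y)
    folds: dict[str, FoldResult] = {}
    confusion = np.zeros((2, 2), dtype=int)
    for pid in pids:
        test_mask = participants == pid
        if not np.any(test_mask):
            warnings.warn(f"participant {pid} has no segments; fold skipped", stacklevel=2)
            continue
        params = dict(clf_params or {})
        params["random_state"] = fold_seed(seed, pid)
        clf = ShallowTanhClassifier(**params)
        clf.fit(X[~test_mask], y[~test_mask])
        pred = clf.predict(X[test_mask])
        truth = y[test_mask]
        n_correct = int(np.sum(pred == truth))
        n_total = int(test_mask.sum())
        for yt, yp in zip(truth, pred):
            confusion[
                int(np.searchsorted(classes, yt)), int(np.searchsorted(classes, yp))
            ] += 1
        folds[pid] = FoldResult(
            participant_id=pid,
            accuracy=100.0 * n_correct / n_total,
            n_correct=n_correct,
            n_total=n_total,
            model=clf,
            predictions=pred,
            test_indices=np.nonzero(test_mask)[0],
        )
    mean_acc = float(np.mean([f.accuracy for f in folds.values()]))
    return EvaluationResult(
        folds=folds, mean_accuracy=mean_acc, confusion=confusion, classes=classes, seed=seed
    )
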