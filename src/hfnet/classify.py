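"""Stimulus-related topology dynamics: ISI labeling + tanh backprop classifier.

Each sliding window is labeled with the index of the inter-stimulus interval
(ISI) containing its onset; a three-layer feed-forward network (inputs =
nodes at one frequency, 8 tanh hidden units, one tanh output per ISI class)
is then trained by plain back-propagation to recognize the ISI from the
window's nodal-metric pattern.  Classification accuracy (CA, percent correct
on a held-out quarter of the windows, averaged over repeated random splits)
measures how strongly network topology is locked to the stimulus schedule.

``TanhBackpropClassifier`` follows the scikit-learn estimator protocol and
composes with sklearn model selection; targets are one-hot at +/-1 to match
the tanh output range, the loss is squared error, and training is full-batch
gradient descent with momentum and early stopping on a loss plateau.  The
repeated-split experiment (75/25 split of 81 windows = 61/20, 100
repetitions) lives in :func:`train_and_evaluate` / :func:`run_stimulus_ntd`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .ntd import MetricDynamicsMatrix
from .synthetic import StimulusSchedule

__all__ = [
    "FNNConfig",
    "ClassificationResult",
    "TanhBackpropClassifier",
    "label_windows",
    "train_and_evaluate",
    "run_stimulus_ntd",
]

logger = logging.getLogger(__name__)


def label_windows(
    schedule: StimulusSchedule,
    n_windows: int,
    step_ms: float = 100.0,
    window_onsets: Optional[np.ndarray] = None,
) -> np.ndarray:
    """ISI class (1..K) of each sliding window, assigned at window onset.

    ISI k spans [onset_k, onset_{k+1}) with the last ISI extending to the
    segment end; a window whose onset lies at a stimulus time belongs to the
    ISI beginning there.  Window onsets before the first stimulus get class 1
    with a warning.
    """
    if window_onsets is None:
        window_onsets = np.arange(n_windows) * (step_ms / 1000.0)
    window_onsets = np.asarray(window_onsets, dtype=float)
    k = np.searchsorted(schedule.onsets, window_onsets, side="right")
    if np.any(k == 0):
        warnings.warn(
            f"{int(np.count_nonzero(k == 0))} window(s) start before the first "
            "stimulus; assigned to the first ISI"
        )
        k = np.maximum(k, 1)
    return k.astype(int)


class TanhBackpropClassifier(BaseEstimator, ClassifierMixin):
    """Three-layer feed-forward network with tanh units and backprop.

    Architecture: n_features -> n_hidden (tanh) -> n_classes (tanh); targets
    are one-hot at +/-1, loss is mean squared error, training is full-batch
    gradient descent with momentum, stopping early once the loss has not
    improved by ``tol`` for ``patience`` consecutive epochs.  Features are
    z-scored on the training data (constant features pass through as zeros).

    Parameters
    ----------
    n_hidden : hidden layer width (default 8).
    learning_rate, momentum : gradient-descent step and momentum term.
    max_epochs, tol, patience : stopping rule.
    standardize : z-score features on fit (statistics stored on the model).
    random_state : seed of the weight initialization.
    """

    def __init__(
        self,
        n_hidden: int = 8,
        learning_rate: float = 0.01,
        momentum: float = 0.9,
        max_epochs: int = 500,
        tol: float = 1e-6,
        patience: int = 25,
        standardize: bool = True,
        random_state: Optional[int] = None,
    ):
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.max_epochs = max_epochs
        self.tol = tol
        self.patience = patience
        self.standardize = standardize
        self.random_state = random_state

    def _scale(self, X: np.ndarray) -> np.ndarray:
        if not self.standardize:
            return X
        return (X - self.mean_) / self.scale_

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be positive")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, d = X.shape
        k = self.classes_.size
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        Xs = self._scale(X)
        T = -np.ones((n, k))
        T[np.arange(n), y_idx] = 1.0

        rng = np.random.default_rng(self.random_state)
        w1 = rng.uniform(-0.5, 0.5, size=(d, self.n_hidden)) / np.sqrt(d)
        b1 = np.zeros(self.n_hidden)
        w2 = rng.uniform(-0.5, 0.5, size=(self.n_hidden, k)) / np.sqrt(self.n_hidden)
        b2 = np.zeros(k)
        v = [np.zeros_like(p) for p in (w1, b1, w2, b2)]
        best = np.inf
        stall = 0
        self.loss_curve_ = []
        for epoch in range(self.max_epochs):
            h = np.tanh(Xs @ w1 + b1)
            o = np.tanh(h @ w2 + b2)
            err = o - T
            loss = float(np.mean(err**2))
            self.loss_curve_.append(loss)
            d2 = (2.0 / (n * k)) * err * (1.0 - o**2)
            g_w2 = h.T @ d2
            g_b2 = d2.sum(axis=0)
            d1 = (d2 @ w2.T) * (1.0 - h**2)
            g_w1 = Xs.T @ d1
            g_b1 = d1.sum(axis=0)
            for p, vel, grad in zip((w1, b1, w2, b2), v, (g_w1, g_b1, g_w2, g_b2)):
                vel *= self.momentum
                vel -= self.learning_rate * grad
                p += vel
            if best - loss > self.tol:
                best = loss
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        self.w1_, self.b1_, self.w2_, self.b2_ = w1, b1, w2, b2
        self.n_iter_ = len(self.loss_curve_)
        self.n_features_in_ = d
        return self

    def decision_function(self, X):
        check_is_fitted(self, "w1_")
        X = check_array(X)
        h = np.tanh(self._scale(X) @ self.w1_ + self.b1_)
        return np.tanh(h @ self.w2_ + self.b2_)

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


@dataclass(frozen=True)
class FNNConfig:
    """Experiment configuration for the split-train-test procedure."""

    n_hidden: int = 8
    train_fraction: float = 0.75
    n_repetitions: int = 100
    learning_rate: float = 0.01
    momentum: float = 0.9
    max_epochs: int = 500
    tol: float = 1e-6
    patience: int = 25
    standardize: bool = True
    seed: Optional[int] = None
    max_redraws: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_hidden < 1 or self.n_repetitions < 1:
            raise ValueError("layer sizes and repetition count must be positive")


@dataclass
class ClassificationResult:
    """Per-repetition and mean classification accuracy (percent correct)."""

    ca_per_repetition: np.ndarray
    split_sizes: tuple[int, int]
    n_redraws: int = 0

    @property
    def ca_mean(self) -> float:
        return float(np.mean(self.ca_per_repetition))

    @property
    def ca_sd(self) -> float:
        return float(np.std(self.ca_per_repetition, ddof=1)) if self.ca_per_repetition.size > 1 else 0.0


def train_and_evaluate(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: Optional[FNNConfig] = None,
) -> ClassificationResult:
    """Repeated random-split training of the tanh network.

    ``features`` is windows x nodes, ``labels`` one ISI class per window.
    Per repetition the windows are split at ``train_fraction`` (61/20 for 81
    windows at 75 %), without stratification; splits missing a training
    class are re-drawn (counted and logged).  CA is percent correct on the
    held-out windows.
    """
    cfg = cfg or FNNConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("one label per feature row required")
    n = X.shape[0]
    n_train = int(round(cfg.train_fraction * n))
    if n_train < 1 or n_train >= n:
        raise ValueError("train fraction leaves an empty split")
    classes = np.unique(y)
    rng = np.random.default_rng(cfg.seed)
    cas = np.empty(cfg.n_repetitions)
    n_redraws = 0
    for rep in range(cfg.n_repetitions):
        for _ in range(cfg.max_redraws + 1):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            if np.isin(classes, y[tr]).all():
                break
            n_redraws += 1
        else:
            raise RuntimeError("could not draw a split containing every class")
        clf = TanhBackpropClassifier(
            n_hidden=cfg.n_hidden,
            learning_rate=cfg.learning_rate,
            momentum=cfg.momentum,
            max_epochs=cfg.max_epochs,
            tol=cfg.tol,
            patience=cfg.patience,
            standardize=cfg.standardize,
            random_state=int(rng.integers(2**31)),
        )
        clf.fit(X[tr], y[tr])
        cas[rep] = 100.0 * float(np.mean(clf.predict(X[te]) == y[te]))
    if n_redraws:
        logger.info("re-drew %d split(s) missing a class", n_redraws)
    return ClassificationResult(
        ca_per_repetition=cas, split_sizes=(n_train, n - n_train), n_redraws=n_redraws
    )


def run_stimulus_ntd(
    metrics: dict[str, MetricDynamicsMatrix],
    schedule: StimulusSchedule,
    cfg: Optional[FNNConfig] = None,
    fois: Optional[Sequence[float]] = None,
    step_ms: float = 100.0,
) -> pd.DataFrame:
    """CA table over (metric, frequency-of-interest) combinations.

    Each MetricDynamicsMatrix must be stacked frequency-major (node blocks of
    equal channel count per FOI, as built by :func:`hfnet.hfn.node_table`).
    Missing or malformed FOI blocks are skipped with a warning.
    """
    cfg = cfg or FNNConfig()
    rows = []
    rng = np.random.default_rng(cfg.seed)
    for name, m in metrics.items():
        if m.node_index is not None:
            block_fois = sorted({nd.foi for nd in m.node_index})
        elif fois is not None:
            block_fois = [float(f) for f in fois]
        else:
            raise ValueError("fois required when matrices carry no node table")
        if m.n_nodes % len(block_fois):
            warnings.warn(f"metric {name}: node count not divisible into FOI blocks")
            continue
        per = m.n_nodes // len(block_fois)
        labels = label_windows(schedule, m.n_windows, step_ms=step_ms)
        for b, foi in enumerate(block_fois):
            feats = m.values[b * per : (b + 1) * per, :].T  # windows x nodes
            feats = np.nan_to_num(feats)
            sub_cfg = FNNConfig(
                **{
                    **cfg.__dict__,
                    "seed": int(rng.integers(2**31)),
                }
            )
            res = train_and_evaluate(feats, labels, sub_cfg)
            rows.append(
                {
                    "metric": name,
                    "foi_hz": foi,
                    "ca_mean": res.ca_mean,
                    "ca_sd": res.ca_sd,
                    "n_repetitions": cfg.n_repetitions,
                }
            )
    return pd.DataFrame(rows)
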