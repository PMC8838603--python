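"""The three synthetic-accessibility classifier families.

* RF-PCD: random forest on the six physicochemical descriptors.
* DNN-ECFP: feed-forward network on 2048-bit ECFP4, trained with RMSprop on
  binary cross-entropy, learning rate halved on validation plateau, best
  checkpoint kept by validation AUC.
* Graph classifier: communicative message-passing network (CMPNN-style) on
  molecular graphs; see :mod:`rxnsa.mpnn`.

All models expose ``predict_proba(X) -> ES-probabilities`` and are
deterministic for a given seed on CPU.
"""
from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import autodiff as ad
from .metrics import roc_auc

log = logging.getLogger(__name__)


@dataclass
class DNNConfig:
    hidden: tuple = (1024, 256)
    dropout: float = 0.2
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 30
    plateau_patience: int = 3
    plateau_factor: float = 0.5
    seed: int = 0


def _check_two_classes(labels01):
    if len(np.unique(labels01)) < 2:
        raise ValueError("training labels contain a single class")


def train_rf_pcd(features: np.ndarray, labels01: np.ndarray,
                 n_estimators: int = 200, seed: int = 0) -> RandomForestClassifier:
    """Random forest on physicochemical descriptors (label 1 = ES)."""
    _check_two_classes(labels01)
    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                   n_jobs=1)
    model.fit(np.asarray(features), np.asarray(labels01, dtype=int))
    return model


def rf_predict_proba(model: RandomForestClassifier, features) -> np.ndarray:
    return model.predict_proba(np.asarray(features))[:, 1]


class FeedForwardNet:
    """Plain MLP on fingerprint inputs with a logit output."""

    def __init__(self, n_in: int, config: DNNConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.weights, self.biases = [], []
        sizes = (n_in, *config.hidden, 1)
        for a, b in zip(sizes, sizes[1:]):
            self.weights.append(ad.glorot(rng, a, b))
            self.biases.append(ad.Parameter(np.zeros((1, b))))

    @property
    def parameters(self):
        return self.weights + self.biases

    def logits(self, x: np.ndarray, dropout_rng=None):
        h = ad.Tensor(x)
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = ad.add(ad.matmul(h, w), b)
            if i < last:
                h = ad.relu(h)
                h = ad.dropout(h, self.config.dropout, dropout_rng)
        return h

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        out = self.logits(np.asarray(x, dtype=np.float64))
        return (0.5 * (1.0 + np.tanh(0.5 * out.data))).ravel()

    def state(self):
        return [p.data.copy() for p in self.parameters]

    def load_state(self, state):
        for p, s in zip(self.parameters, state):
            p.data = s.copy()


def train_dnn_ecfp(fingerprints: np.ndarray, labels01: np.ndarray,
                   val_fingerprints: np.ndarray, val_labels01: np.ndarray,
                   config: DNNConfig | None = None) -> FeedForwardNet:
    """Train the DNN-ECFP classifier; returns the best-validation checkpoint.

    RMSprop on binary cross-entropy; the learning rate decays by the plateau
    factor when validation AUC stops improving, and the weights giving the
    best validation AUC are restored at the end.
    """
    config = config or DNNConfig()
    X = np.asarray(fingerprints, dtype=np.float64)
    y = np.asarray(labels01, dtype=np.float64)
    if config.epochs > 0:
        _check_two_classes(y)
    net = FeedForwardNet(X.shape[1], config)
    opt = ad.RMSprop(net.parameters, lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    best_auc, best_state, stale = -np.inf, net.state(), 0
    for _epoch in range(config.epochs):
        order = rng.permutation(len(X))
        for start in range(0, len(X), config.batch_size):
            idx = order[start:start + config.batch_size]
            loss = ad.bce_with_logits(net.logits(X[idx], dropout_rng=rng), y[idx])
            loss.backward()
            opt.step()
        val_auc = roc_auc(net.predict_proba(val_fingerprints),
                          np.asarray(val_labels01, dtype=bool))
        if val_auc > best_auc + 1e-6:
            best_auc, best_state, stale = val_auc, net.state(), 0
        else:
            stale += 1
            if stale >= config.plateau_patience:
                opt.lr *= config.plateau_factor
                stale = 0
    net.load_state(best_state)
    return net
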