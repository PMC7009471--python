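"""Gaussian naive Bayes classifier, written from first principles.

The model assumes the selected features are conditionally independent given
the class, each with a class-specific Gaussian density.  The posterior of
class k for a feature vector x is

    P(Y=k | x)  =  pi_k * prod_j N(x_j; mu_kj, var_kj)  /  sum_k' (same),

with priors pi_k equal to the class relative frequencies in the training
data.  All products are evaluated in log space with log-sum-exp
normalization; with six standardized features the direct product would
otherwise underflow routinely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

#: relative variance floor: var_kj >= VAR_FLOOR_REL * max(var)
VAR_FLOOR_REL = 1e-9


@dataclass
class GNBModel:
    """Fitted parameters: priors and per-class per-feature Gaussians."""

    classes: np.ndarray
    priors: np.ndarray  # (K,), sums to 1
    means: np.ndarray  # (K, P)
    variances: np.ndarray  # (K, P), floored strictly positive

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "classes": [str(c) for c in self.classes],
            "priors": self.priors.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
        })
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, payload: str | Path) -> "GNBModel":
        if isinstance(payload, Path) or (isinstance(payload, str)
                                         and payload.lstrip()[:1] != "{"):
            payload = Path(payload).read_text()
        d = json.loads(payload)
        return cls(classes=np.asarray(d["classes"]),
                   priors=np.asarray(d["priors"], dtype=float),
                   means=np.asarray(d["means"], dtype=float),
                   variances=np.asarray(d["variances"], dtype=float))


def fit(X: np.ndarray, y: np.ndarray) -> GNBModel:
    """Estimate priors and class-conditional Gaussian parameters.

    Priors are class relative frequencies; means and variances (ddof=0) are
    computed per class per feature.  Variances are floored at
    ``1e-9 * max(variance)`` so a feature that is constant within one class
    cannot produce a degenerate density.  Every class must have at least two
    training rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data must contain at least two classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least two training rows")
    K, P = len(classes), X.shape[1]
    means = np.empty((K, P))
    variances = np.empty((K, P))
    for k, c in enumerate(classes):
        Xc = X[y == c]
        means[k] = Xc.mean(axis=0)
        variances[k] = Xc.var(axis=0, ddof=0)
    vmax = variances.max()
    floor = VAR_FLOOR_REL * (vmax if vmax > 0 else 1.0)
    variances = np.maximum(variances, floor)
    return GNBModel(classes=classes, priors=counts / counts.sum(),
                    means=means, variances=variances)


def log_posterior(model: GNBModel, X: np.ndarray) -> np.ndarray:
    """Unnormalized-then-normalized log posterior, ``(n, K)``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features")
    # log pi_k + sum_j log N(x_j; mu_kj, var_kj)
    diff = X[:, None, :] - model.means[None, :, :]  # (n, K, P)
    ll = -0.5 * (np.log(2 * np.pi * model.variances)[None]
                 + diff ** 2 / model.variances[None]).sum(axis=2)
    joint = np.log(model.priors)[None] + ll
    return joint - logsumexp(joint, axis=1, keepdims=True)


def posterior(model: GNBModel, X: np.ndarray) -> np.ndarray:
    """Posterior class probabilities, rows summing to 1 (within 1e-12)."""
    return np.exp(log_posterior(model, X))


def predict(model: GNBModel, X: np.ndarray) -> np.ndarray:
    """Maximum-posterior class per row; exact ties go to the first class in
    sorted label order (``argmax`` keeps the first maximum)."""
    return model.classes[np.argmax(log_posterior(model, X), axis=1)]


def score(model: GNBModel, X: np.ndarray, positive) -> np.ndarray:
    """Posterior probability of the ``positive`` class (the ROC score)."""
    k = int(np.flatnonzero(model.classes == positive)[0])
    return posterior(model, X)[:, k]
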