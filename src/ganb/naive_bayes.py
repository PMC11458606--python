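"""Naive Bayes risk classification with a posterior-odds risk score.

Two likelihood families are provided.  The Gaussian family models each
feature per class as an independent normal (with a variance floor), which
suits continuous discriminator features.  The multinomial family models a
row as a bag of counts over a vocabulary of V columns and smooths the
per-class value probabilities with a pseudo-count alpha.  Two smoothing
variants are exposed:

    standard:     (count + alpha) / (total + alpha * V)   (Lidstone; sums to 1)
    unnormalized: (count + alpha) / (total + alpha)       (adds alpha once in
                  the denominator, so the per-class conditionals do not sum
                  to 1 over the vocabulary; kept for comparison)

All likelihood arithmetic is in log space; posteriors are normalized with
log-sum-exp.  For a binary {high, low} model the risk score is the
posterior odds S = P(high | x) / P(low | x).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "NbModel",
    "fit",
    "predict_log_posterior",
    "predict_posterior",
    "classify",
    "risk_score",
    "discretize",
    "apply_bins",
    "save_model",
    "load_model",
]

_VAR_FLOOR_SCALE = 1e-9


@dataclass
class NbModel:
    classes: list
    log_priors: np.ndarray  # (k,)
    family: str  # "gaussian" | "multinomial"
    # gaussian
    means: np.ndarray | None = None  # (k, d)
    variances: np.ndarray | None = None  # (k, d)
    # multinomial
    log_cond: np.ndarray | None = None  # (k, V) log P(value v | class)
    alpha: float = 1.0
    smoothing_mode: str = "standard"
    n_features: int = 0
    bin_edges: list | None = None  # optional, carried for serialization

    @property
    def priors(self) -> np.ndarray:
        return np.exp(self.log_priors)


def fit(X: np.ndarray, y, family: str = "gaussian", alpha: float = 1.0,
        smoothing_mode: str = "standard", classes: list | None = None) -> NbModel:
    """Fit class priors and per-class likelihood statistics.

    Priors are empirical class frequencies.  ``classes`` fixes the class
    order (used for tie-breaking and the risk score); by default a binary
    {high, low} problem is ordered (high, low), anything else by first
    appearance.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n_samples, n_features)")
    y = np.asarray(list(y))
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if family not in ("gaussian", "multinomial"):
        raise ValueError(f"unknown family {family!r}")
    if smoothing_mode not in ("standard", "unnormalized"):
        raise ValueError(f"unknown smoothing_mode {smoothing_mode!r}")
    if classes is None:
        seen = list(dict.fromkeys(y.tolist()))
        classes = ["high", "low"] if set(seen) == {"high", "low"} else seen
    counts = np.array([(y == c).sum() for c in classes], dtype=float)
    if np.any(counts == 0):
        empty = classes[int(np.argmin(counts))]
        raise ValueError(f"class {empty!r} has no training samples")
    log_priors = np.log(counts / counts.sum())

    model = NbModel(classes=list(classes), log_priors=log_priors, family=family,
                    alpha=alpha, smoothing_mode=smoothing_mode, n_features=X.shape[1])
    if family == "gaussian":
        k, d = len(classes), X.shape[1]
        means = np.empty((k, d))
        variances = np.empty((k, d))
        global_var = X.var(axis=0).mean() if X.size else 0.0
        floor = _VAR_FLOOR_SCALE * (global_var + 1e-12)
        for i, c in enumerate(classes):
            Xi = X[y == c]
            means[i] = Xi.mean(axis=0)
            variances[i] = np.maximum(Xi.var(axis=0), floor)
        model.means, model.variances = means, variances
    else:
        if np.any(X < 0) or not np.allclose(X, np.round(X)):
            raise ValueError("multinomial family requires non-negative integer counts")
        k, V = len(classes), X.shape[1]
        log_cond = np.empty((k, V))
        for i, c in enumerate(classes):
            cnt = X[y == c].sum(axis=0)
            total = cnt.sum()
            if smoothing_mode == "standard":
                log_cond[i] = np.log(cnt + alpha) - np.log(total + alpha * V)
            else:  # unnormalized variant: alpha added once in the denominator
                log_cond[i] = np.log(cnt + alpha) - np.log(total + alpha)
        model.log_cond = log_cond
    return model


def _joint_log_likelihood(model: NbModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1]}")
    if model.family == "gaussian":
        # log N(x; mu, var) summed over independent features
        diff = X[:, None, :] - model.means[None, :, :]
        ll = -0.5 * (np.log(2.0 * np.pi * model.variances)[None]
                     + diff**2 / model.variances[None])
        return model.log_priors[None, :] + ll.sum(axis=2)
    return model.log_priors[None, :] + X @ model.log_cond.T


def predict_log_posterior(model: NbModel, x: np.ndarray) -> np.ndarray:
    """Log posteriors normalized by log-sum-exp; exp of a row sums to 1."""
    jll = _joint_log_likelihood(model, x)
    out = jll - logsumexp(jll, axis=1, keepdims=True)
    return out[0] if np.asarray(x).ndim == 1 else out


def predict_posterior(model: NbModel, x: np.ndarray) -> np.ndarray:
    return np.exp(predict_log_posterior(model, x))


def classify(model: NbModel, x: np.ndarray):
    """Most probable class; exact ties go to the earlier class in order."""
    jll = _joint_log_likelihood(model, x)
    idx = np.argmax(jll, axis=1)  # argmax takes the first maximum
    labels = [model.classes[i] for i in idx]
    return labels[0] if np.asarray(x).ndim == 1 else labels


def risk_score(model: NbModel, x: np.ndarray):
    """Posterior odds S = P(high | x) / P(low | x), computed in log space."""
    if len(model.classes) != 2:
        raise ValueError("risk score requires a binary model ordered (high, low)")
    lp = np.atleast_2d(predict_log_posterior(model, np.atleast_2d(x)))
    p_low = np.exp(lp[:, 1])
    with np.errstate(over="ignore"):  # saturated odds overflow to the inf sentinel
        s = np.where(p_low < 1e-300, np.inf, np.exp(lp[:, 0] - lp[:, 1]))
    return float(s[0]) if np.asarray(x).ndim == 1 else s


def discretize(X: np.ndarray, n_bins: int = 8, strategy: str = "quantile"
               ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Per-feature binning into integer codes 0..n_bins-1.

    Returns (codes, edges) where edges[j] are the n_bins-1 interior cut
    points of feature j, reusable at prediction time via :func:`apply_bins`.
    A constant feature cannot be cut by quantiles and falls back to uniform
    edges around its value, with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if strategy not in ("quantile", "uniform"):
        raise ValueError(f"unknown strategy {strategy!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    edges: list[np.ndarray] = []
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    for j in range(X.shape[1]):
        col = X[:, j]
        lo, hi = col.min(), col.max()
        if strategy == "quantile" and hi > lo:
            e = np.unique(np.quantile(col, qs))
        else:
            if strategy == "quantile":
                warnings.warn(f"feature {j} is constant; using uniform bins")
            if hi == lo:
                lo, hi = lo - 0.5, hi + 0.5
            e = np.linspace(lo, hi, n_bins + 1)[1:-1]
        edges.append(e)
    return apply_bins(X, edges), edges


def apply_bins(X: np.ndarray, edges: list[np.ndarray]) -> np.ndarray:
    """Map values to bin codes; out-of-range values clamp to the end bins."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    codes = np.empty(X.shape, dtype=np.int64)
    for j, e in enumerate(edges):
        codes[:, j] = np.searchsorted(e, X[:, j], side="right")
    return codes


def save_model(model: NbModel, path: str | Path) -> None:
    doc = {
        "classes": model.classes,
        "log_priors": model.log_priors.tolist(),
        "family": model.family,
        "alpha": model.alpha,
        "smoothing_mode": model.smoothing_mode,
        "n_features": model.n_features,
        "means": None if model.means is None else model.means.tolist(),
        "variances": None if model.variances is None else model.variances.tolist(),
        "log_cond": None if model.log_cond is None else model.log_cond.tolist(),
        "bin_edges": None if model.bin_edges is None else [np.asarray(e).tolist() for e in model.bin_edges],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path: str | Path) -> NbModel:
    doc = json.loads(Path(path).read_text())
    return NbModel(
        classes=doc["classes"],
        log_priors=np.asarray(doc["log_priors"]),
        family=doc["family"],
        alpha=doc["alpha"],
        smoothing_mode=doc["smoothing_mode"],
        n_features=doc["n_features"],
        means=None if doc["means"] is None else np.asarray(doc["means"]),
        variances=None if doc["variances"] is None else np.asarray(doc["variances"]),
        log_cond=None if doc["log_cond"] is None else np.asarray(doc["log_cond"]),
        bin_edges=None if doc["bin_edges"] is None else [np.asarray(e) for e in doc["bin_edges"]],
    )
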