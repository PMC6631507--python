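"""Hudgins' time-domain feature set and the LDA baseline classifier.

The four features per channel — mean absolute value (MAV), zero crossings
(ZC), slope sign changes (SSC) and waveform length (WL) — plus a pooled-
covariance linear discriminant are the field's standard baseline: cheap,
hyperparameter-free, and therefore a fair yardstick for comparing two
acquisition systems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LdaModel",
    "htd_features",
    "lda_fit",
    "lda_predict",
    "mav",
    "slope_sign_changes",
    "wl",
    "zero_crossings",
]

FEATURE_NAMES = ("mav", "zc", "ssc", "wl")


# --------------------------------------------------------------------------
# features
# --------------------------------------------------------------------------

def mav(x) -> float:
    """Mean absolute value: mean |x_i|."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.mean(np.abs(x)))


def wl(x) -> float:
    """Waveform length: sum |x_{i+1} - x_i|."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("window must have at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def zero_crossings(x, eps: float = 0.0) -> int:
    """Count of sign changes whose jump exceeds the deadzone eps."""
    if eps < 0:
        raise ValueError("eps must be nonnegative")
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("window must have at least 2 samples")
    cross = (x[:-1] * x[1:] < 0) & (np.abs(x[:-1] - x[1:]) >= eps)
    return int(np.sum(cross))


def slope_sign_changes(x, eps: float = 0.0) -> int:
    """Count of interior slope reversals with at least one step >= eps."""
    if eps < 0:
        raise ValueError("eps must be nonnegative")
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("window must have at least 3 samples")
    d1 = x[1:-1] - x[:-2]
    d2 = x[1:-1] - x[2:]
    ssc = (d1 * d2 > 0) & (np.maximum(np.abs(d1), np.abs(d2)) >= eps)
    return int(np.sum(ssc))


def htd_features(window: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Per-channel (MAV, ZC, SSC, WL), channel-major, length 4 * n_channels."""
    x = np.atleast_2d(np.asarray(window, dtype=float))
    if x.shape[1] < 3:
        raise ValueError("window too short for the H-TD set")
    mav_c = np.mean(np.abs(x), axis=1)
    wl_c = np.sum(np.abs(np.diff(x, axis=1)), axis=1)
    zc_c = np.sum((x[:, :-1] * x[:, 1:] < 0)
                  & (np.abs(x[:, :-1] - x[:, 1:]) >= eps), axis=1)
    d1 = x[:, 1:-1] - x[:, :-2]
    d2 = x[:, 1:-1] - x[:, 2:]
    ssc_c = np.sum((d1 * d2 > 0) & (np.maximum(np.abs(d1), np.abs(d2)) >= eps), axis=1)
    return np.column_stack([mav_c, zc_c, ssc_c, wl_c]).ravel()


# --------------------------------------------------------------------------
# linear discriminant analysis
# --------------------------------------------------------------------------

@dataclass
class LdaModel:
    classes: np.ndarray      # (K,) class ids, sorted ascending
    means: np.ndarray        # (K, d)
    cov: np.ndarray          # (d, d) pooled covariance after ridge
    priors: np.ndarray       # (K,)
    ridge: float

    def to_dict(self) -> dict:
        return {"classes": self.classes.tolist(), "means": self.means.tolist(),
                "cov": self.cov.tolist(), "priors": self.priors.tolist(),
                "ridge": self.ridge}

    @classmethod
    def from_dict(cls, d: dict) -> "LdaModel":
        return cls(np.asarray(d["classes"]), np.asarray(d["means"], dtype=float),
                   np.asarray(d["cov"], dtype=float), np.asarray(d["priors"], dtype=float),
                   float(d["ridge"]))


def lda_fit(features: np.ndarray, labels: np.ndarray, ridge: float = 1e-6) -> LdaModel:
    """Pooled-covariance LDA with a trace-scaled ridge.

    The shared covariance is the within-class scatter divided by (n − K),
    ridged by ridge * trace(Σ)/d * I to stay positive definite on small
    training sets.  Empirical class priors.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if np.any(counts < 2):
        bad = classes[counts < 2]
        raise ValueError(f"classes with fewer than 2 examples: {bad.tolist()}")
    n, d = X.shape
    if n <= classes.size:
        raise ValueError("need more examples than classes")
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    scatter = np.zeros((d, d))
    for c, mu in zip(classes, means):
        xc = X[y == c] - mu
        scatter += xc.T @ xc
    cov = scatter / (n - classes.size)
    if ridge > 0:
        cov = cov + ridge * np.trace(cov) / d * np.eye(d)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("pooled covariance singular after ridge") from None
    priors = counts / n
    return LdaModel(classes=classes, means=means, cov=cov, priors=priors, ridge=ridge)


def lda_predict(model: LdaModel, features: np.ndarray) -> np.ndarray:
    """argmax_k  x'Σ⁻¹μ_k − ½μ_k'Σ⁻¹μ_k + ln π_k  (ties → lowest class id)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    alpha = np.linalg.solve(model.cov, model.means.T)        # (d, K)
    scores = X @ alpha - 0.5 * np.sum(model.means.T * alpha, axis=0) + np.log(model.priors)
    return model.classes[np.argmax(scores, axis=1)]
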