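"""Score-level fusion of the three matchers (SIFT, shape, orientation).

Each comparison yields a score vector (sift, shape, orientation), all
distances with lower = more genuine.  Scores are z-score normalized with
statistics estimated on training data only, then fused either by a
weighted sum (weights nonnegative, summing to 1; defaults 0.1 / 0.7 / 0.2)
or by an RBF-kernel C-support-vector classifier (gamma = 0.006, C = 1.2)
whose signed decision value, negated so that lower still means genuine,
serves as the fused score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "FEATURES",
    "DEFAULT_WEIGHTS",
    "NormalizationParams",
    "FusionModel",
    "fit_normalization",
    "zscore",
    "inverse_zscore",
    "weighted_sum",
    "fit_svm",
    "fuse",
]

#: Column order of every score matrix handled by this module.
FEATURES = ("sift", "shape", "orientation")

#: Default weighted-sum weights (sift, shape, orientation).
DEFAULT_WEIGHTS = (0.1, 0.7, 0.2)

#: Default RBF kernel width and soft-margin cost of the fused classifier.
DEFAULT_GAMMA = 0.006
DEFAULT_COST = 1.2


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature mean and standard deviation from training scores."""

    u: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sigma) <= 0):
            raise ValueError("sigma must be > 0 for every feature")


@dataclass
class FusionModel:
    """Either a weighted-sum rule or a trained SVC fuser."""

    kind: str  # "weighted_sum" | "svm"
    weights: np.ndarray | None = None
    svc: SVC | None = field(default=None, repr=False)


def fit_normalization(training_scores: np.ndarray,
                      ddof: int = 0) -> NormalizationParams:
    """Per-feature mean and (population, ddof=0) standard deviation."""
    z = np.asarray(training_scores, dtype=float)
    if z.ndim != 2 or z.shape[0] < 2:
        raise ValueError("need at least 2 training score vectors")
    sigma = z.std(axis=0, ddof=ddof)
    if np.any(sigma == 0):
        flat = [FEATURES[i] if i < len(FEATURES) else str(i)
                for i in np.flatnonzero(sigma == 0)]
        raise ValueError(f"zero variance in feature(s): {', '.join(flat)}")
    return NormalizationParams(u=z.mean(axis=0), sigma=sigma)


def zscore(scores: np.ndarray, p: NormalizationParams) -> np.ndarray:
    """z' = (z - u) / sigma, applied per feature."""
    return (np.asarray(scores, dtype=float) - p.u) / p.sigma


def inverse_zscore(z: np.ndarray, p: NormalizationParams) -> np.ndarray:
    """Undo :func:`zscore`."""
    return np.asarray(z, dtype=float) * p.sigma + p.u


def weighted_sum(zv: np.ndarray, weights=DEFAULT_WEIGHTS) -> np.ndarray:
    """Fused score z_f = sum_i z'_i w_i; weights nonnegative, summing to 1."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError(f"weights must sum to 1, got {w.sum()}")
    return np.asarray(zv, dtype=float) @ w


def fit_svm(z_train: np.ndarray, labels: np.ndarray,
            gamma: float = DEFAULT_GAMMA, cost: float = DEFAULT_COST) -> FusionModel:
    """Train the C-SVC fuser on normalized score vectors.

    ``labels`` are +1 for genuine and -1 for imposter vectors; both classes
    must be present.
    """
    y = np.asarray(labels)
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("training labels must contain both classes (+1/-1)")
    svc = SVC(kernel="rbf", gamma=gamma, C=cost)
    svc.fit(np.asarray(z_train, dtype=float), y)
    return FusionModel(kind="svm", svc=svc)


def fuse(zv: np.ndarray, model: FusionModel) -> np.ndarray:
    """Fused score(s) for normalized vector(s); lower = more genuine.

    For the SVC the signed decision value (positive on the genuine side)
    is negated to match the distance convention of the other matchers.
    """
    zv = np.atleast_2d(np.asarray(zv, dtype=float))
    if model.kind == "weighted_sum":
        if model.weights is None:
            raise ValueError("weighted-sum model has no weights")
        out = weighted_sum(zv, model.weights)
    elif model.kind == "svm":
        if model.svc is None:
            raise ValueError("svm model is not fitted")
        out = -model.svc.decision_function(zv)
        # decision_function's sign follows class order; ensure genuine (+1) < 0
        if list(model.svc.classes_) == [-1, 1]:
            pass  # +1 is the positive class: decision > 0 -> genuine -> negated < 0
        else:
            out = -out
    else:
        raise ValueError(f"unknown fusion kind {model.kind!r}")
    return out if out.size > 1 else float(out[0])
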