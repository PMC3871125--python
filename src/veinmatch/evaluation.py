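"""Verification protocols and FAR/FRR/EER/ROC computation.

A verification experiment compares samples of enrolled fingers (classes):
genuine scores come from all unordered within-class sample pairs; imposter
scores from every unordered class pair, crossing a designated subset of s
samples per class (s x s comparisons per class pair).  With n classes and
m samples each, the counts are n*C(m,2) genuine and C(n,2)*s^2 imposter
comparisons — e.g. 142 fingers x 10 samples give 6,390 genuine scores and,
with s = 5, 250,275 imposter scores.

Scores are distances (lower = genuine); a comparison is accepted when its
score <= threshold.  Sweeping the threshold gives the false accept rate
(imposters accepted) and false reject rate (genuines rejected); the equal
error rate is the rate at the FAR = FRR crossing, interpolated linearly
between consecutive (FAR, FRR) pairs in rate space so the EER is exactly
invariant under monotone transforms of the scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

from . import fusion as _fusion

__all__ = [
    "ProtocolSpec",
    "Protocol",
    "RocResult",
    "enumerate_protocol",
    "compute_roc",
    "gar_at_far",
    "run_experiment",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """Comparison-enumeration rule of a verification experiment.

    ``imposter_subset_size`` is s, the number of designated samples per
    class entering imposter comparisons; ``imposter_subset`` optionally
    names those sample indices (defaults to the first s).
    """

    n_classes: int
    samples_per_class: int
    imposter_subset_size: int | None = None

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.samples_per_class < 1:
            raise ValueError("counts must be positive")
        s = self.imposter_subset_size
        if s is not None and not (1 <= s <= self.samples_per_class):
            raise ValueError("imposter subset size must be in 1..samples_per_class")

    @property
    def s(self) -> int:
        return (self.samples_per_class if self.imposter_subset_size is None
                else self.imposter_subset_size)


@dataclass
class Protocol:
    """Explicit comparison lists; each entry is ((class, sample), (class, sample))."""

    genuine: list[tuple[tuple[int, int], tuple[int, int]]]
    imposter: list[tuple[tuple[int, int], tuple[int, int]]]

    @property
    def n_genuine(self) -> int:
        return len(self.genuine)

    @property
    def n_imposter(self) -> int:
        return len(self.imposter)


def enumerate_protocol(spec: ProtocolSpec,
                       imposter_subset: list[int] | None = None) -> Protocol:
    """All genuine and imposter comparison index pairs under ``spec``.

    Genuine: every unordered sample pair within each class.  Imposter: for
    every unordered class pair, all s x s sample crossings over the
    designated subset.  Closed forms: n*C(m,2) and C(n,2)*s^2.
    """
    n, m, s = spec.n_classes, spec.samples_per_class, spec.s
    if imposter_subset is None:
        imposter_subset = list(range(s))
    if len(imposter_subset) != s:
        raise ValueError("imposter subset must have exactly s sample indices")
    genuine = [((c, i), (c, j))
               for c in range(n) for i in range(m) for j in range(i + 1, m)]
    if n < 2:
        raise ValueError("imposter comparisons need at least 2 classes")
    imposter = [((c1, i), (c2, j))
                for c1 in range(n) for c2 in range(c1 + 1, n)
                for i in imposter_subset for j in imposter_subset]
    assert len(genuine) == n * comb(m, 2)
    assert len(imposter) == comb(n, 2) * s * s
    return Protocol(genuine=genuine, imposter=imposter)


@dataclass
class RocResult:
    """Threshold sweep of a labeled score set (accept iff score <= t)."""

    thresholds: np.ndarray
    far: np.ndarray
    frr: np.ndarray
    eer: float

    @property
    def gar(self) -> np.ndarray:
        return 1.0 - self.frr


def compute_roc(genuine, imposter, n_thresholds: int | None = None) -> RocResult:
    """FAR/FRR over all observed score values and the interpolated EER.

    The sweep evaluates every distinct observed score (optionally thinned
    to ``n_thresholds`` values for plotting; the EER always uses the full
    sweep).  FAR is nondecreasing and FRR nonincreasing in the accept
    threshold; the EER interpolates between the two consecutive sweep
    points bracketing the FAR = FRR crossing, in rate space.
    """
    g = np.sort(np.asarray(genuine, dtype=float))
    imp = np.sort(np.asarray(imposter, dtype=float))
    if g.size == 0 or imp.size == 0:
        raise ValueError("both genuine and imposter score lists must be nonempty")

    ts = np.unique(np.concatenate([g, imp]))
    # closed sweep: a threshold below every score and one at/above the max
    ts = np.concatenate([[ts[0] - 1.0], ts])
    far = np.searchsorted(imp, ts, side="right") / imp.size
    frr = 1.0 - np.searchsorted(g, ts, side="right") / g.size

    diff = far - frr  # nondecreasing; EER where it crosses 0
    i = int(np.searchsorted(diff >= 0, True))
    if i == 0:
        eer = (far[0] + frr[0]) / 2.0
    elif diff[i - 1] == 0 or i == ts.size:
        eer = float(far[min(i, ts.size) - 1])
    else:
        # linear interpolation between bracketing (far, frr) pairs
        d0, d1 = diff[i - 1], diff[i]
        lam = -d0 / (d1 - d0)
        eer = float(far[i - 1] + lam * (far[i] - far[i - 1]))

    if n_thresholds is not None and ts.size > n_thresholds:
        idx = np.unique(np.linspace(0, ts.size - 1, n_thresholds).astype(int))
        ts, far, frr = ts[idx], far[idx], frr[idx]
    return RocResult(thresholds=ts, far=far, frr=frr, eer=eer)


def gar_at_far(roc: RocResult, far_level: float) -> float:
    """Genuine accept rate at a given FAR, by interpolation of the sweep."""
    return float(np.interp(far_level, roc.far, roc.gar))


@dataclass
class ExperimentReport:
    """Mean +- sd of EER and GAR(at FAR) per fuser over repeated splits."""

    methods: dict[str, dict[str, float]]
    n_repeats: int
    far_level: float
    details: list[dict] = field(default_factory=list, repr=False)


def _split(n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    half = n // 2
    return perm[:half], perm[half:]


def select_weights(z_genuine: np.ndarray, z_imposter: np.ndarray,
                   step: float = 0.05) -> np.ndarray:
    """Weighted-sum weights minimizing the EER on (training) scores.

    The weights are selected empirically, as in the reference procedure:
    a simplex grid with the given step is searched exhaustively; ties
    break toward the first (lexicographically smallest) combination.
    """
    n = int(round(1.0 / step))
    best, best_w = None, None
    for a in range(n + 1):
        for b in range(n + 1 - a):
            w = np.array([a, b, n - a - b], dtype=float) / n
            eer = compute_roc(z_genuine @ w, z_imposter @ w).eer
            if best is None or eer < best:
                best, best_w = eer, w
    return best_w


def run_experiment(
    genuine_scores: np.ndarray,
    imposter_scores: np.ndarray,
    weights=None,
    gamma: float = _fusion.DEFAULT_GAMMA,
    cost: float = _fusion.DEFAULT_COST,
    n_repeats: int = 20,
    far_level: float = 0.01,
    seed: int = 0,
    keep_details: bool = False,
) -> ExperimentReport:
    """Repeated random-split evaluation of single features and both fusers.

    Per repeat: half of the genuine and half of the imposter score vectors
    train the z-score normalization, the weighted-sum weights (selected
    empirically on the training half unless fixed ``weights`` are given)
    and the SVC fuser; the other halves are scored.  Reports mean and
    standard deviation of the EER and of the GAR at ``far_level`` for each
    single feature (sift, shape, orientation), the weighted sum, and the
    SVC.
    """
    gsc = np.asarray(genuine_scores, dtype=float)
    isc = np.asarray(imposter_scores, dtype=float)
    if gsc.shape[0] < 4 or isc.shape[0] < 4:
        raise ValueError("need at least 4 genuine and 4 imposter score vectors")
    rng = np.random.default_rng(seed)
    names = list(_fusion.FEATURES) + ["weighted_sum", "svm"]
    eers = {k: [] for k in names}
    gars = {k: [] for k in names}
    details = []

    for _ in range(n_repeats):
        gtr, gte = _split(gsc.shape[0], rng)
        itr, ite = _split(isc.shape[0], rng)
        train = np.vstack([gsc[gtr], isc[itr]])
        norm = _fusion.fit_normalization(train)
        zg, zi = _fusion.zscore(gsc[gte], norm), _fusion.zscore(isc[ite], norm)

        fused = {}
        for fi, name in enumerate(_fusion.FEATURES):
            fused[name] = (zg[:, fi], zi[:, fi])
        ztr = _fusion.zscore(train, norm)
        if weights is None:
            w = select_weights(ztr[:len(gtr)], ztr[len(gtr):])
        else:
            w = np.asarray(weights, dtype=float)
        fused["weighted_sum"] = (_fusion.weighted_sum(zg, w),
                                 _fusion.weighted_sum(zi, w))
        ytr = np.concatenate([np.ones(len(gtr)), -np.ones(len(itr))])
        svm = _fusion.fit_svm(ztr, ytr, gamma=gamma, cost=cost)
        fused["svm"] = (np.atleast_1d(_fusion.fuse(zg, svm)),
                        np.atleast_1d(_fusion.fuse(zi, svm)))

        for name, (sg, si) in fused.items():
            roc = compute_roc(sg, si)
            eers[name].append(roc.eer)
            gars[name].append(gar_at_far(roc, far_level))
        if keep_details:
            details.append({"norm": norm, "train_genuine": gtr, "train_imposter": itr})

    methods = {}
    for name in names:
        e, gr = np.array(eers[name]), np.array(gars[name])
        methods[name] = {
            "eer_mean": float(e.mean()), "eer_sd": float(e.std(ddof=1)) if e.size > 1 else 0.0,
            "eer_se": float(e.std(ddof=1) / np.sqrt(e.size)) if e.size > 1 else 0.0,
            "gar_mean": float(gr.mean()), "gar_sd": float(gr.std(ddof=1)) if gr.size > 1 else 0.0,
        }
    return ExperimentReport(methods=methods, n_repeats=n_repeats,
                            far_level=far_level, details=details)
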