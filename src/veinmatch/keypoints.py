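"""SIFT keypoint detection and the geometric-distance match filter.

Keypoints are detected on the (smoothed, cropped) grayscale image, not on
the binarized templates.  Matching is asymmetric: every gallery keypoint is
paired with its Euclidean-nearest probe descriptor.  Because vein images
are smooth, low-contrast objects, Lowe's ratio test discards too little;
instead, pairs are ranked by the geometric (image-plane) distance between
the matched positions and only the k = min(T, m) closest pairs are kept
(T = 20), the rest being discarded as mismatches.  The SIFT score of a
comparison is the mean descriptor distance over the retained pairs; lower
means more similar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from skimage.feature import SIFT

__all__ = [
    "Keypoint",
    "MatchPair",
    "KeypointMatchSet",
    "NoMatchError",
    "detect_and_describe",
    "nearest_neighbor_match",
    "lowe_ratio_filter",
    "geometric_filter",
    "sift_score",
]


class NoMatchError(ValueError):
    """Raised when a comparison has no keypoints to match (verification
    failure condition, mapped to a worst score by callers)."""


@dataclass(frozen=True)
class Keypoint:
    """One scale-space keypoint with its 128-element descriptor."""

    row: float
    col: float
    scale: float
    orientation: float
    descriptor: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.descriptor, dtype=float)
        if d.shape != (128,):
            raise ValueError("descriptor must have exactly 128 elements")
        object.__setattr__(self, "descriptor", d)


@dataclass(frozen=True)
class MatchPair:
    """A gallery keypoint and its nearest probe keypoint.

    ``descriptor_distance`` is the Euclidean distance between the two
    128-d descriptors; ``geometric_distance`` the Euclidean distance
    between the two image positions.
    """

    gallery_kp: Keypoint
    probe_kp: Keypoint
    descriptor_distance: float
    geometric_distance: float


@dataclass
class KeypointMatchSet:
    """The retained pairs after mismatch removal.

    ``k = min(T, m)`` where ``m`` is the pre-filter pair count; pairs are
    sorted by geometric distance ascending.
    """

    pairs: list[MatchPair]
    k: int
    T: int
    m: int


def detect_and_describe(img: np.ndarray, **sift_params) -> list[Keypoint]:
    """Detect scale-space keypoints and 128-d descriptors.

    Deterministic for a fixed image.  An image with no scale-space extrema
    (e.g. constant) yields an empty list, not an error.
    """
    detector = SIFT(**sift_params)
    try:
        detector.detect_and_extract(np.asarray(img, dtype=float))
    except (RuntimeError, ValueError):  # no features / image too small
        return []
    return [
        Keypoint(row=float(r), col=float(c), scale=float(s),
                 orientation=float(o), descriptor=d.astype(float))
        for (r, c), s, o, d in zip(detector.keypoints, detector.scales,
                                   detector.orientations, detector.descriptors)
    ]


def _descriptor_matrix(kps: list[Keypoint]) -> np.ndarray:
    return np.stack([kp.descriptor for kp in kps])


def nearest_neighbor_match(gallery: list[Keypoint],
                           probe: list[Keypoint]) -> list[MatchPair]:
    """One pair per gallery keypoint: its Euclidean-nearest probe descriptor."""
    if not gallery:
        raise NoMatchError("gallery has no keypoints")
    if not probe:
        raise NoMatchError("probe has no keypoints")
    dists = cdist(_descriptor_matrix(gallery), _descriptor_matrix(probe))
    nearest = dists.argmin(axis=1)
    pairs = []
    for i, j in enumerate(nearest):
        g, p = gallery[i], probe[int(j)]
        pairs.append(MatchPair(
            gallery_kp=g, probe_kp=p,
            descriptor_distance=float(dists[i, j]),
            geometric_distance=float(np.hypot(g.row - p.row, g.col - p.col)),
        ))
    return pairs


def lowe_ratio_filter(pairs: list[MatchPair], gallery: list[Keypoint],
                      probe: list[Keypoint], c: float = 0.8) -> list[MatchPair]:
    """Ratio-test baseline: keep pairs with d_nearest <= c * d_second_nearest.

    Provided for comparison only; the pipeline's default mismatch removal
    is :func:`geometric_filter`.  The constant ``c`` has no reference
    value; 0.8 is the conventional choice.
    """
    if c <= 0:
        raise ValueError("ratio constant c must be > 0")
    if len(probe) < 2:
        raise ValueError("ratio test needs at least 2 probe keypoints")
    dists = cdist(_descriptor_matrix(gallery), _descriptor_matrix(probe))
    part = np.partition(dists, 1, axis=1)
    by_gallery = {id(kp): i for i, kp in enumerate(gallery)}
    kept = []
    for pair in pairs:
        i = by_gallery[id(pair.gallery_kp)]
        if part[i, 0] <= c * part[i, 1]:
            kept.append(pair)
    return kept


def geometric_filter(pairs: list[MatchPair], T: int = 20) -> KeypointMatchSet:
    """Keep the k = min(T, m) pairs with smallest geometric distance.

    Ties in the k-th distance break by smaller descriptor distance, then
    input order, for determinism.
    """
    if not pairs:
        raise NoMatchError("no matched pairs to filter")
    if T < 1:
        raise ValueError("T must be >= 1")
    m = len(pairs)
    order = sorted(range(m), key=lambda i: (pairs[i].geometric_distance,
                                            pairs[i].descriptor_distance, i))
    k = min(T, m)
    return KeypointMatchSet(pairs=[pairs[i] for i in order[:k]], k=k, T=T, m=m)


def sift_score(ms: KeypointMatchSet) -> float:
    """Mean descriptor distance over the retained pairs; lower = more similar."""
    if ms.k < 1 or not ms.pairs:
        raise NoMatchError("match set is empty")
    return float(np.mean([p.descriptor_distance for p in ms.pairs]))
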