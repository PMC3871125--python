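"""End-to-end feature extraction and pairwise scoring.

One image is reduced to three representations: the binarized vein shape
template and the 8-direction orientation template from the difference
curvature, and a SIFT keypoint set from the smoothed grayscale image.
A gallery-probe comparison produces a (sift, shape, orientation) score
vector: keypoints are matched and filtered to k = min(T, m) pairs by
geometric distance; the SIFT score is their mean descriptor distance; the
retained match positions anchor the sub-region template scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import curvature, keypoints, preprocess, subregion
from .config import RunConfig
from .evaluation import Protocol

__all__ = ["ImageFeatures", "ScoreVector", "extract_features", "score_pair",
           "build_score_table", "WORST_SCORE"]

#: Score vector assigned when a comparison has no keypoints to match.
WORST_SCORE = {"sift": 1e4, "shape": 1.0, "orientation": 1.0}


@dataclass
class ImageFeatures:
    """All per-image representations needed for matching."""

    image: np.ndarray
    shape_template: np.ndarray
    orientation_template: np.ndarray
    keypoints: list = field(repr=False, default_factory=list)


@dataclass(frozen=True)
class ScoreVector:
    """Distances of one comparison; lower = more similar for all three."""

    sift: float
    shape: float
    orientation: float

    def as_array(self) -> np.ndarray:
        return np.array([self.sift, self.shape, self.orientation])


def extract_features(img: np.ndarray, config: RunConfig | None = None,
                     smoothed: bool = False) -> ImageFeatures:
    """Smooth, enhance, binarize, encode orientation, and detect keypoints."""
    cfg = config or RunConfig()
    if not smoothed:
        img = preprocess.gaussian_smooth(img, cfg.smooth_size, cfg.smooth_sigma)
    dmap = curvature.difference_curvature_map(img, r=cfg.curvature_r)
    mask = curvature.binarize(dmap, cfg.threshold)
    codes = curvature.orientation_encode(img, r=cfg.curvature_r, support=mask)
    kps = keypoints.detect_and_describe(img, **cfg.sift_params)
    return ImageFeatures(image=img, shape_template=mask,
                         orientation_template=codes, keypoints=kps)


def score_pair(gallery: ImageFeatures, probe: ImageFeatures,
               config: RunConfig | None = None) -> ScoreVector:
    """The (sift, shape, orientation) score vector of one comparison.

    Raises :class:`~veinmatch.keypoints.NoMatchError` when either image has
    no keypoints; batch callers map that to :data:`WORST_SCORE`.
    """
    cfg = config or RunConfig()
    pairs = keypoints.nearest_neighbor_match(gallery.keypoints, probe.keypoints)
    ms = keypoints.geometric_filter(pairs, T=cfg.match_T)
    sift = keypoints.sift_score(ms)

    g_centers = [(p.gallery_kp.row, p.gallery_kp.col) for p in ms.pairs]
    p_centers = [(p.probe_kp.row, p.probe_kp.col) for p in ms.pairs]

    scores = {}
    for kind, spec, g_tpl, p_tpl in (
        ("shape", cfg.shape_spec, gallery.shape_template, probe.shape_template),
        ("orientation", cfg.orientation_spec, gallery.orientation_template,
         probe.orientation_template),
    ):
        ga = subregion.extract_subregions(g_tpl, g_centers, spec, "gallery")
        pb = subregion.extract_subregions(p_tpl, p_centers, spec, "probe")
        scores[kind] = subregion.template_score(
            ga, pb, kind=kind,
            ignore_background=cfg.ignore_background).total
    return ScoreVector(sift=sift, shape=scores["shape"],
                       orientation=scores["orientation"])


def build_score_table(features: list[list[ImageFeatures]], protocol: Protocol,
                      config: RunConfig | None = None) -> pd.DataFrame:
    """Score every protocol comparison; columns gallery_id, probe_id, label,
    sift, shape, orientation.

    ``features[c][i]`` is sample i of class c.  Comparisons with no
    keypoints receive :data:`WORST_SCORE` instead of failing.
    """
    cfg = config or RunConfig()
    rows = []
    for label, comparisons in (("genuine", protocol.genuine),
                               ("imposter", protocol.imposter)):
        for (c1, i1), (c2, i2) in comparisons:
            try:
                sv = score_pair(features[c1][i1], features[c2][i2], cfg)
                rec = {"sift": sv.sift, "shape": sv.shape,
                       "orientation": sv.orientation}
            except keypoints.NoMatchError:
                rec = dict(WORST_SCORE)
            rows.append({"gallery_id": f"{c1}:{i1}", "probe_id": f"{c2}:{i2}",
                         "label": label, **rec})
    return pd.DataFrame(rows)
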