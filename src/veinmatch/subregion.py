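"""Keypoint-centered sub-region template matching.

The vein shape / orientation templates of a gallery-probe comparison are
partitioned into k sub-regions, one per retained keypoint match, centered
on the matched positions.  The gallery window is larger than the probe
window (default 120x60 vs 110x50 for shape templates, 60x40 vs 50x30 for
orientation templates, sizes given as width x height), so a probe region
slides over every integer offset (x, y), x in [0, w_a - w_b],
y in [0, h_a - h_b], inside its gallery region.  The per-region score

    Psi_i = min_offsets  sum Phi(a(u+x, v+y), b(u, v)) / (w_b * h_b)

is the minimum mismatch fraction over offsets, with Phi the per-pixel
mismatch kernel: |P1 - P2| = 1 for binary shape pixels, P1 != P2 for
orientation codes.  The comparison's score S = mean_i Psi_i; scores lie in
[0, 1] and lower means more similar.  Templates are zero-padded so regions
centered near an edge keep their nominal size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SubRegionSpec",
    "SHAPE_SPEC",
    "ORIENTATION_SPEC",
    "MatchScore",
    "extract_subregion",
    "extract_subregions",
    "phi_shape",
    "phi_orientation",
    "subregion_score",
    "template_score",
]


@dataclass(frozen=True)
class SubRegionSpec:
    """Gallery and probe window sizes, each (width, height) in pixels."""

    gallery_size: tuple[int, int]
    probe_size: tuple[int, int]

    def __post_init__(self) -> None:
        (wa, ha), (wb, hb) = self.gallery_size, self.probe_size
        if min(wa, ha, wb, hb) < 1:
            raise ValueError("sub-region sizes must be positive")
        if not (wa > wb and ha > hb):
            raise ValueError("gallery window must exceed probe window in both axes")


#: Default window sizes for the binary vein shape templates.
SHAPE_SPEC = SubRegionSpec(gallery_size=(120, 60), probe_size=(110, 50))
#: Default window sizes for the orientation-code templates.
ORIENTATION_SPEC = SubRegionSpec(gallery_size=(60, 40), probe_size=(50, 30))


@dataclass
class MatchScore:
    """Per-region mismatch fractions and their mean; all in [0, 1]."""

    per_region: np.ndarray
    total: float


def extract_subregion(template: np.ndarray, center: tuple[float, float],
                      size: tuple[int, int]) -> np.ndarray:
    """A (width, height)-sized window centered on ``center`` = (row, col).

    The center lands at index floor(size/2); parts outside the template are
    zero-padded (background).
    """
    w, h = size
    th, tw = template.shape
    if h > th or w > tw:
        raise ValueError(f"sub-region {w}x{h} larger than template {tw}x{th}")
    r0 = int(round(center[0])) - h // 2
    c0 = int(round(center[1])) - w // 2
    out = np.zeros((h, w), dtype=template.dtype)
    rs, re = max(r0, 0), min(r0 + h, th)
    cs, ce = max(c0, 0), min(c0 + w, tw)
    if rs < re and cs < ce:
        out[rs - r0:re - r0, cs - c0:ce - c0] = template[rs:re, cs:ce]
    return out


def extract_subregions(template: np.ndarray, centers, spec: SubRegionSpec,
                       role: str) -> list[np.ndarray]:
    """One window per keypoint center, sized for ``role`` ('gallery'|'probe')."""
    if role not in ("gallery", "probe"):
        raise ValueError("role must be 'gallery' or 'probe'")
    if len(centers) < 1:
        raise ValueError("need at least one sub-region center")
    size = spec.gallery_size if role == "gallery" else spec.probe_size
    return [extract_subregion(template, c, size) for c in centers]


def phi_shape(p1: int, p2: int) -> int:
    """Mismatch kernel for binary shape pixels: 1 iff |P1 - P2| = 1."""
    if p1 not in (0, 1) or p2 not in (0, 1):
        raise ValueError("shape template pixels must be binary")
    return int(abs(p1 - p2) == 1)


def phi_orientation(p1: int, p2: int) -> int:
    """Mismatch kernel for orientation codes 0..8: 1 iff P1 != P2.

    Code 0 is background; two background pixels therefore agree.
    """
    if not (0 <= p1 <= 8 and 0 <= p2 <= 8):
        raise ValueError("orientation codes must lie in 0..8")
    return int(p1 != p2)


def _validate_pair(a: np.ndarray, b: np.ndarray) -> None:
    ha, wa = a.shape
    hb, wb = b.shape
    if not (wa > wb and ha > hb):
        raise ValueError(
            f"gallery window {wa}x{ha} must exceed probe window {wb}x{hb}")


def subregion_score(a: np.ndarray, b: np.ndarray, kind: str = "shape",
                    ignore_background: bool = False) -> float:
    """Psi: minimum mismatch fraction of probe window b inside gallery window a.

    Exhaustive search over all non-negative integer offsets.  For both
    kernels the per-pixel mismatch reduces to inequality of values, so the
    window comparison is vectorized; ``ignore_background`` (orientation
    only) drops pixels where both codes are 0 from the denominator.
    """
    if kind not in ("shape", "orientation"):
        raise ValueError("kind must be 'shape' or 'orientation'")
    a = np.asarray(a)
    b = np.asarray(b)
    if kind == "shape":
        for t in (a, b):
            if not np.isin(t, (0, 1)).all():
                raise ValueError("shape templates must be binary")
    else:
        for t in (a, b):
            if t.min() < 0 or t.max() > 8:
                raise ValueError("orientation codes must lie in 0..8")
    _validate_pair(a, b)
    hb, wb = b.shape
    ha, wa = a.shape
    best = 1.0
    for y in range(ha - hb + 1):
        for x in range(wa - wb + 1):
            win = a[y:y + hb, x:x + wb]
            mism = win != b
            if ignore_background and kind == "orientation":
                valid = (win != 0) | (b != 0)
                n = int(valid.sum())
                frac = float((mism & valid).sum()) / n if n else 0.0
            else:
                frac = float(mism.sum()) / (wb * hb)
            if frac < best:
                best = frac
                if best == 0.0:
                    return 0.0
    return best


def template_score(gallery_regions: list[np.ndarray],
                   probe_regions: list[np.ndarray], kind: str = "shape",
                   ignore_background: bool = False) -> MatchScore:
    """S(A, B): mean of the per-region Psi over the k aligned sub-regions."""
    if len(gallery_regions) != len(probe_regions):
        raise ValueError("gallery and probe sub-region lists must align")
    if not gallery_regions:
        raise ValueError("need at least one sub-region pair")
    psi = np.array([
        subregion_score(a, b, kind=kind, ignore_background=ignore_background)
        for a, b in zip(gallery_regions, probe_regions)
    ])
    return MatchScore(per_region=psi, total=float(psi.mean()))
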