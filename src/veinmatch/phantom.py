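"""Synthetic finger-vein phantoms with ground truth.

Finger-vein databases are rarely redistributable, so every stage of the
pipeline is exercised on generated near-infrared-like phantoms: a smooth
bright tissue background with an illumination gradient and low-frequency
tissue texture, dark curvilinear vessels running lengthwise along the
finger, and additive sensor noise.  Vessels are rendered from random
cubic-spline centerlines with a Gaussian cross-sectional shadow whose
depth scales with vessel width (absorption grows with the blood column)
and whose spread slightly exceeds the vessel half-width (tissue
scattering).  Each phantom carries a ground-truth vessel mask (pixels
within half-width of a centerline) and a per-pixel centerline tangent
angle, used downstream as oracles for segmentation and orientation coding.

A genuine acquisition pair is emulated by moving the *geometry*, not by
resampling pixels: the centerlines are transformed by a small global rigid
motion plus a smooth random elastic displacement and the vessels are
re-rendered sharply at the new pose, over the correspondingly warped
tissue texture, with fresh sensor noise.  The illumination gradient stays
fixed to the sensor.  Ground truth for the warped phantom is therefore
exact rather than interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.spatial import cKDTree

__all__ = [
    "PhantomSpec",
    "Phantom",
    "PairTransform",
    "generate_phantom",
    "render_phantom",
    "make_genuine_pair",
    "generate_dataset",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic finger-vein image.

    Intensities are on the [0, 1] gray scale; all lengths in pixels.
    ``contrast`` is the intensity dip depth of a vessel of mean width
    (absorption scales with the blood-column width, so wider vessels are
    proportionally darker), ``scatter`` widens the Gaussian shadow beyond
    the vessel half-width to mimic tissue scattering (dip sigma =
    scatter * width / 2), ``illum_gradient`` is the total background change
    across the image width, and ``texture_amp``/``texture_scale`` control a
    smooth tissue-texture field (standard deviation / correlation length).
    """

    width: int = 221
    height: int = 83
    n_vessels: int = 4
    width_range: tuple[float, float] = (4.0, 6.0)
    contrast: float = 0.25
    noise_sd: float = 0.02
    illum_gradient: float = 0.1
    background: float = 0.7
    texture_amp: float = 0.05
    texture_scale: float = 6.0
    scatter: float = 1.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("phantom dimensions must be positive")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be >= 0")
        lo, hi = self.width_range
        if not (0 < lo <= hi):
            raise ValueError("width_range must satisfy 0 < min <= max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class Phantom:
    """A generated image with its ground truth and rendering provenance.

    ``tangent_angle`` holds the centerline tangent (radians in [0, pi),
    measured from the +column axis) on vessel pixels and NaN elsewhere.
    ``clean`` is the noise-free image; ``spec``, ``centerlines`` and
    ``texture`` record how the phantom was rendered so genuine pairs can
    be re-rendered at a new pose.
    """

    image: np.ndarray
    vessel_mask: np.ndarray
    tangent_angle: np.ndarray
    clean: np.ndarray = field(repr=False, default=None)
    spec: PhantomSpec | None = field(repr=False, default=None)
    centerlines: list = field(repr=False, default=None)
    texture: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not (self.image.shape == self.vessel_mask.shape == self.tangent_angle.shape):
            raise ValueError("phantom grids must share dimensions")
        if self.clean is None:
            self.clean = self.image.copy()
        on_mask = self.tangent_angle[self.vessel_mask.astype(bool)]
        if on_mask.size and not np.all(np.isfinite(on_mask)):
            raise ValueError("vessel pixels must carry a defined tangent angle")


@dataclass(frozen=True)
class PairTransform:
    """Global rigid motion plus local elastic warp for a genuine pair.

    The default rotation bound pi/8 is the largest rotation the
    8-direction orientation coding tolerates.
    """

    dx: float = 0.0
    dy: float = 0.0
    rotation: float = 0.0
    elastic_amplitude: float = 0.0
    elastic_scale: float = 8.0
    noise_seed: int = 0

    ROTATION_BOUND = np.pi / 8


def _noise(shape: tuple[int, int], sd: float, seed: int) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    return np.random.default_rng([int(seed), 1]).normal(0.0, sd, shape)


def _texture_field(shape: tuple[int, int], amp: float, scale: float, rng) -> np.ndarray:
    if amp == 0:
        return np.zeros(shape)
    f = gaussian_filter(rng.standard_normal(shape), scale, mode="reflect")
    s = f.std()
    return amp * f / s if s > 0 else np.zeros(shape)


def _elastic_fields(shape: tuple[int, int], t: PairTransform):
    """Smooth random (row, col) displacement fields of the given amplitude."""
    erng = np.random.default_rng([int(t.noise_seed), 2])
    out = []
    for _ in range(2):
        d = gaussian_filter(erng.standard_normal(shape), t.elastic_scale,
                            mode="reflect")
        s = d.std()
        out.append(t.elastic_amplitude * d / s if s > 0 else np.zeros(shape))
    return out


def _draw_centerlines(spec: PhantomSpec, rng) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Random cubic-spline centerlines spanning the image lengthwise.

    Veins run roughly parallel along the finger, so each vessel occupies
    its own horizontal band (stratified placement keeps vessels separated,
    as in real crops) with gentle spline meander within the band.  Returns
    per vessel: dense (col, row) sample arrays and the vessel width.
    """
    lines = []
    w, h = spec.width, spec.height
    n_knots = max(4, w // 60 + 3)
    edges = np.linspace(0.08 * h, 0.92 * h, spec.n_vessels + 1)
    for v in range(spec.n_vessels):
        lo, hi = edges[v], edges[v + 1]
        y0 = rng.uniform(lo + 0.25 * (hi - lo), hi - 0.25 * (hi - lo))
        kx = np.linspace(0.0, w - 1.0, n_knots)
        ky = np.clip(y0 + rng.normal(0.0, 0.02 * h, n_knots), 1.0, h - 2.0)
        spline = CubicSpline(kx, ky)
        xs = np.linspace(0.0, w - 1.0, 4 * w)
        lines.append((xs, spline(xs), rng.uniform(*spec.width_range)))
    return lines


def render_phantom(
    spec: PhantomSpec,
    centerlines: list[tuple[np.ndarray, np.ndarray, float]],
    rng=None,
    texture: np.ndarray | None = None,
    noise_seed: int | None = None,
) -> Phantom:
    """Render a phantom from explicit centerlines (cols, rows, width).

    Exposed separately so tests can supply analytic centerlines and so
    genuine pairs can re-render transformed geometry over a warped
    texture.
    """
    if rng is None:
        rng = np.random.default_rng([int(spec.seed), 0])
    h, w = spec.height, spec.width
    rows, cols = np.mgrid[0:h, 0:w]
    pix = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)

    if texture is None:
        texture = _texture_field((h, w), spec.texture_amp, spec.texture_scale, rng)
    img = np.full((h, w), float(spec.background)) + texture
    if spec.illum_gradient and w > 1:
        img += spec.illum_gradient * cols / (w - 1.0)

    mask = np.zeros((h, w), dtype=bool)
    tangent = np.full((h, w), np.nan)
    best_dist = np.full(h * w, np.inf)
    width_ref = float(np.mean(spec.width_range))

    for xs, ys, width in centerlines:
        pts = np.column_stack([xs, ys])
        tree = cKDTree(pts)
        dist, idx = tree.query(pix)
        # centerline tangent from finite differences along the polyline
        ang = np.mod(np.arctan2(np.gradient(ys), np.gradient(xs)), np.pi)

        sigma = spec.scatter * width / 2.0
        depth = spec.contrast * width / width_ref
        img -= (depth * np.exp(-(dist**2) / (2.0 * sigma**2))).reshape(h, w)

        vmask = dist <= width / 2.0
        closer = vmask & (dist < best_dist)
        best_dist[closer] = dist[closer]
        tangent.ravel()[closer] = ang[idx[closer]]
        mask.ravel()[vmask] = True

    clean = img
    image = clean + _noise((h, w), spec.noise_sd,
                           spec.seed if noise_seed is None else noise_seed)
    return Phantom(image=image, vessel_mask=mask, tangent_angle=tangent,
                   clean=clean, spec=spec, centerlines=list(centerlines),
                   texture=texture)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate a phantom with random spline vessels; deterministic per seed."""
    rng = np.random.default_rng([int(spec.seed), 0])
    lines = _draw_centerlines(spec, rng)
    return render_phantom(spec, lines, rng=rng)


def make_genuine_pair(
    phantom: Phantom,
    t: PairTransform,
    noise_sd: float | None = None,
    check_bounds: bool = True,
) -> Phantom:
    """Re-render a phantom as a second 'acquisition' of the same finger.

    The vessel centerlines are moved by the rigid motion plus the elastic
    displacement field and re-rendered at the new pose, so mask and
    tangent angles are recomputed exactly (angles acquire the local
    rotation and are reduced mod pi).  The tissue texture is warped along;
    the illumination gradient stays fixed to the sensor; fresh noise is
    drawn from ``t.noise_seed``.  With the identity transform and the
    source phantom's seed as noise seed the phantom is reproduced exactly.
    """
    if phantom.spec is None or phantom.centerlines is None:
        raise ValueError("phantom lacks rendering provenance (spec/centerlines)")
    if check_bounds and abs(t.rotation) > PairTransform.ROTATION_BOUND + 1e-12:
        raise ValueError("|rotation| exceeds the pi/8 orientation-coding tolerance")
    spec = phantom.spec
    h, w = spec.height, spec.width
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    cos, sin = np.cos(t.rotation), np.sin(t.rotation)
    elastic = t.elastic_amplitude != 0
    if elastic:
        drow, dcol = _elastic_fields((h, w), t)

    rigid = t.dx != 0 or t.dy != 0 or t.rotation != 0
    moved = []
    for xs, ys, width in phantom.centerlines:
        if rigid:
            xc, yc = xs - cc, ys - cr
            nx = cos * xc - sin * yc + cc + t.dx
            ny = sin * xc + cos * yc + cr + t.dy
        else:
            nx, ny = xs.copy(), ys.copy()
        if elastic:
            # displacement sampled at the source position of each point
            crd = np.stack([np.clip(ys, 0, h - 1), np.clip(xs, 0, w - 1)])
            nx = nx + map_coordinates(dcol, crd, order=1, mode="nearest")
            ny = ny + map_coordinates(drow, crd, order=1, mode="nearest")
        moved.append((nx, ny, width))

    # warp the texture with the finger (inverse mapping)
    texture = phantom.texture
    if texture is not None and (rigid or elastic):
        rows, cols = np.mgrid[0:h, 0:w].astype(float)
        tr, tc = rows - cr - t.dy, cols - cc - t.dx
        src_r = cos * tr + sin * tc + cr
        src_c = -sin * tr + cos * tc + cc
        if elastic:
            src_r = src_r - drow
            src_c = src_c - dcol
        texture = map_coordinates(texture, np.stack([src_r, src_c]),
                                  order=1, mode="reflect")

    out = render_phantom(spec, moved, texture=texture, noise_seed=t.noise_seed)
    if not out.vessel_mask.any():
        raise ValueError("warp pushed all vessels out of frame")
    if noise_sd is not None and noise_sd != spec.noise_sd:
        out.image = out.clean + _noise((h, w), noise_sd, t.noise_seed)
    return out


def generate_dataset(
    n_classes: int,
    samples_per_class: int,
    base_spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
    max_shift: float = 4.0,
    max_rotation: float = 0.05,
    elastic_amplitude: float = 1.5,
    elastic_scale: float = 10.0,
) -> list[list[Phantom]]:
    """A verification dataset: each class is one 'finger'.

    Sample 0 of a class is a freshly generated phantom; the remaining
    samples are genuine pairs derived from it with random small
    transforms.  Defaults model a guided capture device: shifts of a few
    pixels, roll within ~3 degrees (a guide slot constrains finger
    rotation far below the pi/8 coding tolerance), and a gentle elastic
    distortion from soft-tissue pressure.
    """
    rng = np.random.default_rng([int(seed), 3])
    dataset = []
    for _ in range(n_classes):
        cls_seed = int(rng.integers(0, 2**31 - 1))
        spec = PhantomSpec(**{**base_spec.__dict__, "seed": cls_seed})
        base = generate_phantom(spec)
        samples = [base]
        for _ in range(samples_per_class - 1):
            t = PairTransform(
                dx=float(rng.uniform(-max_shift, max_shift)),
                dy=float(rng.uniform(-max_shift, max_shift)),
                rotation=float(rng.uniform(-max_rotation, max_rotation)),
                elastic_amplitude=elastic_amplitude,
                elastic_scale=elastic_scale,
                noise_seed=int(rng.integers(0, 2**31 - 1)),
            )
            samples.append(make_genuine_pair(base, t))
        dataset.append(samples)
    return dataset
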