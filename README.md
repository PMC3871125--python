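# veinmatch

Finger-vein verification from multi-feature fusion: difference-curvature
vein extraction, 8-direction orientation coding, SIFT-anchored sub-region
template matching, and score-level fusion, evaluated with FAR/FRR/EER/ROC.

Finger veins are an intrinsic biometric: the pattern sits under the skin,
is hard to spoof, and is imaged by near-infrared transmission as dark
curvilinear valleys on a bright tissue background.  `veinmatch` is for
biometrics researchers and engineers who want a tested, reproducible
reference implementation of a classical multi-feature vein pipeline —
including a synthetic phantom generator with exact ground truth, so that
every stage can be exercised and benchmarked without access to any
(typically private) vein database.

## The method

For a pixel and direction θ, the curvature of the cross-sectional
intensity profile P(z) is K = |P″| / (1 + P′²)^{3/2}.  Directions are
quantized to θ_j = (j−1)π/8, j = 1..8, in perpendicular pairs
G_j = {j, j+4}, and each pixel is scored by the maximum curvature
difference

  D_max = max_j ( K_j − K_{j±4} ),

which is large on line-like vessels but small on flat regions *and* on
isotropic blobs or noise, whose orthogonal curvatures cancel.
Thresholding D_max gives the binary vein **shape** template; the argmax
index j_max gives the **orientation** code (1..8, 0 = background).

Matching is anchored on SIFT keypoints detected on the grayscale image:
each gallery keypoint is paired with its nearest probe descriptor, pairs
are ranked by the geometric distance g = √((x−x*)² + (y−y*)²) and only
the k = min(T, m) closest are kept (T = 20).  The **sift** score is the
mean retained descriptor distance.  The retained matches centre k
sub-region windows on each template (gallery window larger than probe
window); each probe window slides over all integer offsets inside its
gallery window and scores the minimum mismatch fraction Ψ ∈ [0, 1]; the
template score is the mean of the k values of Ψ.  The three scores are
z-score normalized and fused by a weighted sum or an RBF-kernel C-SVC
(γ = 0.006, C = 1.2); lower fused score = more genuine.  Verification is
evaluated by sweeping an accept threshold: EER is the rate where the
false accept and false reject rates cross.

See `docs/methods.md` for assumptions, parameter defaults, the phantom
model, and known limitations.

## Worked example

```python
from veinmatch import phantom, pipeline, RunConfig

cfg = RunConfig()
base  = phantom.generate_phantom(phantom.PhantomSpec(seed=42))
twin  = phantom.make_genuine_pair(base, phantom.PairTransform(
            dx=3.0, dy=-1.5, rotation=0.03, elastic_amplitude=1.5,
            noise_seed=7))                      # same finger, new acquisition
other = phantom.generate_phantom(phantom.PhantomSpec(seed=99))  # different finger

gallery = pipeline.extract_features(base.image, cfg)
for name, ph in [("genuine", twin), ("imposter", other)]:
    probe = pipeline.extract_features(ph.image, cfg)
    print(name, pipeline.score_pair(gallery, probe, cfg))
```

prints

```
genuine ScoreVector(sift=264.1..., shape=0.231..., orientation=0.218...)
imposter ScoreVector(sift=329.6..., shape=0.268..., orientation=0.236...)
```

All three scores are distances: the genuine comparison (same vessel
geometry, re-imaged with a small shift, roll and elastic distortion) is
closer than the imposter on every feature — a mean retained descriptor
distance of 264 vs 330, and 23% vs 27% minimum template mismatch.  Over a
whole dataset these margins compound into the EERs below.

The same pipeline is scriptable from the shell:

```sh
veinmatch fixtures --out data/ --classes 4 --samples 3 --seed 0
veinmatch match data/class000_sample00.png data/class000_sample01.png
veinmatch evaluate --out report.json
```

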