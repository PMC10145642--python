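# mmpso-s

Detection and segmentation of regions of interest (ROIs) — typically cell
nuclei — in H&E-stained histopathology images, by **multiobjective
particle-swarm multilevel thresholding fused with superpixel clustering**.

Hematoxylin renders nuclei dark purple while eosin renders cytoplasm and
stroma pink, so nuclei occupy the dark end of the grayscale histogram.
This package finds two intensity thresholds `t1 < t2` that carve the
pre-processed image into three maps and selects the darkest one as the ROI
map, then corroborates it with a color-spatial superpixel clustering of
the original RGB image.

## Method

**Threshold search.** A swarm of particles, each a candidate threshold
pair `(t1, t2)` in `[0, 255]`, maximizes three criteria simultaneously on
the 256-bin histogram with probabilities `P_i = n_i / n_p`:

- Otsu between-class variance
  `f1 = Σ_r ω_r (μ_r − μ_T)²`,
- Kapur entropy
  `f2 = Σ_r −Σ_i (P_i/ω_r) ln(P_i/ω_r)`,
- Renyi entropy of order α
  `f3 = Σ_r (1−α)⁻¹ ln Σ_i (P_i/ω_r)^α`,

where region `r` spans `[t_{r−1}, t_r − 1]`, `ω_r` is its probability
mass and `μ_r` its mean. Velocity and position follow the canonical PSO
update `V ← ωV + c1 r1 (pBest − X) + c2 r2 (L − X)`, `X ← X + V` with the
leader `L` drawn from a bounded Pareto archive via a roulette wheel biased
toward sparsely occupied hypercubes of the objective space (weight
`x / occupancy`). After the final iteration the archive member with the
largest distance `d(O, i) = √(f1² + f2² + f3²)` from the objective-space
origin yields the thresholds. The map `I1 = [0, t1−1]` is the ROI map.

**Superpixel route.** The RGB image is clustered into up to `nc`
superpixels by local k-means under `Dm = dRGB + (p/S)·dXY` with grid
spacing `S = sqrt(n_p / nc)`; clusters whose mean pre-processed intensity
falls below `t1` are kept whole as `Ithresh`.

**Fusion.** `Imerge = I1 ∪ Ithresh` is hole-filled, smoothed by
morphological opening-then-closing, and stripped of small components.

## Worked example

```python
from mmpso_s import (FixtureSpec, SwarmConfig, SuperpixelConfig,
                     make_nuclei_image, run_pipeline, segmentation_metrics)

img, gt, centres = make_nuclei_image(FixtureSpec(seed=0))   # 160x160 synthetic H&E
mask, report = run_pipeline(img, SwarmConfig(seed=0), SuperpixelConfig(nc=711))
print("thresholds:", report.t1, report.t2)
print("superpixels:", report.nc_actual)
print("dice: %.3f" % segmentation_metrics(mask, gt).dice)
```

prints

```
thresholds: 116 204
superpixels: 676
dice: 0.994
```

i.e. the swarm placed the dark/ROI cutoff at intensity 116 (between the
nucleus mode ~70 and the background mode ~185 after contrast enhancement),
the clustering produced 676 of the 711 requested superpixels, and the
final mask overlaps the ground truth with Dice 0.994.

The same pipeline runs from the shell:

```
mmpso-s make-fixtures --out fx --n 5 --seed 0
mmpso-s segment --input fx/images/fixture_000.png --output mask.png --seed 0
mmpso-s evaluate --pred-dir preds/ --gt-dir fx/masks/ --out metrics.csv
```

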