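# Methods

## Problem and model

The package segments dark regions of interest (nuclei, immune cells) in
H&E-stained histopathology images. The model is a two-route pipeline:

1. **Multilevel thresholding by multiobjective PSO.** The pre-processed
   grayscale image `Ipre` is summarized by its 256-bin histogram. A
   threshold vector `t1 < t2` partitions the gray range into regions
   `[0, t1−1]`, `[t1, t2−1]`, `[t2, 255]` (half-open on thresholds; the
   first map is the ROI map because hematoxylin-stained nuclei are
   darker than the eosin background). Three criteria are maximized
   jointly: Otsu's between-class variance, Kapur's entropy and Renyi's
   entropy of order α. Empty regions contribute 0 to every criterion so
   the search space stays total while the swarm explores degenerate
   vectors.
2. **Superpixel clustering.** Local k-means in `[R, G, B, X, Y]` with
   distance `Dm = dRGB + (p/S)·dXY`, grid spacing `S = sqrt(n_p/nc)`,
   and a 2S × 2S search window per center. Clusters with mean `Ipre`
   intensity below `t1` are kept whole; the union with the thresholded
   map is post-processed morphologically.

## Swarm engine

Particles hold real-valued positions in `[0, 255]²` (rounded to integer
thresholds only for fitness evaluation and final extraction) and
velocities clamped to `[−5, 5]`. The velocity update is the canonical
attractive form `V ← ωV + c1 r1 (pBest − X) + c2 r2 (L − X)`; position
components are re-sorted after every move so the pair remains a valid
threshold vector. Personal bests follow Pareto dominance, with mutual
non-dominance resolved by a fair coin from the run RNG.

The external archive keeps at most `Amax` mutually non-dominated
solutions. Its occupied fitness bounding box is cut into `Gsize`
divisions per objective; the adaptive grid is rebuilt whenever
membership changes. Leaders are selected by roulette over occupied
hypercubes with weight `x / occupancy` (`x = 10`; the roulette is
invariant to `x` up to normalization), then uniformly within the cube.
When a non-dominated candidate arrives at a full archive, one member of
the most crowded cube — the newest, a deterministic choice — is evicted.

The mutation operator follows the decreasing non-uniform schedule
`pm(t) = (1 − (t−1)/(Nite−1))^(5/μ)`: at `t = 1` every particle is
eligible, at `t = Nite` none. A mutated particle has one position
component redrawn uniformly in a window of half-width
`pm · (Xmax − Xmin)/2` around its current value, clamped to bounds.

The final thresholds come from the archive member maximizing the
Euclidean distance `d(O, i) = ||f_i||` of its fitness vector from the
objective-space origin (ties by first index).

### Plateau tie-break

All three criteria are piecewise constant in a threshold: moving a
threshold across a zero-count intensity level changes no region mass and
therefore no objective value. On images with well-separated intensity
populations the histogram has long empty runs between modes, and every
threshold inside such a run is exactly equally optimal. At extraction,
each threshold is therefore centred on its run of empty bins — the
classical valley-centred tie-break. This makes the output well defined
(and close to the analytic mixture valley on synthetic mixtures) instead
of an arbitrary point of the plateau determined by swarm history. On
dense histograms the rule is a no-op.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_particles` | 150 | swarm size |
| `n_iterations` | 150 | iterative-phase length (loop runs while `t < Nite`) |
| `n_thresholds` | 2 | `k`; three maps, the darkest is the ROI map |
| `inertia`, `c1`, `c2` | 1.3, 0.5, 0.5 | PSO coefficients |
| `mutation_rate` | 0.1 | μ in the mutation schedule |
| `archive_max` | 30 | Pareto archive capacity |
| `grid_size` | 7 | hypercube divisions per objective |
| `alpha` | 2 | Renyi order (quadratic entropy); any α > 0, α ≠ 1 |
| position / velocity bounds | [0, 255] / [−5, 5] | search space |
| `nc` | 1000 | requested superpixels (WSI-scale density, ≈ `n_p`/36 px per cluster for typical inputs) |
| `compactness` (p) | 10 | spatial weight on a 0–255 color scale |
| `max_iter`, `e_tol` | 10, 1.0 | superpixel stopping rule |
| `min_roi_area` | 30 px | post-processing component floor |
| `smooth_radius` | 2 px | opening/closing disk radius |
| CLAHE `clip_limit`, `tile_grid` | 0.01, 8×8 | contrast enhancement |

α, the CLAHE settings, `p`, `e_tol`, `max_iter` and both post-processing
sizes are library defaults in the absence of a canonical value; each is
exposed in the config and the threshold search adapts to whatever
histogram CLAHE produces, so results depend on them only weakly.

## Numerical choices

- Grayscale uses BT.601 weights (0.299/0.587/0.114), rounded and
  clamped; conversion is idempotent on gray inputs.
- Objective evaluation is O(k) per vector via cumulative-sum tables
  (`Σ P`, `Σ iP`, `Σ P ln P`, `Σ P^α`), which also vectorizes across the
  swarm.
- Positions saturate at the bounds (no reflection); `x1 ≤ x2` is
  maintained by sorting after every update.
- Superpixel spacing uses `S = sqrt(n_p/nc)` — the quantity `n_p/nc` is
  a pixel count, and the grid distance is its square root.
- Empty superpixel clusters are dropped (hence `nc′ ≤ nc`); final
  centers are recomputed as exact member means, labels compacted to
  `[1, nc′]`. No connectivity enforcement pass is applied.
- Hole filling floods the 4-connected background (the dual of
  8-connected foreground, so a 1-px wall still encloses a hole);
  components use 8-connectivity throughout.
- Degenerate single-intensity images raise an error from the threshold
  search: no meaningful thresholds exist.
- One `numpy.random.Generator`, seeded once per run, drives swarm
  initialization, `r1`/`r2`, pBest coin flips, leader roulette, mutation
  and fixture synthesis; identical seeds give byte-identical masks.

## Synthetic data

`make_nuclei_image` emulates the structure the pipeline exploits:
non-overlapping dark ellipses (luminance mode 70 ± 6) tinted purple on a
brighter pink background (mode 185 ± 6) with additive Gaussian RGB noise
(σ = 4), at 160 × 160 by default — high-contrast, bimodal, with exact
masks and centre lists. `make_trimodal_image` draws i.i.d. pixels from a
three-component Gaussian mixture (default modes 40/128/215, σ = 8, equal
weights) and returns the analytic decision boundaries (84 and 171.5 for
the defaults, solved generally by root-finding on the weighted density
difference) as recovery targets.

What the generator does **not** emulate: stain variability and overlap,
texture inside nuclei and stroma, touching/overlapping nuclei, blur,
tissue folds, and the scale of whole-slide images. Passing tests
demonstrate the algorithmic contracts (oracle equivalence, archive
integrity, partition identities, recovery of known mixture structure)
and end-to-end behaviour under the intended polarity — not clinical
performance on real H&E slides.

## Problem sizes

Default test and reproduction sizes: 160 × 160 fixtures with 25 nuclei;
`nc` scaled to image area at ≈ 36 px per superpixel; 10 seeds for each
oracle-equivalence and recovery experiment; 5 images for end-to-end
quality. The swarm runs at its full 150 × 150 operating point in all
acceptance experiments.

## Known limitations

- Touching nuclei merge into single components (no instance splitting);
  this depresses detection F-measure relative to segmentation Dice.
- `k > 2` is supported by the types but untuned; the pipeline consumes
  the first and last thresholds only.
- The superpixel stage operates in RGB, not CIELAB; distances are not
  perceptually uniform.
- On histograms with no empty runs and genuinely multimodal structure,
  the three criteria can disagree; the distance-from-origin compromise
  is dominated by the largest-magnitude objective (Otsu variance, which
  is numerically far larger than the entropies).
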