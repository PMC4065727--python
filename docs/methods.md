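# Methods

## The cumulative-grayscale depth model

The analysis treats a single secondary-electron micrograph of a fibrous
mat as a depth-coded image: fibers near the imaged surface are bright,
deeper fibers darker, the open background darkest.  Under that
assumption the set of pixels at or above a gray level *x* is the
projection of all material down to "depth" *x*, and the layered porosity

P_xb = 100 · (1 − S(x)/N),  with S(x) = Σ_{g ≥ x} t(g),

is the percent open area of the cumulative layer [x, b].  The discrete
convention is fixed as: pixels at exactly level *x* count as solid, the
histogram supremum *b* and infimum *a* are the highest/lowest occupied
levels, and the profile therefore ends at exactly 0 at *x* = *a*.  This
makes P_xb identical to direct pixel counting — an invariant the test
suite asserts exactly, with no floating tolerance.

The model is 2D throughout: "depth" is an intensity ordering, not a
reconstructed z-coordinate, and occlusion by shallower fibers is
irreversible (nothing below a bright fiber is visible).  This matches
what a single micrograph can support; tomography is out of scope.

### Layer scheme

Layers are placed at thresholds μ + kσ of the intensity histogram (μ, σ
population convention), with max(1, n−2) consecutive integers k centered
on zero (biased toward +σ when that count is even), clipped into (a, b],
deduplicated, and closed with the terminal threshold *a* so the deepest
cumulative layer spans the full occupied range.  The default n = 7
yields {μ+2σ, μ+σ, μ, μ−σ, μ−2σ, a}.  When clipping removes thresholds
(very wide σ), the scheme carries the reduced count and a `reduced`
flag rather than inventing thresholds.  A constant image (σ = 0) has no
depth structure and is rejected with an explicit error.

### Interconnectivity and SPE

Layered porosity is regressed on layer index 1…n (surface → depth) by
ordinary least squares.  The regression abscissa is the *index*, not the
raw threshold, so the blocking rate H = |slope| (percent open area lost
per layer) is comparable across images with different μ and σ.  The
interconnectivity index is 1/H: fast blocking ⇒ low interconnectivity.
Below a guard of 1e−9 on H, 1/H and SPE are reported undefined instead
of astronomically large.  SPE = P(percent)/H has units of layers; Pearson
correlations downstream are invariant to this unit choice.

## Projection measurements

**Binarization.**  Two masks are computed, reflecting what each
measurement means physically:

* the *projection* mask (overall porosity, pore sizing) should include
  fibers at every depth.  Its default threshold is minimum cross-entropy
  (Li), which does not assume a bimodal histogram; the depth-coded solid
  class deliberately spans several gray levels, and a between-class
  variance criterion (Otsu) then places its cut inside the fiber class,
  misclassifying the deepest fibers as pore.
* the *fiber-width* mask uses Otsu, which isolates the bright, in-focus
  surface fibers — the fibers whose widths are actually resolvable,
  and the ones an operator would caliper manually.  At an inclusive
  threshold, blur halos of bright fibers fill small pores and inflate
  apparent widths.

Both masks use solid = level ≥ threshold (fibers brighter than
background; an `invert` flag handles the opposite contrast), and a
`fixed(level)` override is available for both.  The in-package Otsu
maximizes between-class variance over all 256 candidate levels with ties
broken toward the lower threshold, making the threshold a deterministic
function of the histogram.

**Overall porosity** is the pore-area fraction of the projection mask.

**Pores** are 4-connected components of the pore phase (solid is
implicitly 8-connected — the standard duality).  Components under
5 px are treated as noise; components touching the frame border are
censored by the field of view and excluded from Feret statistics by
default.  The maximum Feret diameter is the longest distance between
boundary-pixel centers, computed by convex hull plus rotating calipers in
integer arithmetic, and is exactly equal to the all-pairs brute force
(asserted to 1e−9 in tests).  Note a pixel-center subtlety: upscaling a
mask by an integer factor s maps a diameter d to the interval
[s·d, s·d + (s−1)·√2], not exactly s·d (a single pixel has diameter 0,
its s×s upscaling does not).

**Fiber diameters** replace the manual 100-caliper protocol: the solid
phase is thinned (Zhang–Suen skeletonization), skeleton pixels within
2 px of a branch point or a skeleton endpoint are discarded (junctions
inflate the local width, ridge ends under-measure it), and at 100
randomly sampled surviving centerline pixels the local diameter is
2·EDT − 1 (EDT = Euclidean distance to the nearest pore-pixel center),
a convention under which a w-pixel straight band measures exactly w.
Thinning was chosen over the true medial axis because the medial axis
sprouts spurs at staircase boundaries (it fails scale-covariance on
upscaled masks by ~2×) and its library implementation breaks thinning
ties randomly.  Sampling is seeded; if fewer candidate pixels exist than
requested, sampling is with replacement and flagged.

Calibration (nm per pixel) is a user-supplied configuration number; no
scale-bar detection is attempted.  Pixel/nm statistics use the sample
(ddof = 1) standard deviation.

## Synthetic mats

The generator emulates the depth-coded imaging regime directly: straight
fibers (locally straight is adequate at high magnification) with
uniformly random orientation through a uniformly random in-frame point,
diameters drawn Normal(mean, sd) truncated at 1 px, rasterized as bands
of width d via |distance to axis| ≤ (d−1)/2 in pixel centers.  Fibers
are deposited in n depth layers and painted deepest-first so shallower
fibers occlude deeper ones; each layer has a fixed mean gray level
strictly decreasing with depth.  Gaussian blur then clipped additive
Gaussian noise complete the imaging model.  Ground truth (per-layer
cumulative coverage, porosity, realized diameters) is recorded *before*
blur and noise.

Defaults describe a packed nanofibrous mat at high magnification:
512 × 512 px, 7 layers at levels 230 → 110 (step −20) over background 30,
fiber diameter 8 ± 1 px, blur σ = 1 px, noise σ = 5 levels, and a target
projected coverage of 0.70 (porosity ≈ 0.30, the packed end of the
0.11–0.32 range typical of electrospun chitosan/PEO mats).  With a
coverage target, fibers are added round-robin across layers until the
union coverage first reaches the target; targets above 0.99 are rejected.

What the generator does **not** emulate: fiber curvature, charging and
shading artifacts, depth-of-field defocus gradients, beads or other
spinning defects, and non-Gaussian detector noise.  Passing recovery
tests therefore demonstrates the measurement pipeline is unbiased under
the stated imaging model, not that it is robust to every real-world
artifact.

The default multi-sample study (the `run` pipeline) sweeps eleven mats
from fine to coarse along the electrospinning trend — fiber diameter
rising 5 → 12 px while packing rises (coverage 0.55 → 0.80, porosity
falling) — because in practice thicker-fiber process settings also
produce denser, lower-porosity mats.

## Viability simulation and comparative statistics

Relative viability is scored per replicate as 100 · A_i / mean(control),
summarized by mean and sample sd over the three replicates.  The
generator draws replicate absorbances control_mean · latent/100 + ε with
latent viability linear in standardized structural metrics
(intercept 80% of control, matching mid-range viability of
non-cytotoxic scaffolds; absorbances floored at 1e−6).  A linear model is
the simplest generator whose correlation *sign* structure is
controllable, and sign structure is what the comparative stage tests.

`sample_structural_metrics` draws plausible per-sample metric tables on
realistic ranges (fiber 170–320 nm, pore 330–790 nm, porosity fraction
0.32 → 0.11, 1/H 0.04 → 0.06, SPE = P·100/H consistent by construction)
with the electrospinning trend structure encoded: fiber and pore size
rise together, porosity falls, and SPE falls because the porosity decline
dominates the 1/H rise.

Each metric is correlated with mean relative viability by Pearson's r;
significance per metric uses the correlation t-test (df = n − 2,
two-sided), the reading of a per-metric "unpaired Student's t between
relative absorbance and each structural element" that actually yields one
p-value per metric.  A plain pooled-variance two-group t-test
(`student_t_unpaired`, df = n₁+n₂−2) is exposed for direct group
comparisons, and the report labels which method was used.  The cutoff
defaults to p < 0.001 and no multiple-testing correction is applied (the
report says so).  Degenerate inputs — constant metrics, zero-variance
groups, flat porosity profiles — are flagged (NaN / `defined=False` /
exact (0, 1) outcomes) rather than raised mid-analysis.

## Determinism and problem sizes

Every stochastic component (fiber placement, noise, skeleton sampling,
viability noise) is driven by an explicit seed; pipeline stages derive
their seeds from the master seed, and rerunning `nanomat run` with the
same config and seed reproduces every CSV byte-for-byte (config hash and
seed are stamped in each output header).  The validation studies use
five 512² renders for parameter recovery and twenty 11-sample studies
for sign recovery — small enough to run in seconds while leaving the
recovery estimates' Monte-Carlo error well below the tolerances tested.

## Known limitations

* The depth model is ordinal: layered porosity quantifies *blocking*
  with depth, not metric layer thickness.
* Absolute porosity from a binarized projection depends on the threshold
  convention when edges are blurred; the ±0.01 recovery observed on
  synthetic mats should not be read as an absolute-accuracy claim for
  real micrographs with charging or gamma adjustments.
* Feret sizing of border-touching pores is censored (excluded by
  default); dense mats with few interior pores yield small-n pore
  statistics.
* The skeleton width estimator reports merged fiber bundles as single
  thick fibers when fibers run parallel in contact.
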