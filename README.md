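# nanomat

Depth-profile structural characterization of electrospun nanofibrous
scaffolds from single grayscale micrographs, plus the comparative
statistics that relate those structural metrics to cell viability.

Nonwoven nanofiber mats (e.g. electrospun chitosan/PEO) are standard
tissue-engineering scaffolds, and how cells infiltrate and survive on
them depends on structural properties that are tedious to quantify:
porosity, pore size, how quickly open channels close up with depth
(interconnectivity), and fiber diameter.  A single secondary-electron
micrograph encodes depth in brightness — surface fibers image bright,
deeper fibers darker — so the depth profile can be read off the intensity
histogram without tomography.  `nanomat` implements that analysis, a
synthetic micrograph generator with known ground truth to validate every
stage, and the structure-viability correlation report.

## The model

For a micrograph with differential intensity histogram *t*(*g*) occupied
on [*a*, *b*] (total *N* pixels), the **layered porosity** of the
cumulative layer reaching gray depth *x* is

    P_xb = 100 · (1 − S(x)/N),       S(x) = Σ_{g ≥ x} t(g),

the percent open area once every fiber at level *x* or brighter counts as
solid.  Thresholds *μ* ± *kσ* of the histogram (defaults: *k* = 2, 1, 0,
−1, −2, then the terminal *a*) define a seven-layer scheme; regressing
P_xb on layer index gives the **blocking rate** *H* (percent open area
lost per layer, the magnitude of the fitted slope).  Its reciprocal 1/*H*
is the **interconnectivity index**, and the **scaffold percolative
efficiency** is

    SPE = P(percent) / H        (units: layers),

combining total open volume with channel openness.  Planar measures come
from binarized projections: overall porosity *P* is the pore-area
fraction, pore size is each pore region's **maximum Feret diameter**
(longest boundary-to-boundary distance, convex hull + rotating calipers),
and fiber diameters are measured automatically along the skeleton of the
solid phase as 2·EDT − 1 at sampled centerline pixels.

The comparative stage scores MTT-assay viability relative to a
scaffold-free control (percent of control absorbance) and correlates each
structural metric with mean relative viability; per-metric significance
uses the t-test of the Pearson coefficient, *t* = *r*·√((*n*−2)/(1−*r*²)),
at a *p* < 0.001 cutoff.

## Worked example

```python
import nanomat as nm

# a synthetic mat with known ground truth (true porosity 0.2969)
img, truth = nm.render_mat(nm.default_mat_spec(seed=0))
res = nm.ScaffoldModel(img, sample_id="demo").fit()
print(res.summary())
```

```
Scaffold structural characterization — sample demo
  image: 512 x 512 px, projection threshold 94, fiber threshold 122
  overall porosity P        : 0.2861 (28.61%)
  blocking rate H           : 26.2529 %/layer (r^2 = 0.9800)
  interconnectivity 1/H     : 0.03809
  percolative efficiency SPE: 1.0897 layers
  pore max-Feret (462 pores): 15.8 +/- 11.3 px
  fiber diameter (100 meas.): 8.99 +/- 3.92 px
  layered porosity profile (threshold -> P_xb %):
      207.07 ->  81.02
      138.09 ->  43.54
       69.11 ->  24.07
        9.00 ->   0.00
```

The measured porosity 0.286 recovers the renderer's truth 0.297 to about
0.01, and the 8.99 px fiber estimate recovers the generating 8 px
diameter.  The profile drops from 81% open at the surface layer to 0 at
the full depth interval; its slope magnitude is *H*.

Correlating structure with simulated viability across an 11-sample study:

```python
m  = nm.sample_structural_metrics(11, seed=0)
vt = nm.simulate_viability(m, {"fiber_mean": 4, "pore_mean": 4,
                               "P": -4, "SPE": -4}, seed=1)
print(nm.StructureViabilityModel(m, vt).fit().summary())
```

```
metric                            r         t           p  significant
fiber_mean                   0.9916    22.945   2.695e-09  yes
pore_mean                    0.9976    43.350   9.235e-12  yes
P                           -0.9912   -22.510   3.193e-09  yes
interconnectivity_index      0.9520     9.328   6.365e-06  yes
SPE                         -0.9690   -11.772   9.066e-07  yes
```

Coarser-fiber, larger-pore mats correlate positively with viability while
overall porosity and percolative efficiency correlate negatively — the
expected pattern for packed electrospun mats, where low interconnectivity
mats present more attachment area in their surface layers.

## Command line

```sh
nanomat run --seed 3 --out out/          # simulate + analyze + compare
nanomat analyze mat.png --out out/       # structural metrics for an image
nanomat compare --metrics out/structural_summary.csv \
                --viability out/viability.csv --out out/
```

All outputs are CSV with a config-hash header; reruns with the same
config and seed are bit-identical.

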