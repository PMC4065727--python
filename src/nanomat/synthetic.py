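"""Synthetic fibrous-mat micrographs and viability tables with ground truth.

Electrospun mats imaged by secondary electrons show bright fibers near the
surface and progressively darker fibers at depth.  The renderer emulates
that regime directly: straight fibers of normally distributed diameter are
deposited in depth layers, painted deepest-first so shallower fibers
occlude deeper ones, each layer at a fixed mean gray level decreasing with
depth; optical blur and detector noise are applied last.  True per-layer
coverage, porosity, and fiber diameters are recorded *before* blur/noise,
so every measurement stage can be tested against known ground truth.

The viability generator closes the loop for the comparative statistics: a
latent viability that is linear in standardized structural metrics is
converted into MTT-style replicate absorbances against a control, with
seeded Gaussian noise.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import GrayscaleImage

__all__ = [
    "MatSpec",
    "MatGroundTruth",
    "ViabilityTable",
    "render_mat",
    "default_mat_spec",
    "simulate_viability",
    "sample_structural_metrics",
    "METRIC_COLUMNS",
]

#: Structural metrics carried into the comparative analysis.
METRIC_COLUMNS = ("fiber_mean", "pore_mean", "P", "interconnectivity_index", "SPE")


@dataclass(frozen=True)
class MatSpec:
    """Rendering recipe for one synthetic mat field.

    Exactly one of ``fibers_per_layer`` and ``target_coverage`` must be
    given; with a target coverage, fibers are added round-robin across
    layers until the projected (union) coverage first reaches the target.
    Defaults mirror a packed nanofibrous mat at high magnification:
    512 x 512 px, seven depth layers whose mean levels fall from 230 at the
    surface to 110 at depth, fibers 8 +/- 1 px wide over a level-30
    background, 1 px optical blur and sd-5 detector noise.
    """

    width: int = 512
    height: int = 512
    n_depth_layers: int = 7
    fibers_per_layer: int | None = None
    target_coverage: float | None = None
    fiber_diameter_mean: float = 8.0
    fiber_diameter_sd: float = 1.0
    layer_intensities: tuple[int, ...] = (230, 210, 190, 170, 150, 130, 110)
    background_level: int = 30
    blur_sigma: float = 1.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("frame must be at least 1x1")
        if (self.fibers_per_layer is None) == (self.target_coverage is None):
            raise ValueError(
                "exactly one of fibers_per_layer and target_coverage is required"
            )
        if self.target_coverage is not None and self.target_coverage > 0.99:
            raise ValueError("target_coverage above 0.99 is unreachable")
        li = tuple(self.layer_intensities)
        if len(li) != self.n_depth_layers:
            raise ValueError("layer_intensities must match n_depth_layers")
        if any(li[i] <= li[i + 1] for i in range(len(li) - 1)):
            raise ValueError("layer intensities must strictly decrease with depth")
        if not all(0 <= v <= 255 for v in li) or not 0 <= self.background_level <= 255:
            raise ValueError("intensity levels must lie in [0, 255]")
        if self.fiber_diameter_mean <= 0:
            raise ValueError("fiber_diameter_mean must be positive")
        object.__setattr__(self, "layer_intensities", li)


@dataclass(frozen=True)
class MatGroundTruth:
    """Renderer-side truth recorded before blur and noise."""

    per_layer_cumulative_coverage: tuple[float, ...]
    true_porosity: float
    true_diameters: tuple[float, ...]
    seed: int

    def to_dict(self) -> dict:
        return {
            "per_layer_cumulative_coverage": list(self.per_layer_cumulative_coverage),
            "true_porosity": self.true_porosity,
            "true_diameters": list(self.true_diameters),
            "seed": self.seed,
        }


@dataclass(frozen=True)
class ViabilityTable:
    """MTT-style replicate absorbances per sample, with control replicates."""

    frame: pd.DataFrame  # sample_id, abs_1..3, ctrl_1..3

    def __post_init__(self) -> None:
        cols = ["sample_id", "abs_1", "abs_2", "abs_3", "ctrl_1", "ctrl_2", "ctrl_3"]
        if list(self.frame.columns) != cols:
            raise ValueError(f"viability table must have columns {cols}")
        if (self.frame[cols[1:]] <= 0).any().any():
            raise ValueError("absorbances must be positive")


def default_mat_spec(seed: int = 0, target_coverage: float = 0.7, **overrides) -> MatSpec:
    """The package's default synthetic fixture (see module docstring)."""
    return MatSpec(seed=seed, target_coverage=target_coverage, **overrides)


def _fiber_mask(shape: tuple[int, int], row0: float, col0: float,
                theta: float, diameter: float) -> np.ndarray:
    """Rasterize a straight fiber crossing the frame as a constant-width band.

    A pixel is covered when its center lies within (diameter-1)/2 of the
    fiber axis, so an axis-aligned fiber through a row of pixel centers is
    exactly ``diameter`` pixels wide.
    """
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    # unit normal to the axis direction (cos t, sin t) in (row, col) coords
    n_r, n_c = -np.sin(theta), np.cos(theta)
    dist = np.abs((rr - row0) * n_c - (cc - col0) * n_r)
    return dist <= (diameter - 1.0) / 2.0


def render_mat(spec: MatSpec) -> tuple[GrayscaleImage, MatGroundTruth]:
    """Render a depth-layered fibrous mat and its ground truth.

    Fibers have uniformly random orientation and pass through a uniformly
    random in-frame point; diameters are normal, truncated at 1 px.
    Layers are painted deepest-first (painter's algorithm) so shallower
    fibers occlude deeper ones; blur and clipped additive Gaussian noise
    follow, driven by the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    n_layers = spec.n_depth_layers
    layer_masks = [np.zeros(shape, dtype=bool) for _ in range(n_layers)]
    diameters: list[float] = []
    union = np.zeros(shape, dtype=bool)

    def add_fiber(layer: int) -> None:
        theta = rng.uniform(0.0, np.pi)
        row0 = rng.uniform(0, spec.height - 1) if spec.height > 1 else 0.0
        col0 = rng.uniform(0, spec.width - 1) if spec.width > 1 else 0.0
        d = max(1.0, rng.normal(spec.fiber_diameter_mean, spec.fiber_diameter_sd))
        diameters.append(d)
        fm = _fiber_mask(shape, row0, col0, theta, d)
        layer_masks[layer] |= fm
        np.logical_or(union, fm, out=union)

    if spec.fibers_per_layer is not None:
        for layer in range(n_layers):
            for _ in range(spec.fibers_per_layer):
                add_fiber(layer)
    else:
        i = 0
        max_fibers = 100_000  # safety valve; coverage targets <= 0.99 converge long before
        while union.mean() < spec.target_coverage:
            add_fiber(i % n_layers)
            i += 1
            if i >= max_fibers:  # pragma: no cover
                raise RuntimeError("target coverage not reached")

    cumulative = []
    acc = np.zeros(shape, dtype=bool)
    for layer in range(n_layers):  # surface (0) downward
        acc |= layer_masks[layer]
        cumulative.append(float(acc.mean()))
    truth = MatGroundTruth(
        per_layer_cumulative_coverage=tuple(cumulative),
        true_porosity=1.0 - cumulative[-1],
        true_diameters=tuple(diameters),
        seed=spec.seed,
    )

    img = np.full(shape, float(spec.background_level))
    for layer in range(n_layers - 1, -1, -1):  # deepest first
        img[layer_masks[layer]] = float(spec.layer_intensities[layer])
    if spec.blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(img, sigma=spec.blur_sigma)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=shape)
    pixels = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return (
        GrayscaleImage(pixels=pixels, source_id=f"synthetic-mat-seed{spec.seed}"),
        truth,
    )


# ---------------------------------------------------------------------------
# structural metric tables and viability
# ---------------------------------------------------------------------------


def sample_structural_metrics(n_samples: int = 11, seed: int = 0) -> pd.DataFrame:
    """Draw a plausible per-sample structural metric table.

    Encodes the trend structure of electrospun mats over the ranges
    typical of chitosan/PEO nanofiber scaffolds: as fiber diameter grows
    from ~170 to ~320 nm, pore size grows (~330-790 nm), overall porosity
    falls (~0.32 -> ~0.11), reciprocal interconnectivity 1/H rises, and
    SPE = P(percent)/H falls because the porosity decline dominates.
    Small Gaussian perturbations keep the metrics from being exactly
    collinear.  Indexed by sample_id.
    """
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.0, 1.0, size=n_samples)  # latent fineness->coarseness axis
    fiber = 170.0 + 150.0 * f + rng.normal(0, 6.0, n_samples)
    pore = 330.0 + 460.0 * f + rng.normal(0, 25.0, n_samples)
    P = np.clip(0.32 - 0.21 * f + rng.normal(0, 0.012, n_samples), 0.02, 0.6)
    inv_h = np.clip(0.040 + 0.020 * f + rng.normal(0, 0.0015, n_samples), 1e-3, None)
    spe = 100.0 * P * inv_h  # == P(percent) / H
    frame = pd.DataFrame(
        {
            "fiber_mean": fiber,
            "pore_mean": pore,
            "P": P,
            "interconnectivity_index": inv_h,
            "SPE": spe,
        },
        index=pd.Index([f"S{i + 1:02d}" for i in range(n_samples)], name="sample_id"),
    )
    return frame


def _metrics_frame(metrics) -> pd.DataFrame:
    """Accept a metric DataFrame or a list of StructuralSummary objects."""
    if isinstance(metrics, pd.DataFrame):
        missing = [c for c in METRIC_COLUMNS if c not in metrics.columns]
        if missing:
            raise ValueError(f"metric table lacks columns {missing}")
        return metrics[list(METRIC_COLUMNS)]
    rows = {}
    for s in metrics:
        rows[s.sample_id] = {
            "fiber_mean": s.fiber_stats.mean,
            "pore_mean": s.pore_stats.mean,
            "P": s.P_fraction,
            "interconnectivity_index": s.fit.interconnectivity_index,
            "SPE": s.SPE,
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sample_id"
    return frame[list(METRIC_COLUMNS)]


def simulate_viability(
    metrics,
    coefficients: Mapping[str, float],
    noise_sd: float = 0.01,
    control_mean: float = 0.5,
    seed: int = 0,
    intercept: float = 80.0,
) -> ViabilityTable:
    """Generate MTT-style replicate absorbances from structural metrics.

    Latent viability (percent of control) is linear in the standardized
    metrics: ``intercept + sum_m w_m * z_m``.  Each sample receives three
    replicate absorbances ``control_mean * latent/100 + N(0, noise_sd)``;
    three control replicates are ``control_mean + N(0, noise_sd)``.
    Absorbances are floored at 1e-6 to remain physical.

    ``metrics`` is a DataFrame indexed by sample_id with columns
    fiber_mean, pore_mean, P, interconnectivity_index, SPE — or a list of
    StructuralSummary objects.  Coefficient keys must be a subset of those
    columns; the caller chooses the signs.
    """
    if control_mean <= 0:
        raise ValueError("control_mean must be positive")
    frame = _metrics_frame(metrics)
    if len(frame) < 2:
        raise ValueError("viability simulation needs at least 2 samples")
    unknown = [k for k in coefficients if k not in METRIC_COLUMNS]
    if unknown:
        raise ValueError(f"unknown metric keys in coefficients: {unknown}")
    rng = np.random.default_rng(seed)
    latent = np.full(len(frame), float(intercept))
    for key, weight in coefficients.items():
        col = frame[key].to_numpy(dtype=float)
        sd = col.std()
        if sd > 0:
            latent = latent + weight * (col - col.mean()) / sd
    rows = []
    controls = np.maximum(control_mean + rng.normal(0, noise_sd, 3), 1e-6)
    for sid, lat in zip(frame.index, latent):
        reps = np.maximum(
            control_mean * lat / 100.0 + rng.normal(0, noise_sd, 3), 1e-6
        )
        rows.append([sid, *reps, *controls])
    table = pd.DataFrame(
        rows, columns=["sample_id", "abs_1", "abs_2", "abs_3", "ctrl_1", "ctrl_2", "ctrl_3"]
    )
    return ViabilityTable(frame=table)
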