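"""Depth-profile structural characterization of fibrous-mat micrographs.

The mat is treated as a stack of cumulative grayscale layers: brighter
pixels are fibers closer to the imaged surface.  From the differential
intensity histogram t(g) of a micrograph with occupied range [a, b], the
layered porosity of the cumulative layer reaching gray depth x is

    P_xb = 100 * (1 - S(x) / N),        S(x) = sum_{g >= x} t(g),

the percent open area once every fiber at level x or brighter is treated
as solid.  Thresholding the image at mu +/- k*sigma produces a small set
of physically comparable layers; regressing P_xb on layer index gives the
blocking rate H (percent open area lost per layer), whose reciprocal 1/H
is the interconnectivity index, and the scaffold percolative efficiency
is SPE = P(percent) / H, combining open volume with channel openness.

Planar measurements come from a binarized projection of the fiber
network: overall porosity P is the pore-phase area fraction, pore size is
the maximum Feret diameter of each pore region, and fiber diameters are
read off the medial-axis skeleton via the Euclidean distance transform.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .imaging import GrayscaleImage, IntensityHistogram, intensity_histogram

__all__ = [
    "LayerScheme",
    "LayeredPorosityProfile",
    "InterconnectivityFit",
    "BinaryMask",
    "PoreRegion",
    "MeasurementStats",
    "DiameterStats",
    "StructuralSummary",
    "layered_porosity",
    "build_layer_scheme",
    "porosity_profile",
    "interconnectivity",
    "otsu_threshold",
    "binarize",
    "overall_porosity",
    "segment_pores",
    "max_feret",
    "fiber_diameters",
    "structural_summary",
]

#: Slopes below this magnitude are treated as zero blocking rate; 1/H and
#: SPE are reported undefined instead of astronomically large.
H_GUARD = 1e-9


# ---------------------------------------------------------------------------
# layered porosity (histogram depth profile)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LayerScheme:
    """Strictly decreasing intensity thresholds defining cumulative layers.

    The first threshold is the shallowest (surface) layer, the last equals
    the histogram infimum ``a`` so the deepest cumulative layer spans the
    full occupied range.  ``reduced`` flags schemes where clipping into
    (a, b] or deduplication removed nominal thresholds.
    """

    thresholds: tuple[float, ...]
    n_requested: int
    reduced: bool = False

    def __post_init__(self) -> None:
        t = self.thresholds
        if len(t) < 1 or any(t[i] <= t[i + 1] for i in range(len(t) - 1)):
            raise ValueError("layer thresholds must be strictly decreasing")

    @property
    def n(self) -> int:
        return len(self.thresholds)


@dataclass(frozen=True)
class LayeredPorosityProfile:
    """Ordered (threshold, P_xb percent) pairs, surface to depth."""

    thresholds: tuple[float, ...]
    porosities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.porosities):
            raise ValueError("thresholds and porosities must align")

    def __len__(self) -> int:
        return len(self.thresholds)

    @property
    def entries(self) -> tuple[tuple[float, float], ...]:
        return tuple(zip(self.thresholds, self.porosities))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"layer": np.arange(1, len(self) + 1),
             "threshold": self.thresholds,
             "P_xb_percent": self.porosities}
        )


@dataclass(frozen=True)
class InterconnectivityFit:
    """Blocking rate H from the layered-porosity regression.

    H is the magnitude of the least-squares slope of P_xb against layer
    index (percent open area lost per layer); the interconnectivity index
    is its reciprocal.  ``defined`` is False when the slope is below the
    guard tolerance (flat profile).
    """

    H: float
    interconnectivity_index: float
    r_squared: float
    defined: bool
    slope: float

    def __post_init__(self) -> None:
        if self.H < 0:
            raise ValueError("H is a magnitude and cannot be negative")


def layered_porosity(hist: IntensityHistogram, x: float) -> float:
    """Percent open area of the cumulative layer at gray depth ``x``.

    Pixels at level >= x (including x itself) count as solid; the result
    is 100 * (1 - S(x)/N), clamped into [0, 100].
    """
    levels = np.arange(256)
    solid = int(hist.counts[levels >= x].sum())
    return float(min(100.0, max(0.0, 100.0 * (1.0 - solid / hist.total))))


def build_layer_scheme(hist: IntensityHistogram, n: int = 7) -> LayerScheme:
    """Cumulative layer thresholds mu + k*sigma, clipped into (a, b].

    For ``n`` layers, max(1, n-2) consecutive multiples k centered on zero
    (biased toward +sigma when the count is even) give thresholds
    mu + k*sigma; thresholds falling outside (a, b] are dropped, duplicates
    removed, and the terminal threshold a (the full occupied interval) is
    appended.  The default n = 7 yields {mu+2s, mu+s, mu, mu-s, mu-2s, a}.
    """
    if n < 2:
        raise ValueError("a layer scheme needs at least 2 layers")
    if hist.sigma == 0:
        raise ValueError("degenerate histogram: constant image")
    n_k = max(1, n - 2)
    k_hi = (n - 2) // 2 if n >= 3 else 0
    ks = [k_hi - i for i in range(n_k)]
    raw = [hist.mu + k * hist.sigma for k in ks]
    kept: list[float] = []
    for x in raw:
        if hist.a < x <= hist.b and x not in kept:
            kept.append(x)
    kept.sort(reverse=True)
    thresholds = tuple(kept) + (float(hist.a),)
    reduced = len(thresholds) < n_k + 1
    return LayerScheme(thresholds=thresholds, n_requested=n, reduced=reduced)


def porosity_profile(
    hist: IntensityHistogram, scheme: LayerScheme
) -> LayeredPorosityProfile:
    """Layered porosity at every scheme threshold, surface to depth."""
    porosities = tuple(layered_porosity(hist, x) for x in scheme.thresholds)
    # non-increasing by construction (S(x) grows as x decreases); asserted
    assert all(
        porosities[i] >= porosities[i + 1] - 1e-12 for i in range(len(porosities) - 1)
    )
    return LayeredPorosityProfile(thresholds=scheme.thresholds, porosities=porosities)


def interconnectivity(profile: LayeredPorosityProfile) -> InterconnectivityFit:
    """Least-squares blocking rate of the layered-porosity profile.

    P_xb is regressed on layer index 1..n (surface to depth); H is the
    slope magnitude, the interconnectivity index its reciprocal.
    """
    if len(profile) < 3:
        raise ValueError("regression needs >= 3 layers")
    k = np.arange(1, len(profile) + 1, dtype=np.float64)
    y = np.asarray(profile.porosities, dtype=np.float64)
    kc = k - k.mean()
    yc = y - y.mean()
    slope = float((kc * yc).sum() / (kc * kc).sum())
    sst = float((yc * yc).sum())
    if sst == 0.0:
        r2 = float("nan")
    else:
        resid = yc - slope * kc
        r2 = 1.0 - float((resid * resid).sum()) / sst
    H = abs(slope)
    defined = H > H_GUARD
    index = 1.0 / H if defined else float("nan")
    return InterconnectivityFit(
        H=H, interconnectivity_index=index, r_squared=r2, defined=defined, slope=slope
    )


# ---------------------------------------------------------------------------
# planar (projection) measurements
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinaryMask:
    """Solid/pore segmentation of a micrograph (True = solid fiber)."""

    solid: np.ndarray
    threshold_used: int

    def __post_init__(self) -> None:
        solid = np.asarray(self.solid, dtype=bool)
        if solid.ndim != 2 or solid.size == 0:
            raise ValueError("mask must be a non-empty 2D grid")
        object.__setattr__(self, "solid", solid)

    @property
    def pore(self) -> np.ndarray:
        return ~self.solid


@dataclass(frozen=True)
class PoreRegion:
    """A 4-connected component of the pore phase."""

    id: int
    pixels: np.ndarray  # (N, 2) row/col coordinates
    boundary: np.ndarray  # (M, 2) member pixels with an outside 4-neighbor
    area: int
    touches_border: bool
    max_feret: float


@dataclass(frozen=True)
class MeasurementStats:
    """Mean/sd summary of repeated measurements (sample sd, ddof = 1)."""

    n_measurements: int
    mean: float
    sd: float
    measurements: tuple[float, ...]
    resampled: bool = False

    @classmethod
    def from_values(cls, values: Iterable[float], resampled: bool = False):
        vals = tuple(float(v) for v in values)
        if not vals:
            return cls(0, float("nan"), float("nan"), (), resampled)
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return cls(len(vals), mean, sd, vals, resampled)


# the field-standard name for fiber-width summaries
DiameterStats = MeasurementStats


def otsu_threshold(hist: IntensityHistogram) -> int:
    """Threshold maximizing between-class variance; ties break low.

    The candidate t splits the histogram into background {g < t} and solid
    {g >= t}; the returned level is therefore directly usable as the lower
    bound of the solid class.
    """
    counts = hist.counts.astype(np.float64)
    levels = np.arange(256, dtype=np.float64)
    total = counts.sum()
    if hist.a == hist.b:
        raise ValueError("no bimodality: constant image")
    # for threshold t, background is levels < t: use cumulative sums over t=0..255
    cum_n = np.concatenate([[0.0], np.cumsum(counts)])[:256]  # pixels below t
    cum_s = np.concatenate([[0.0], np.cumsum(counts * levels)])[:256]
    w0 = cum_n / total
    w1 = 1.0 - w0
    s_total = (counts * levels).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(cum_n > 0, cum_s / cum_n, 0.0)
        mu1 = np.where(total - cum_n > 0, (s_total - cum_s) / (total - cum_n), 0.0)
    var_between = w0 * w1 * (mu0 - mu1) ** 2
    return int(np.argmax(var_between))  # argmax returns the first (lowest) maximizer


def binarize(
    img: GrayscaleImage,
    method: str = "li",
    level: int | None = None,
    invert: bool = False,
) -> BinaryMask:
    """Segment fibers (solid) from pores.

    Fibers are assumed brighter than the background, as in secondary-
    electron micrographs: pixels at or above the threshold are solid.
    Methods: ``li`` (minimum cross-entropy; robust when the solid class
    spans several depth-coded gray levels and is the projection default),
    ``otsu`` (between-class variance; isolates the bright in-focus surface
    fibers), ``fixed(level)``.  ``invert`` flips the convention for
    dark-fiber imagery.
    """
    pixels = img.pixels if not invert else (255 - img.pixels)
    if method == "otsu":
        t = otsu_threshold(intensity_histogram(GrayscaleImage(pixels)))
    elif method == "li":
        if pixels.min() == pixels.max():
            raise ValueError("no contrast: constant image")
        from skimage.filters import threshold_li

        t = int(np.ceil(threshold_li(pixels)))
    elif method == "fixed":
        if level is None:
            raise ValueError("fixed-threshold binarization needs a level")
        t = int(level)
    else:
        raise ValueError(f"unknown binarization method: {method!r}")
    return BinaryMask(solid=pixels >= t, threshold_used=t)


def overall_porosity(mask: BinaryMask) -> float:
    """Pore-phase area fraction of the 2D projection, in [0, 1]."""
    return float(mask.pore.mean())


def _region_boundary(local: np.ndarray) -> np.ndarray:
    """Member pixels with a 4-neighbor outside the component (or frame)."""
    padded = np.pad(local, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return np.argwhere(local & ~interior)


def segment_pores(
    mask: BinaryMask,
    min_area: int = 5,
    border_policy: str = "exclude",
) -> list[PoreRegion]:
    """4-connected pore components with their maximum Feret diameters.

    Components smaller than ``min_area`` are treated as noise specks;
    components touching the field-of-view border are censored and dropped
    under the default ``exclude`` policy.
    """
    if border_policy not in {"exclude", "include"}:
        raise ValueError(f"unknown border policy: {border_policy!r}")
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    labels, n_labels = ndimage.label(mask.pore, structure=structure)
    regions: list[PoreRegion] = []
    h, w = labels.shape
    for idx, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:  # pragma: no cover
            continue
        local = labels[sl] == idx
        area = int(local.sum())
        if area < min_area:
            continue
        touches = (
            sl[0].start == 0 or sl[1].start == 0 or sl[0].stop == h or sl[1].stop == w
        )
        if touches and border_policy == "exclude":
            continue
        offset = np.array([sl[0].start, sl[1].start])
        boundary = _region_boundary(local) + offset
        pixels = np.argwhere(local) + offset
        feret = _max_feret_points(boundary)
        regions.append(
            PoreRegion(
                id=idx,
                pixels=pixels,
                boundary=boundary,
                area=area,
                touches_border=touches,
                max_feret=feret,
            )
        )
    return regions


def _rotating_calipers_sq(hull: np.ndarray) -> int:
    """Squared diameter of a convex polygon (integer vertices, CCW)."""
    m = len(hull)
    if m == 1:
        return 0
    if m == 2:
        d = hull[1] - hull[0]
        return int(d[0] * d[0] + d[1] * d[1])

    def cross(o, p, q):
        return (p[0] - o[0]) * (q[1] - o[1]) - (p[1] - o[1]) * (q[0] - o[0])

    def dist2(p, q):
        return int((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2)

    best = 0
    k = 1
    for i in range(m):
        j = (i + 1) % m
        # advance the antipodal point while the triangle area keeps growing
        while abs(cross(hull[i], hull[j], hull[(k + 1) % m])) > abs(
            cross(hull[i], hull[j], hull[k])
        ):
            k = (k + 1) % m
        best = max(best, dist2(hull[i], hull[k]), dist2(hull[j], hull[k]))
    return best


def _max_feret_points(points: np.ndarray) -> float:
    """Longest pairwise distance between pixel centers via convex hull."""
    pts = np.unique(np.asarray(points, dtype=np.int64), axis=0)
    if len(pts) == 1:
        return 0.0
    if len(pts) <= 3:
        d = pts[:, None, :] - pts[None, :, :]
        return float(np.sqrt((d * d).sum(axis=2).max()))
    try:
        from scipy.spatial import ConvexHull, QhullError

        hull = pts[ConvexHull(pts).vertices]  # CCW order
    except QhullError:
        # collinear point set: the diameter is between the extreme points
        d = pts[:, None, :] - pts[None, :, :]
        return float(np.sqrt((d * d).sum(axis=2).max()))
    return float(math.sqrt(_rotating_calipers_sq(hull)))


def max_feret(region: PoreRegion) -> float:
    """Maximum Feret diameter: the longest distance between two boundary
    pixel centers of the pore."""
    return _max_feret_points(region.boundary)


def fiber_diameters(
    mask: BinaryMask,
    n_samples: int = 100,
    seed: int = 0,
) -> MeasurementStats:
    """Automated fiber-width measurements along the skeleton centerline.

    The solid phase is thinned to its skeleton; skeleton pixels within
    2 px of a branch point (junctions inflate apparent width) or of a
    skeleton endpoint (ridge ends under-measure it) are discarded; at each
    of ``n_samples`` randomly chosen remaining skeleton pixels the local
    diameter is 2*EDT - 1, where EDT is the Euclidean distance to the
    nearest pore pixel center — a w-pixel-wide straight band measures
    exactly w.  Sampling is with replacement (and flagged) when fewer
    candidate pixels exist.
    """
    from skimage.morphology import skeletonize

    solid = mask.solid
    if not solid.any():
        raise ValueError("empty skeleton: no solid phase to measure")
    if solid.all():
        raise ValueError("no pore phase: fiber width is unbounded")
    skel = skeletonize(solid)
    if not skel.any():
        raise ValueError("empty skeleton")
    neighbor_count = ndimage.convolve(
        skel.astype(np.int8), np.ones((3, 3), dtype=np.int8), mode="constant"
    ) - skel.astype(np.int8)
    unreliable = skel & ((neighbor_count > 2) | (neighbor_count <= 1))
    if unreliable.any():
        dist_to_bad = ndimage.distance_transform_edt(~unreliable)
        retained = skel & (dist_to_bad > 2.0)
    else:
        retained = skel
    if not retained.any():
        retained = skel  # short or heavily branched skeleton: use all of it
    coords = np.argwhere(retained)
    rng = np.random.default_rng(seed)
    replace = len(coords) < n_samples
    pick = rng.choice(len(coords), size=n_samples, replace=replace)
    edt = ndimage.distance_transform_edt(solid)
    values = 2.0 * edt[coords[pick, 0], coords[pick, 1]] - 1.0
    return MeasurementStats.from_values(values, resampled=replace)


# ---------------------------------------------------------------------------
# per-sample summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StructuralSummary:
    """All structural metrics of one micrograph field."""

    sample_id: str
    P_fraction: float
    profile: LayeredPorosityProfile
    scheme: LayerScheme
    fit: InterconnectivityFit
    SPE: float
    pore_stats: MeasurementStats
    fiber_stats: MeasurementStats
    nm_per_pixel: float | None
    threshold_used: int
    fiber_threshold: int
    n_pores: int

    @property
    def P_percent(self) -> float:
        return 100.0 * self.P_fraction

    @property
    def spe_defined(self) -> bool:
        return self.fit.defined

    def _nm(self, px: float) -> float:
        return px * self.nm_per_pixel if self.nm_per_pixel else float("nan")

    def as_row(self) -> dict:
        """Flat per-sample record for tabular output."""
        return {
            "sample_id": self.sample_id,
            "P_fraction": self.P_fraction,
            "H": self.fit.H,
            "interconnectivity_index": self.fit.interconnectivity_index,
            "SPE": self.SPE,
            "r_squared": self.fit.r_squared,
            "pore_mean_px": self.pore_stats.mean,
            "pore_sd_px": self.pore_stats.sd,
            "pore_mean_nm": self._nm(self.pore_stats.mean),
            "pore_sd_nm": self._nm(self.pore_stats.sd),
            "fiber_mean_px": self.fiber_stats.mean,
            "fiber_sd_px": self.fiber_stats.sd,
            "fiber_mean_nm": self._nm(self.fiber_stats.mean),
            "fiber_sd_nm": self._nm(self.fiber_stats.sd),
            "n_pores": self.n_pores,
            "threshold_used": self.threshold_used,
            "fiber_threshold": self.fiber_threshold,
            "spe_defined": self.fit.defined,
            "scheme_reduced": self.scheme.reduced,
            "fiber_resampled": self.fiber_stats.resampled,
        }


def structural_summary(img: GrayscaleImage, config=None) -> StructuralSummary:
    """Run the full single-field analysis pipeline.

    Stages: intensity histogram -> layer scheme -> porosity profile ->
    interconnectivity regression; an inclusive projection mask (all depth
    layers) -> overall porosity / pore segmentation; and a surface-fiber
    mask -> fiber diameters.  The two masks reflect what each measurement
    means physically: the projection porosity counts fibers at every
    depth, while width measurements are only meaningful on the bright,
    in-focus surface fibers (the ones an operator would caliper on a real
    micrograph).  SPE = P(percent)/H when the blocking-rate fit is
    defined.  Stage failures are re-raised with the stage name prefixed.
    """
    from .config import AnalysisConfig

    cfg = config or AnalysisConfig()

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    hist = _stage("intensity_histogram", intensity_histogram, img)
    scheme = _stage("build_layer_scheme", build_layer_scheme, hist, cfg.n_layers)
    profile = _stage("porosity_profile", porosity_profile, hist, scheme)
    fit = _stage("interconnectivity", interconnectivity, profile)
    mask = _stage(
        "binarize", binarize, img, cfg.binarization, cfg.fixed_level, cfg.invert
    )
    p = _stage("overall_porosity", overall_porosity, mask)
    pores = _stage(
        "segment_pores", segment_pores, mask, cfg.min_pore_area, cfg.border_policy
    )
    if cfg.fiber_binarization == cfg.binarization:
        fiber_mask = mask
    else:
        fiber_mask = _stage(
            "binarize_fibers", binarize, img, cfg.fiber_binarization,
            cfg.fixed_level, cfg.invert,
        )
    fiber = _stage(
        "fiber_diameters", fiber_diameters, fiber_mask, cfg.fiber_samples, cfg.seed
    )
    pore_stats = MeasurementStats.from_values([r.max_feret for r in pores])
    spe = (100.0 * p) / fit.H if fit.defined else float("nan")
    return StructuralSummary(
        sample_id=img.source_id,
        P_fraction=p,
        profile=profile,
        scheme=scheme,
        fit=fit,
        SPE=spe,
        pore_stats=pore_stats,
        fiber_stats=fiber,
        nm_per_pixel=cfg.nm_per_pixel,
        threshold_used=mask.threshold_used,
        fiber_threshold=fiber_mask.threshold_used,
        n_pores=len(pores),
    )
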