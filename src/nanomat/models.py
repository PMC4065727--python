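"""Model/Results objects — the package's primary API.

`ScaffoldModel` wraps one micrograph field: fitting runs the full
depth-profile characterization (histogram layering, blocking-rate
regression, binarized projection measurements) and returns a
`ScaffoldResults` carrying the estimates, the layer profile, the
interconnectivity fit diagnostics, and a text summary.

`StructureViabilityModel` wraps the comparative stage: structural metrics
across samples against relative MTT viability, fitted by Pearson
correlation with per-metric t-tests.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .compare import CorrelationReport, ViabilityStats, comparative_report, viability_stats
from .config import AnalysisConfig, StatsConfig
from .imaging import GrayscaleImage, load_grayscale
from .structure import StructuralSummary, structural_summary
from .synthetic import ViabilityTable, _metrics_frame

__all__ = [
    "ScaffoldModel",
    "ScaffoldResults",
    "StructureViabilityModel",
    "StructureViabilityResults",
]


class ScaffoldModel:
    """Depth-profile structural model of a single fibrous-mat micrograph."""

    def __init__(
        self,
        image: GrayscaleImage | np.ndarray,
        config: AnalysisConfig | None = None,
        sample_id: str | None = None,
    ) -> None:
        if not isinstance(image, GrayscaleImage):
            image = GrayscaleImage(np.asarray(image))
        if sample_id is not None:
            image = GrayscaleImage(image.pixels, source_id=sample_id)
        self.image = image
        self.config = config or AnalysisConfig()

    @classmethod
    def from_file(
        cls, path: str | Path, config: AnalysisConfig | None = None
    ) -> "ScaffoldModel":
        return cls(load_grayscale(path), config=config)

    def fit(self) -> "ScaffoldResults":
        """Run the full structural characterization pipeline."""
        return ScaffoldResults(self, structural_summary(self.image, self.config))


@dataclass
class ScaffoldResults:
    """Fitted structural characterization of one micrograph field."""

    model: ScaffoldModel
    summary_data: StructuralSummary

    # -- convenience accessors ------------------------------------------
    @property
    def P(self) -> float:
        """Overall porosity as a fraction in [0, 1]."""
        return self.summary_data.P_fraction

    @property
    def H(self) -> float:
        return self.summary_data.fit.H

    @property
    def interconnectivity_index(self) -> float:
        return self.summary_data.fit.interconnectivity_index

    @property
    def SPE(self) -> float:
        return self.summary_data.SPE

    @property
    def params(self) -> pd.Series:
        row = self.summary_data.as_row()
        return pd.Series(row, name=self.summary_data.sample_id)

    def profile_frame(self) -> pd.DataFrame:
        return self.summary_data.profile.to_frame()

    def summary(self) -> str:
        s = self.summary_data
        unit = "nm" if s.nm_per_pixel else "px"
        scale = s.nm_per_pixel or 1.0
        lines = [
            f"Scaffold structural characterization — sample {s.sample_id or '(unnamed)'}",
            f"  image: {self.model.image.height} x {self.model.image.width} px, "
            f"projection threshold {s.threshold_used}, fiber threshold {s.fiber_threshold}",
            f"  overall porosity P        : {s.P_fraction:.4f} ({s.P_percent:.2f}%)",
            f"  blocking rate H           : "
            + (f"{s.fit.H:.4f} %/layer (r^2 = {s.fit.r_squared:.4f})"
               if s.fit.defined else "undefined (flat profile)"),
            f"  interconnectivity 1/H     : "
            + (f"{s.fit.interconnectivity_index:.5f}" if s.fit.defined else "undefined"),
            f"  percolative efficiency SPE: "
            + (f"{s.SPE:.4f} layers" if s.fit.defined else "undefined"),
            f"  pore max-Feret ({s.n_pores} pores): "
            + (f"{s.pore_stats.mean * scale:.1f} +/- {s.pore_stats.sd * scale:.1f} {unit}"
               if s.n_pores else "none retained"),
            f"  fiber diameter ({s.fiber_stats.n_measurements} meas.): "
            f"{s.fiber_stats.mean * scale:.2f} +/- {s.fiber_stats.sd * scale:.2f} {unit}",
            "  layered porosity profile (threshold -> P_xb %):",
        ]
        for x, p in s.profile.entries:
            lines.append(f"    {x:8.2f} -> {p:6.2f}")
        return "\n".join(lines)

    def plot_profile(self, ax=None):
        """Plot the layered-porosity profile with its regression line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.summary_data
        k = np.arange(1, len(s.profile) + 1)
        y = np.asarray(s.profile.porosities)
        ax.plot(k, y, "o-", label="layered porosity")
        if s.fit.defined:
            yhat = y.mean() + s.fit.slope * (k - k.mean())
            ax.plot(k, yhat, "--", label=f"fit: H = {s.fit.H:.2f} %/layer")
        ax.set_xlabel("cumulative layer (surface -> depth)")
        ax.set_ylabel("layered porosity P_xb (%)")
        ax.set_title(s.sample_id or "layered porosity profile")
        ax.legend()
        return ax


class StructureViabilityModel:
    """Correlation model between structural metrics and relative viability."""

    def __init__(
        self,
        metrics: pd.DataFrame | Sequence[StructuralSummary],
        viability: pd.DataFrame | Iterable[ViabilityStats] | ViabilityTable,
    ) -> None:
        self.metrics = _metrics_frame(metrics)
        if isinstance(viability, ViabilityTable):
            viability = viability_stats(viability)
        if not isinstance(viability, pd.DataFrame):
            viability = pd.DataFrame(
                [
                    {
                        "sample_id": v.sample_id,
                        "mean_relative_viability": v.mean_relative_viability,
                        "sd": v.sd,
                    }
                    for v in viability
                ]
            )
        self.viability = viability

    @classmethod
    def from_results(
        cls,
        results: Sequence[ScaffoldResults],
        viability: ViabilityTable | pd.DataFrame | Iterable[ViabilityStats],
    ) -> "StructureViabilityModel":
        return cls([r.summary_data for r in results], viability)

    def fit(self, stats: StatsConfig | None = None) -> "StructureViabilityResults":
        cfg = stats or StatsConfig()
        report = comparative_report(self.metrics, self.viability, alpha=cfg.alpha)
        return StructureViabilityResults(self, report)


@dataclass
class StructureViabilityResults:
    """Fitted structure-viability correlation analysis."""

    model: StructureViabilityModel
    report: CorrelationReport

    @property
    def frame(self) -> pd.DataFrame:
        return self.report.frame

    def sign_pattern(self) -> dict[str, int]:
        return self.report.sign_pattern()

    def summary(self) -> str:
        return self.report.summary()

    def plot(self, axes=None):
        """Scatter each metric against relative viability."""
        import matplotlib.pyplot as plt

        metrics = self.model.metrics
        via = self.model.viability.set_index("sample_id")["mean_relative_viability"]
        via = via.loc[metrics.index]
        cols = list(metrics.columns)
        if axes is None:
            _, axes = plt.subplots(1, len(cols), figsize=(3 * len(cols), 3))
        for ax, col, row in zip(np.atleast_1d(axes), cols, self.frame.itertuples()):
            ax.scatter(metrics[col], via)
            ax.set_xlabel(col)
            ax.set_title(f"r = {row.pearson_r:.2f}" if row.defined else "undefined")
        np.atleast_1d(axes)[0].set_ylabel("relative viability (%)")
        return axes
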