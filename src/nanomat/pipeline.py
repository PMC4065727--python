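"""Reproducible simulate -> analyze -> compare orchestration.

All randomness is derived deterministically from the pipeline seed; every
CSV written carries a header comment with the config hash and seed, so a
rerun with the same config and seed is bit-identical.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .compare import comparative_report, viability_stats
from .config import AnalysisConfig, PipelineConfig
from .imaging import GrayscaleImage, load_grayscale, save_png
from .structure import StructuralSummary, structural_summary
from .synthetic import MatSpec, ViabilityTable, render_mat, simulate_viability

__all__ = ["run_pipeline", "simulate_samples", "analyze_samples", "aggregate_fields"]

log = logging.getLogger("nanomat")


def _header(config: PipelineConfig) -> str:
    return f"nanomat config_hash={config.config_hash()} seed={config.seed}"


def _write_csv(frame: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# {_header(config)}\n")
        frame.to_csv(fh, index=False)


def simulate_samples(
    config: PipelineConfig, out_dir: Path
) -> dict[str, list[Path]]:
    """Render the synthetic study's mat images with ground-truth sidecars.

    Sample seeds and target coverages are spread deterministically from
    the pipeline seed across the configured coverage range, emulating a
    set of mats electrospun at different processing parameters.
    """
    sim = config.simulation
    if sim is None:
        raise ValueError("config has no simulation section")
    out_dir.mkdir(parents=True, exist_ok=True)
    coverages = np.linspace(*sim.coverage_range, sim.n_samples)
    diameters = np.linspace(*sim.diameter_range, sim.n_samples)
    samples: dict[str, list[Path]] = {}
    for i, (cov, diam) in enumerate(zip(coverages, diameters)):
        sid = f"S{i + 1:02d}"
        overrides = dict(sim.mat)
        overrides.setdefault("target_coverage", float(cov))
        overrides.setdefault("fiber_diameter_mean", float(diam))
        spec = MatSpec(seed=int(config.seed * 1000 + i) % (2**31), **overrides)
        img, truth = render_mat(spec)
        img_path = out_dir / f"{sid}.png"
        save_png(GrayscaleImage(img.pixels, source_id=sid), img_path)
        (out_dir / f"{sid}.truth.json").write_text(
            json.dumps(truth.to_dict(), indent=1)
        )
        samples[sid] = [img_path]
        log.info("simulated %s: coverage %.3f, true porosity %.3f",
                 sid, 1 - truth.true_porosity, truth.true_porosity)
    return samples


def analyze_samples(
    samples: dict[str, Sequence[str | Path]], config: PipelineConfig
) -> tuple[pd.DataFrame, list[StructuralSummary]]:
    """Analyze every field of every sample; average fields per sample.

    Returns the per-field rows (sample_id, field, metrics...) and one
    representative StructuralSummary per sample (the per-sample metric
    table is the field mean of each numeric column).
    """
    rows = []
    per_sample: list[StructuralSummary] = []
    for sid, paths in samples.items():
        field_summaries = []
        for j, p in enumerate(paths):
            img = load_grayscale(p)
            img = GrayscaleImage(img.pixels, source_id=sid)
            s = structural_summary(img, config.analysis)
            field_summaries.append(s)
            row = s.as_row()
            row["field"] = j
            rows.append(row)
        per_sample.append(field_summaries[0] if len(field_summaries) == 1
                          else _mean_summary(field_summaries))
    frame = pd.DataFrame(rows)
    return frame, per_sample


def _mean_summary(fields: list[StructuralSummary]) -> StructuralSummary:
    """Average multi-field metrics onto the first field's summary object."""
    import dataclasses

    from .structure import InterconnectivityFit, MeasurementStats

    base = fields[0]
    p = float(np.mean([f.P_fraction for f in fields]))
    H = float(np.mean([f.fit.H for f in fields]))
    defined = all(f.fit.defined for f in fields) and H > 1e-9
    fit = InterconnectivityFit(
        H=H,
        interconnectivity_index=1.0 / H if defined else float("nan"),
        r_squared=float(np.mean([f.fit.r_squared for f in fields])),
        defined=defined,
        slope=float(np.mean([f.fit.slope for f in fields])),
    )
    pore = MeasurementStats.from_values(
        [v for f in fields for v in f.pore_stats.measurements]
    )
    fiber = MeasurementStats.from_values(
        [v for f in fields for v in f.fiber_stats.measurements]
    )
    return dataclasses.replace(
        base,
        P_fraction=p,
        fit=fit,
        SPE=(100.0 * p) / H if defined else float("nan"),
        pore_stats=pore,
        fiber_stats=fiber,
        n_pores=sum(f.n_pores for f in fields),
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Path]:
    """Execute the configured stages and write tabular artifacts.

    Returns a mapping of artifact name -> path.  Stages: simulation (when
    configured), per-field and per-sample structural analysis, viability
    simulation (when coefficients are configured), and the comparative
    correlation report (skipped with a logged notice when no viability
    table exists).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    try:
        log.info("config %s", _header(config))
        samples: dict[str, Sequence[str | Path]] = dict(config.samples)
        if config.simulation is not None:
            samples.update(simulate_samples(config, out_dir / "images"))
        if not samples:
            raise ValueError("nothing to analyze: no samples configured or simulated")

        field_frame, summaries = analyze_samples(samples, config)
        _write_csv(field_frame, out_dir / "structural_fields.csv", config)
        artifacts["structural_fields"] = out_dir / "structural_fields.csv"
        sample_frame = pd.DataFrame([s.as_row() for s in summaries])
        _write_csv(sample_frame, out_dir / "structural_summary.csv", config)
        artifacts["structural_summary"] = out_dir / "structural_summary.csv"

        profiles = []
        for s in summaries:
            pf = s.profile.to_frame()
            pf.insert(0, "sample_id", s.sample_id)
            profiles.append(pf)
        _write_csv(pd.concat(profiles, ignore_index=True),
                   out_dir / "layer_profiles.csv", config)
        artifacts["layer_profiles"] = out_dir / "layer_profiles.csv"

        viability = None
        if config.simulation is not None and config.simulation.coefficients:
            sim = config.simulation
            viability = simulate_viability(
                summaries,
                sim.coefficients,
                noise_sd=sim.noise_sd,
                control_mean=sim.control_mean,
                seed=(config.seed + 7919) % (2**31),
                intercept=sim.intercept,
            )
            _write_csv(viability.frame, out_dir / "viability.csv", config)
            artifacts["viability"] = out_dir / "viability.csv"

        if viability is not None:
            stats = viability_stats(viability)
            report = comparative_report(summaries, stats, alpha=config.stats.alpha)
            report.to_csv(out_dir / "correlation_report.csv",
                          header_comment=_header(config))
            (out_dir / "correlation_report.txt").write_text(report.summary() + "\n")
            artifacts["correlation_report"] = out_dir / "correlation_report.csv"
        else:
            log.info("compare stage skipped: no viability table available")
        return artifacts
    finally:
        log.removeHandler(handler)
        handler.close()
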