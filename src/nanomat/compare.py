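"""Structure-viability comparative statistics.

Cell viability from an MTT assay is expressed relative to a scaffold-free
control (percent of the control's mean absorbance).  Each structural
metric — mean fiber diameter, mean pore size, overall porosity P,
interconnectivity index 1/H, and SPE — is then correlated with the mean
relative viability across samples.  Per-metric significance uses the
t-test of the Pearson correlation coefficient,

    t = r * sqrt((n - 2) / (1 - r^2)),   df = n - 2,

the reading of an "unpaired Student's t between relative absorbance and
each structural element" that yields one p-value per metric; a plain
pooled-variance two-group t-test is also exposed for direct group
comparisons.  The significance cutoff defaults to p < 0.001.  No
multiple-testing correction is applied; the report says so.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import METRIC_COLUMNS, ViabilityTable, _metrics_frame

__all__ = [
    "ViabilityStats",
    "CorrelationReport",
    "relative_viability",
    "viability_stats",
    "pearson_r",
    "student_t_unpaired",
    "comparative_report",
]


@dataclass(frozen=True)
class ViabilityStats:
    """Relative viability of one sample: mean and sd over replicates (%)."""

    sample_id: str
    mean_relative_viability: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean_relative_viability < 0 or self.sd < 0:
            raise ValueError("viability mean and sd must be nonnegative")


def relative_viability(
    sample_abs: Sequence[float],
    control_abs: Sequence[float],
    sample_id: str = "",
) -> ViabilityStats:
    """Percent-of-control viability from replicate absorbances.

    Each replicate is scored as 100 * A_i / mean(control); the sample's
    viability is the mean of those relative values, with the sample
    (ddof = 1) standard deviation.
    """
    sample = np.asarray(sample_abs, dtype=float)
    control = np.asarray(control_abs, dtype=float)
    if (sample <= 0).any() or (control <= 0).any():
        raise ValueError("absorbances must be positive")
    rel = 100.0 * sample / control.mean()
    sd = float(np.std(rel, ddof=1)) if len(rel) > 1 else 0.0
    return ViabilityStats(sample_id, float(rel.mean()), sd)


def viability_stats(table: ViabilityTable) -> list[ViabilityStats]:
    """Per-sample relative viability from a replicate absorbance table."""
    out = []
    for _, row in table.frame.iterrows():
        out.append(
            relative_viability(
                [row["abs_1"], row["abs_2"], row["abs_3"]],
                [row["ctrl_1"], row["ctrl_2"], row["ctrl_3"]],
                sample_id=str(row["sample_id"]),
            )
        )
    return out


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN when either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson_r needs two equal-length vectors, n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if den == 0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / den, -1.0, 1.0))


def student_t_unpaired(
    group1: Sequence[float], group2: Sequence[float]
) -> tuple[float, float]:
    """Pooled-variance two-sided unpaired t-test (df = n1 + n2 - 2).

    Degenerate cases: zero pooled variance with equal means gives
    (0.0, 1.0); zero pooled variance with different means gives
    (inf-signed t, 0.0) and should be treated as degenerate by callers.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / df
    diff = g1.mean() - g2.mean()
    if sp2 == 0:
        if diff == 0:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), p


@dataclass(frozen=True)
class CorrelationReport:
    """Per-metric Pearson correlations with relative viability."""

    frame: pd.DataFrame  # metric, pearson_r, t_statistic, p_value, significant, n_samples, defined
    alpha: float
    method: str = "correlation-t"

    def sign_pattern(self) -> dict[str, int]:
        """Sign of each defined correlation (+1 / -1 / 0)."""
        return {
            row.metric: int(np.sign(row.pearson_r)) if row.defined else 0
            for row in self.frame.itertuples()
        }

    def to_csv(self, path: str | Path, header_comment: str | None = None) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.frame.to_csv(fh, index=False)
        return path

    def summary(self) -> str:
        lines = [
            "Structure-viability correlation report",
            f"method: t-test of Pearson r ({self.method}), two-sided, df = n - 2",
            f"significance cutoff: p < {self.alpha:g} (no multiple-testing correction)",
            "",
            f"{'metric':<26}{'r':>9}{'t':>10}{'p':>12}  significant",
        ]
        for row in self.frame.itertuples():
            if not row.defined:
                lines.append(f"{row.metric:<26}{'undefined':>9}")
                continue
            lines.append(
                f"{row.metric:<26}{row.pearson_r:>9.4f}{row.t_statistic:>10.3f}"
                f"{row.p_value:>12.3e}  {'yes' if row.significant else 'no'}"
            )
        return "\n".join(lines)


def comparative_report(
    summaries,
    viability: Iterable[ViabilityStats] | pd.DataFrame,
    alpha: float = 0.001,
) -> CorrelationReport:
    """Correlate every structural metric with mean relative viability.

    ``summaries`` is a list of StructuralSummary objects or a metric
    DataFrame indexed by sample_id; ``viability`` is a list of
    ViabilityStats or a DataFrame with sample_id and
    mean_relative_viability columns.  Sample ids must match one-to-one.
    """
    metrics = _metrics_frame(summaries)
    if isinstance(viability, pd.DataFrame):
        via = viability.set_index("sample_id")["mean_relative_viability"]
    else:
        via = pd.Series(
            {v.sample_id: v.mean_relative_viability for v in viability},
            name="mean_relative_viability",
        )
    missing = sorted(set(metrics.index.astype(str)) ^ set(via.index.astype(str)))
    if missing:
        raise ValueError(f"sample ids do not match between tables: {missing}")
    if len(metrics) < 3:
        raise ValueError("comparative analysis needs >= 3 matched samples")
    via = via.loc[metrics.index]
    n = len(metrics)
    rows = []
    y = via.to_numpy(dtype=float)
    for metric in METRIC_COLUMNS:
        x = metrics[metric].to_numpy(dtype=float)
        r = pearson_r(x, y) if np.isfinite(x).all() else float("nan")
        defined = bool(np.isfinite(r))
        if defined and abs(r) < 1.0:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * float(sps.t.sf(abs(t), n - 2))
        elif defined:  # |r| == 1 exactly
            t, p = float(np.sign(r) * np.inf), 0.0
        else:
            t, p = float("nan"), float("nan")
        rows.append(
            {
                "metric": metric,
                "pearson_r": r,
                "t_statistic": t,
                "p_value": p,
                "significant": bool(defined and p < alpha),
                "n_samples": n,
                "defined": defined,
            }
        )
    return CorrelationReport(frame=pd.DataFrame(rows), alpha=alpha)
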