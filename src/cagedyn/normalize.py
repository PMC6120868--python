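"""Tag-count normalization and expression filters.

CAGE tag counts are scaled to tags-per-million (TPM) within each library.
Time-course summaries average TPM across replicates per time point, and fold
changes are log2 ratios against the unstimulated baseline (t = 0) with a
pseudocount of 1 TPM, so up- and down-regulation are symmetric (a 4-fold
induction is +2, the equivalent repression is -2).

Two expression filters gate downstream analyses: a minimum of 5 raw tags
summed across a time course (differential expression), and a minimum of
10 TPM in at least one sample (motif activity fitting).  Both thresholds are
inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Agonist, CountMatrix, SampleMeta, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "tags_to_tpm",
    "log_expression",
    "course_samples",
    "timepoint_mean",
    "log2fc_vs_t0",
    "filter_min_tags",
    "filter_min_tpm",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Expression values, regions x samples; scale is 'tpm' or 'log' (log2(TPM+1))."""

    data: pd.DataFrame
    scale: str = "tpm"

    def __post_init__(self) -> None:
        if self.scale not in ("tpm", "log"):
            raise ValidationError(f"unknown expression scale {self.scale!r}")

    @property
    def region_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)


def tags_to_tpm(counts: CountMatrix) -> ExpressionMatrix:
    """Scale each library so its column sums to one million tags."""
    totals = counts.data.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"zero total tag count in sample(s): {list(zero.index)[:5]}")
    tpm = counts.data.div(totals, axis=1) * 1e6
    return ExpressionMatrix(tpm, scale="tpm")


def log_expression(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(TPM + pseudocount); identity if already on the log scale."""
    if expr.scale == "log":
        return expr
    return ExpressionMatrix(np.log2(expr.data + pseudocount), scale="log")


def course_samples(meta: list[SampleMeta], agonist: Agonist | str) -> list[SampleMeta]:
    """Samples belonging to one agonist's course: its stimulated libraries plus
    every t=0 baseline library (the baseline is shared between agonists)."""
    agonist = Agonist(agonist)
    return [m for m in meta if m.agonist == agonist or m.time_min == 0]


def timepoint_mean(
    expr: ExpressionMatrix,
    meta: list[SampleMeta],
    agonist: Agonist | str,
) -> ExpressionMatrix:
    """Mean TPM across replicates per time point; columns are time_min (sorted)."""
    members = course_samples(meta, agonist)
    if not members:
        raise ValidationError(f"no samples for agonist {agonist}")
    by_time: dict[int, list[str]] = {}
    for m in members:
        by_time.setdefault(m.time_min, []).append(m.sample_id)
    cols = {}
    for t in sorted(by_time):
        ids = [s for s in by_time[t] if s in expr.data.columns]
        if not ids:
            raise ValidationError(f"no expression columns for time {t} min")
        cols[t] = expr.data[ids].mean(axis=1)
    out = pd.DataFrame(cols)
    return ExpressionMatrix(out, scale=expr.scale)


def log2fc_vs_t0(mean_expr: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2((x_t + 1) / (x_0 + 1)) per region for every nonzero time point.

    Antisymmetric by construction: exchanging the two time points negates it.
    """
    if mean_expr.scale != "tpm":
        raise ValidationError("log2fc_vs_t0 expects TPM-scale expression")
    df = mean_expr.data
    if 0 not in df.columns:
        raise ValidationError("baseline time point t=0 missing from mean expression")
    base = df[0] + pseudocount
    times = [t for t in df.columns if t != 0]
    lfc = pd.DataFrame(
        {t: np.log2((df[t] + pseudocount) / base) for t in times}, index=df.index
    )
    return lfc


def filter_min_tags(
    counts: CountMatrix,
    min_total: int = 5,
    sample_subset: list[str] | None = None,
) -> CountMatrix:
    """Keep promoters with >= min_total tags summed over the given samples.

    The threshold is inclusive ("at least"); row order is preserved.
    """
    df = counts.data if sample_subset is None else counts.select_samples(sample_subset).data
    keep = df.sum(axis=1) >= min_total
    if not keep.any():
        logger.warning("filter_min_tags: no promoters pass min_total=%d", min_total)
    return CountMatrix(counts.data.loc[keep[keep].index])


def filter_min_tpm(expr: ExpressionMatrix, threshold: float = 10.0) -> list[str]:
    """Region ids whose TPM reaches the threshold in at least one sample (inclusive)."""
    if expr.scale != "tpm":
        raise ValidationError("filter_min_tpm expects TPM-scale expression")
    keep = expr.data.max(axis=1) >= threshold
    return list(expr.data.index[keep])
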