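"""Response summaries built on the differential-expression tables.

Three views of a two-agonist time course:

* per-time-point tallies of promoters significantly changed versus the
  unstimulated baseline (the t0-anchored comparison families only);
* a partition of responsive promoters (significant in at least one pairwise
  comparison up to and including 6 h) into agonist-exclusive and shared sets;
* a deterministic response-shape label per promoter from its log2FC profile
  and its per-time significance flags.

The shape taxonomy is a reduced, fully parameterized stand-in: onset class
(rapid <= 60 min < early <= 120 min < late), whether the response returned to
baseline (|log2FC| below a threshold), and a biphasic direction when the sign
of the fold change flips between significant time points.  All thresholds
live in ShapeParams.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = [
    "ResponderPartition",
    "ShapeParams",
    "ResponseShape",
    "count_significant_per_timepoint",
    "responder_set",
    "partition_responders",
    "classify_response_shape",
    "classify_all_shapes",
    "shape_matches_planted",
]

SHAPE_LABELS = (
    "rapid_short",
    "rapid_long",
    "early_standard",
    "late",
    "late_flat",
    "long",
    "flat",
)


def _round1(x: float) -> float:
    """One-decimal display rounding, half-up."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ResponderPartition:
    """Disjoint split of responsive promoters by agonist."""

    fgf2_only: frozenset
    il1b_only: frozenset
    both: frozenset
    total: int
    pct_fgf2_only: float
    pct_il1b_only: float
    pct_both: float


@dataclass(frozen=True)
class ShapeParams:
    """Thresholds of the response-shape taxonomy (minutes / log2 units)."""

    rapid_onset_max: int = 60
    early_onset_max: int = 120
    return_by_min: int = 180
    return_threshold: float = 0.5


@dataclass(frozen=True)
class ResponseShape:
    region_id: str
    onset_min: int | None
    peak_min: int | None
    returned_to_baseline: bool
    direction: str  # up | down | biphasic
    label: str


def count_significant_per_timepoint(de: pd.DataFrame, agonist: str | None = None) -> dict[int, int]:
    """Promoters significant in each (0, t) family -- change versus baseline.

    Only t0-anchored families count; non-baseline pairs are ignored here.
    """
    df = de
    if agonist is not None:
        df = df[df["agonist"] == str(agonist)]
    out: dict[int, int] = {int(t): 0 for t in sorted(df["time_b"].unique()) if t != 0}
    anchored = df[(df["time_a"] == 0) & df["significant"]]
    for t, n in anchored.groupby("time_b").size().items():
        out[int(t)] = int(n)
    return out


def responder_set(de: pd.DataFrame, max_time: int = 360) -> set[str]:
    """Promoters significant in >= 1 pairwise family with both times <= max_time."""
    sel = de[(de["time_a"] <= max_time) & (de["time_b"] <= max_time) & de["significant"]]
    return set(sel["region_id"])


def partition_responders(responders_fgf2: set[str], responders_il1b: set[str]) -> ResponderPartition:
    """Exact set algebra over the union; percentages displayed to one decimal."""
    a, b = set(responders_fgf2), set(responders_il1b)
    union = a | b
    if not union:
        raise ValidationError("no responders in either set")
    both = a & b
    total = len(union)
    return ResponderPartition(
        fgf2_only=frozenset(a - b),
        il1b_only=frozenset(b - a),
        both=frozenset(both),
        total=total,
        pct_fgf2_only=_round1(100.0 * len(a - b) / total),
        pct_il1b_only=_round1(100.0 * len(b - a) / total),
        pct_both=_round1(100.0 * len(both) / total),
    )


def classify_response_shape(
    region_id: str,
    lfc_profile: pd.Series,
    sig_vs_t0: pd.Series,
    params: ShapeParams = ShapeParams(),
) -> ResponseShape:
    """Deterministic shape label from a time-indexed log2FC profile.

    `lfc_profile` and `sig_vs_t0` are indexed by nonzero time points (minutes).
    Every input receives exactly one label; no significant time -> 'flat'.
    """
    times = sorted(int(t) for t in lfc_profile.index)
    sig_times = [t for t in times if bool(sig_vs_t0.get(t, False))]
    if not sig_times:
        return ResponseShape(region_id, None, None, False, "up", "flat")

    onset = sig_times[0]
    # peak among significant times so onset <= peak always holds
    peak = max(sig_times, key=lambda t: abs(float(lfc_profile[t])))
    last = times[-1]
    returned_last = abs(float(lfc_profile[last])) < params.return_threshold
    returned_by = all(
        abs(float(lfc_profile[t])) < params.return_threshold
        for t in times
        if t >= params.return_by_min
    )

    sig_signs = {np.sign(float(lfc_profile[t])) for t in sig_times} - {0.0}
    if len(sig_signs) > 1:
        direction = "biphasic"
    else:
        direction = "up" if float(lfc_profile[peak]) >= 0 else "down"

    if onset <= params.rapid_onset_max:
        label = "rapid_short" if returned_by else "rapid_long"
    elif onset <= params.early_onset_max:
        label = "early_standard" if returned_last else "long"
    else:
        label = "late_flat" if returned_last else "late"

    return ResponseShape(region_id, onset, peak, returned_last, direction, label)


def classify_all_shapes(
    lfc: pd.DataFrame,
    sig: pd.DataFrame,
    params: ShapeParams = ShapeParams(),
) -> pd.DataFrame:
    """Classify every row of a promoters x times log2FC table.

    `sig` shares the index/columns of `lfc` and holds per-time significance
    versus t0 (from the t0-anchored DE families).
    """
    rows = []
    for rid in lfc.index:
        s = classify_response_shape(rid, lfc.loc[rid], sig.loc[rid], params)
        rows.append(
            {
                "region_id": s.region_id,
                "onset_min": s.onset_min,
                "peak_min": s.peak_min,
                "returned_to_baseline": s.returned_to_baseline,
                "direction": s.direction,
                "label": s.label,
            }
        )
    return pd.DataFrame(rows).set_index("region_id")


def shape_matches_planted(row: pd.Series, planted: str) -> bool:
    """Does a classified shape agree with a generator-planted shape name?

    'biphasic' is planted as a direction (sign-flipping trajectory); the other
    planted names are labels.
    """
    if planted == "biphasic":
        return row["direction"] == "biphasic"
    return row["label"] == planted
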