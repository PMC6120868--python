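"""Minimal bidirectional-enhancer caller.

Transcribed enhancers show balanced divergent CAGE signal: reads on the
minus strand immediately upstream of reads on the plus strand.  This module
detects such loci from strand-split binned tag counts by pairing a
minus-strand bin with the nearest downstream plus-strand bin within a
pairing window (default 400 bp), merging the pair into one locus, and
discarding loci overlapping or within 500 bp of any annotated gene.  It is a
deliberately simple stand-in for atlas-scale enhancer calling, sufficient to
define an enhancer compartment for motif-activity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = ["EnhancerLocus", "detect_bidirectional_loci"]


@dataclass(frozen=True)
class EnhancerLocus:
    """A bidirectionally transcribed locus distal to annotated genes."""

    chrom: str
    start: int
    end: int
    plus_tags: int
    minus_tags: int
    distance_to_nearest_gene: int

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def _check_sorted(bins: pd.DataFrame, label: str) -> None:
    for chrom, sub in bins.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(np.diff(starts) < 0):
            raise ValidationError(f"{label} bins are not sorted by start on {chrom}")
        if np.any(starts[1:] < ends[:-1]):
            raise ValidationError(f"{label} bins overlap on {chrom}")


def _gene_distance(chrom: str, start: int, end: int, genes: pd.DataFrame) -> int:
    sub = genes[genes["chrom"] == chrom]
    if sub.empty:
        return np.iinfo(np.int64).max
    gs = sub["start"].to_numpy()
    ge = sub["end"].to_numpy()
    overlap = (gs < end) & (ge > start)
    if overlap.any():
        return 0
    left = np.where(ge <= start, start - ge, np.iinfo(np.int64).max)
    right = np.where(gs >= end, gs - end, np.iinfo(np.int64).max)
    return int(min(left.min(), right.min()))


def detect_bidirectional_loci(
    plus_bins: pd.DataFrame,
    minus_bins: pd.DataFrame,
    genes: pd.DataFrame,
    pair_window: int = 400,
    min_tags_per_strand: int = 1,
    min_gene_distance: int = 500,
) -> list[EnhancerLocus]:
    """Pair divergent minus/plus signal bins into candidate enhancer loci.

    Inputs are BED-like frames (chrom, start, end, score = tag count), sorted
    and non-overlapping per strand.  A minus bin pairs with the first plus bin
    starting at or after its end with a gap of at most `pair_window`; each bin
    is consumed once (greedy left-to-right).  The merged locus spans both bins
    and is kept only when both strands reach `min_tags_per_strand` and the
    locus lies at least `min_gene_distance` bp from every gene interval.
    """
    for df, label in ((plus_bins, "plus"), (minus_bins, "minus")):
        _check_sorted(df, label)
    loci: list[EnhancerLocus] = []
    for chrom in sorted(set(minus_bins["chrom"]) & set(plus_bins["chrom"])):
        minus = minus_bins[minus_bins["chrom"] == chrom].reset_index(drop=True)
        plus = plus_bins[plus_bins["chrom"] == chrom].reset_index(drop=True)
        p_starts = plus["start"].to_numpy()
        used = np.zeros(len(plus), dtype=bool)
        for _, mrow in minus.iterrows():
            j = int(np.searchsorted(p_starts, mrow["end"], side="left"))
            while j < len(plus) and used[j]:
                j += 1
            if j >= len(plus):
                continue
            gap = int(p_starts[j] - mrow["end"])
            if gap < 0 or gap > pair_window:
                continue
            minus_tags = int(mrow["score"])
            plus_tags = int(plus.iloc[j]["score"])
            if minus_tags < min_tags_per_strand or plus_tags < min_tags_per_strand:
                continue
            used[j] = True
            start, end = int(mrow["start"]), int(plus.iloc[j]["end"])
            dist = _gene_distance(chrom, start, end, genes)
            if dist < min_gene_distance:
                continue
            loci.append(
                EnhancerLocus(
                    chrom=chrom,
                    start=start,
                    end=end,
                    plus_tags=plus_tags,
                    minus_tags=minus_tags,
                    distance_to_nearest_gene=dist,
                )
            )
    return loci
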