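"""Readers and writers for the on-disk artifacts of a CAGE promoter pipeline.

All tabular artifacts are plain UTF-8 TSV with a single header row; genomic
intervals are BED (0-based, half-open).  Readers validate strictly and never
silently reorder rows or columns; every reader/writer pair round-trips
bit-exactly for integer tables and to ~1e-12 relative for real-valued ones.

Promoter names follow the FANTOM-style ``pN@GENE`` convention, where ``p1@``
marks the promoter of a gene with the highest tag support, ``p2@`` the second,
and so on.  Names without the prefix are kept verbatim (rank absent), which
covers unannotated CAGE peaks such as ``chr10:1000..1001,+``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "Agonist",
    "SampleMeta",
    "CountMatrix",
    "PromoterAnnotation",
    "MotifSiteMatrix",
    "read_count_table",
    "write_count_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_promoter_bed",
    "write_promoter_bed",
    "read_motif_sites",
    "write_motif_sites",
    "read_bed_intervals",
]


class ValidationError(ValueError):
    """An input file or in-memory table violates a structural invariant."""


class Agonist(str, Enum):
    """Stimulation agonist of a CAGE library; NONE marks the shared t=0 baseline."""

    FGF2 = "FGF2"
    IL1B = "IL1B"
    NONE = "NONE"


@dataclass(frozen=True)
class SampleMeta:
    """One CAGE library: which agonist, minutes after stimulation, replicate."""

    sample_id: str
    agonist: Agonist
    time_min: int
    replicate: int

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValidationError(f"sample {self.sample_id!r}: negative time_min {self.time_min}")
        if self.replicate < 1:
            raise ValidationError(f"sample {self.sample_id!r}: replicate must be >= 1")


def _check_unique(values, what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass(frozen=True)
class CountMatrix:
    """Raw CAGE tag counts, promoters x samples (non-negative integers)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "promoter ids")
        _check_unique(df.columns, "sample ids")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError("count matrix entries must be integers")
        if arr.size and arr.min() < 0:
            r, c = np.unravel_index(int(arr.argmin()), arr.shape)
            raise ValidationError(
                f"negative count {arr[r, c]} at row {df.index[r]!r}, column {df.columns[c]!r}"
            )

    @property
    def promoter_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def library_sizes(self) -> pd.Series:
        return self.data.sum(axis=0)

    def select_samples(self, sample_ids: list[str]) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        return CountMatrix(self.data.loc[:, sample_ids])

    def select_promoters(self, promoter_ids: list[str]) -> "CountMatrix":
        missing = [p for p in promoter_ids if p not in self.data.index]
        if missing:
            raise ValidationError(f"unknown promoter ids: {missing[:5]}")
        return CountMatrix(self.data.loc[promoter_ids])


_PN_RE = re.compile(r"^p(\d+)@(.+)$")


@dataclass(frozen=True)
class PromoterAnnotation:
    """Genomic annotation of one promoter (0-based, half-open interval)."""

    promoter_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_symbol: str = ""
    rank: int | None = field(default=None)
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"promoter {self.promoter_id!r}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"promoter {self.promoter_id!r}: malformed strand {self.strand!r}")


def parse_promoter_name(name: str) -> tuple[int | None, str]:
    """Split a ``pN@GENE`` name into (rank, gene_symbol); (None, "") if unranked."""
    m = _PN_RE.match(name)
    if m is None:
        return None, ""
    return int(m.group(1)), m.group(2)


@dataclass(frozen=True)
class MotifSiteMatrix:
    """Predicted binding-site counts N[p, m]: regions x motifs, non-negative reals."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "region ids")
        _check_unique(df.columns, "motif ids")
        arr = df.to_numpy(dtype=float)
        if arr.size and np.nanmin(arr) < 0:
            r, c = np.unravel_index(int(np.nanargmin(arr)), arr.shape)
            raise ValidationError(
                f"negative site count {arr[r, c]} at row {df.index[r]!r}, column {df.columns[c]!r}"
            )
        if arr.size and np.isnan(arr).any():
            raise ValidationError("site matrix contains missing values")

    @property
    def region_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def motif_ids(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# count tables


def read_count_table(path: str | Path, fmt: str = "tsv") -> CountMatrix:
    """Read a promoters x samples integer count TSV (header row = sample ids)."""
    if fmt != "tsv":
        raise ValidationError(f"unsupported count-table format {fmt!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.integer):
            numeric = pd.to_numeric(vals, errors="coerce")
            bad = numeric.isna() | (numeric != np.floor(numeric))
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise ValidationError(
                    f"non-integer value {vals[bad].iloc[0]!r} at row {row!r}, column {col!r}"
                )
            df[col] = numeric.astype(np.int64)
    return CountMatrix(df)


def write_count_table(matrix: CountMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="promoter_id")


# ---------------------------------------------------------------------------
# sample metadata

_META_COLUMNS = ["sample_id", "agonist", "time_min", "replicate"]


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata TSV with columns sample_id, agonist, time_min, replicate."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing required columns: {missing}")
    _check_unique(df["sample_id"], "sample ids")
    allowed = {a.value for a in Agonist}
    records = []
    for _, row in df.iterrows():
        ag = str(row["agonist"])
        if ag not in allowed:
            raise ValidationError(
                f"unknown agonist {ag!r} for sample {row['sample_id']!r}; allowed: {sorted(allowed)}"
            )
        records.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                agonist=Agonist(ag),
                time_min=int(row["time_min"]),
                replicate=int(row["replicate"]),
            )
        )
    return records


def write_sample_metadata(meta: list[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "agonist": [m.agonist.value for m in meta],
            "time_min": [m.time_min for m in meta],
            "replicate": [m.replicate for m in meta],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# promoter / interval BED


def read_promoter_bed(path: str | Path) -> list[PromoterAnnotation]:
    """Read BED6+ promoter annotation.

    Columns: chrom, start, end, name, score, strand[, gene_symbol[, is_tf]].
    The name column carries the promoter id; ``pN@GENE`` names are parsed into
    rank and gene symbol.  A missing is_tf column defaults to False (logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[PromoterAnnotation] = []
    warned_tf = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ValidationError(f"{path}:{lineno}: expected >= 6 BED columns")
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            rank, gene = parse_promoter_name(name)
            if len(fields) >= 7 and fields[6]:
                gene = fields[6]
            if len(fields) >= 8:
                is_tf = fields[7].strip().lower() in ("1", "true", "yes")
            else:
                is_tf = False
                if not warned_tf:
                    logger.warning("%s: no is_tf column; defaulting is_tf=False", path)
                    warned_tf = True
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer coordinates") from exc
            out.append(
                PromoterAnnotation(
                    promoter_id=name,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    gene_symbol=gene,
                    rank=rank,
                    is_tf=is_tf,
                )
            )
    return out


def write_promoter_bed(annotations: list[PromoterAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in annotations:
            fh.write(
                "\t".join(
                    [
                        a.chrom,
                        str(a.start),
                        str(a.end),
                        a.promoter_id,
                        "0",
                        a.strand,
                        a.gene_symbol,
                        "1" if a.is_tf else "0",
                    ]
                )
                + "\n"
            )


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Read a plain BED file into a DataFrame (chrom, start, end[, name, score, strand]).

    The score column is numeric when present (used for binned CAGE signal where
    score carries the tag count).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: expected >= 3 BED columns")
            rec = {
                "chrom": fields[0],
                "start": int(fields[1]),
                "end": int(fields[2]),
                "name": fields[3] if len(fields) > 3 else "",
                "score": float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0,
                "strand": fields[5] if len(fields) > 5 else ".",
            }
            if rec["start"] >= rec["end"]:
                raise ValidationError(f"{path}:{lineno}: start >= end")
            rows.append(rec)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


# ---------------------------------------------------------------------------
# motif site matrices


def read_motif_sites(path: str | Path) -> MotifSiteMatrix:
    """Read a regions x motifs TSV of non-negative (possibly weighted) site counts."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric site count: {exc}") from exc
    return MotifSiteMatrix(df)


def write_motif_sites(sites: MotifSiteMatrix, path: str | Path) -> None:
    sites.data.to_csv(path, sep="\t", index_label="region_id", float_format="%.17g")
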