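"""Locus-level small-RNA read counting and RPM normalization.

Reads arrive pre-aligned (zero-mismatch, with the number of genomic
placements recorded per read); this module assigns placements to annotation
loci under the coverage rule that a read counts towards a locus only when it
covers at least ``overlap_frac`` (default 70%) of the locus length, drops
reads with more than ``max_locations`` placements, and produces raw count
and reads-per-million matrices plus per-sample mapping statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import AnnotationSet
from .errors import DataError, ParseError

ALN_COLUMNS = ["chrom", "start", "end", "read_id", "n_hits", "strand"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Raw locus x sample counts with per-sample totals.

    ``aligned_total`` is the number of alignment records seen per sample;
    ``assigned_total`` (column sums of ``counts``) can never exceed it
    because each placement contributes at most one count.
    """

    counts: pd.DataFrame  # loci x samples, int
    aligned_total: pd.Series  # per sample

    @property
    def assigned_total(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def validate(self) -> None:
        if (self.assigned_total > self.aligned_total[self.counts.columns]).any():
            raise DataError("assigned_total exceeds aligned_total")


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame  # loci x samples, RPM floats
    normalization_denominator: str = "assigned"


@dataclass
class SampleTable:
    """Sample metadata: sample_id -> (animal_id, tissue)."""

    frame: pd.DataFrame  # columns sample_id, animal_id, tissue

    def __post_init__(self) -> None:
        required = {"sample_id", "animal_id", "tissue"}
        missing = required - set(self.frame.columns)
        if missing:
            raise DataError(f"samples table missing columns {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            raise DataError("duplicate sample_id in samples table")
        if self.frame["tissue"].isna().any() or (self.frame["tissue"] == "").any():
            raise DataError("every sample needs a tissue label")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def tissue_of(self) -> pd.Series:
        return self.frame.set_index("sample_id")["tissue"]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alignment input
# ---------------------------------------------------------------------------

def read_alignment_bed(path: str | Path) -> pd.DataFrame:
    """6-column BED-like TSV: chrom, start, end, read_id, n_hits, strand."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=ALN_COLUMNS,
            dtype={"chrom": str, "read_id": str, "strand": str},
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse alignment BED ({exc})") from exc
    if len(df) and ((df["start"] >= df["end"]).any() or (df["n_hits"] < 1).any()):
        raise DataError(f"{path}: invalid alignment intervals or n_hits")
    return df


def read_alignment_sam(path: str | Path) -> pd.DataFrame:
    """Minimal SAM reader mapping the NH tag to n_hits (1 when absent)."""
    rows = []
    for line in Path(path).open():
        if line.startswith("@"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 11:
            raise ParseError(f"{path}: truncated SAM line")
        flag = int(f[1])
        if flag & 4:  # unmapped
            continue
        n_hits = 1
        for tag in f[11:]:
            if tag.startswith("NH:i:"):
                n_hits = int(tag[5:])
        start = int(f[3]) - 1
        rows.append(
            (f[2], start, start + len(f[9]), f[0], n_hits,
             "-" if flag & 16 else "+")
        )
    return pd.DataFrame(rows, columns=ALN_COLUMNS)


# ---------------------------------------------------------------------------
# read -> locus assignment
# ---------------------------------------------------------------------------

def _locus_index(annotation: AnnotationSet, stranded: bool):
    """Per-(chrom[,strand]) sorted locus arrays for interval lookup."""
    groups: dict[tuple, list] = {}
    for i, loc in enumerate(annotation.loci):
        key = (loc.chrom, loc.strand) if stranded else (loc.chrom,)
        groups.setdefault(key, []).append((loc.start, loc.end, i))
    index = {}
    for key, entries in groups.items():
        entries.sort()
        starts = np.array([e[0] for e in entries])
        ends = np.array([e[1] for e in entries])
        idx = np.array([e[2] for e in entries])
        index[key] = (starts, ends, idx)
    return index


def assign_reads(
    alignments: Mapping[str, pd.DataFrame],
    annotation: AnnotationSet,
    samples: SampleTable,
    overlap_frac: float = 0.7,
    max_locations: int = 10,
    stranded: bool = True,
    overlap_denominator: str = "locus",
) -> CountMatrix:
    """Count reads per locus under the fractional-coverage rule.

    A placement contributes one count to a locus when
    ``overlap / denominator_length >= overlap_frac`` where the denominator is
    the locus length (default, matching the rule that a read must cover at
    least 70% of the locus) or the read length.  Reads whose total number of
    genomic placements exceeds ``max_locations`` contribute nothing.
    """
    if not (0 < overlap_frac <= 1):
        raise DataError(f"overlap_frac must be in (0, 1], got {overlap_frac}")
    if overlap_denominator not in ("locus", "read"):
        raise DataError(f"unknown overlap_denominator {overlap_denominator!r}")
    known = set(samples.sample_ids)
    unknown = set(alignments) - known
    if unknown:
        raise DataError(f"alignments for samples missing from metadata: {sorted(unknown)}")

    index = _locus_index(annotation, stranded)
    names = [loc.name for loc in annotation.loci]
    counts = pd.DataFrame(
        0, index=names, columns=samples.sample_ids, dtype=int
    )
    aligned_total = pd.Series(0, index=samples.sample_ids, dtype=int)

    for sample_id in samples.sample_ids:
        df = alignments.get(sample_id)
        if df is None:
            continue
        aligned_total[sample_id] = len(df)
        keep = df["n_hits"].to_numpy() <= max_locations
        col = counts[sample_id].to_numpy()
        chroms = df["chrom"].to_numpy()
        starts = df["start"].to_numpy()
        ends = df["end"].to_numpy()
        strands = df["strand"].to_numpy()
        for k in np.nonzero(keep)[0]:
            key = (chroms[k], strands[k]) if stranded else (chroms[k],)
            entry = index.get(key)
            if entry is None:
                continue
            lstarts, lends, lidx = entry
            # loci with start < read_end and end > read_start
            lo = np.searchsorted(lends, starts[k], side="right")
            hi = np.searchsorted(lstarts, ends[k], side="left")
            for j in range(lo, hi):
                ov = min(ends[k], lends[j]) - max(starts[k], lstarts[j])
                if ov <= 0:
                    continue
                denom = (
                    lends[j] - lstarts[j]
                    if overlap_denominator == "locus"
                    else ends[k] - starts[k]
                )
                if ov / denom >= overlap_frac:
                    col[lidx[j]] += 1
        counts[sample_id] = col
    cm = CountMatrix(counts, aligned_total)
    cm.validate()
    return cm


# ---------------------------------------------------------------------------
# normalization, detection, mapping statistics
# ---------------------------------------------------------------------------

def rpm_normalize(
    counts: CountMatrix, denominator: str = "assigned"
) -> ExpressionMatrix:
    """Reads-per-million: counts / per-sample denominator total * 1e6.

    With ``denominator='assigned'`` each non-empty column sums to exactly
    one million.  Samples with a zero denominator get all-zero RPM and a
    warning.
    """
    if denominator == "assigned":
        totals = counts.assigned_total
    elif denominator == "aligned":
        totals = counts.aligned_total[counts.counts.columns]
    else:
        raise DataError(f"unknown RPM denominator {denominator!r}")
    zero = totals[totals == 0].index.tolist()
    if zero:
        warnings.warn(f"samples with zero {denominator} reads: {zero}; RPM set to 0")
    safe = totals.replace(0, 1)
    values = counts.counts.div(safe, axis=1) * 1e6
    values[zero] = 0.0
    return ExpressionMatrix(values, normalization_denominator=denominator)


def tissue_medians(expr: ExpressionMatrix, samples: SampleTable) -> pd.DataFrame:
    """Per-(locus, tissue) median RPM."""
    tissue = samples.tissue_of()[expr.values.columns]
    return expr.values.T.groupby(tissue.values).median().T


def detection_matrix(
    expr: ExpressionMatrix,
    samples: SampleTable,
    detection_rpm: float = 100.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-(locus, tissue) detection: tissue median RPM strictly > threshold.

    Returns the boolean matrix and per-locus number of detected tissues.
    """
    med = tissue_medians(expr, samples)
    detected = med > detection_rpm
    return detected, detected.sum(axis=1)


def percent_mapped(
    aligned: pd.Series | Mapping[str, int], total: pd.Series | Mapping[str, int]
) -> pd.Series:
    """100 * aligned/total per sample; a zero total is an error."""
    aligned = pd.Series(aligned, dtype=float)
    total = pd.Series(total, dtype=float)[aligned.index]
    if (total <= 0).any():
        bad = total[total <= 0].index.tolist()
        raise DataError(f"total read count is zero for samples {bad}")
    if (aligned > total).any():
        raise DataError("aligned exceeds total read count")
    return 100.0 * aligned / total


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, name: str = "locus") -> None:
    df.to_csv(path, sep="\t", index_label=name, float_format="%.6g")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
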