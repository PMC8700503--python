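"""Family-level read counting over a TE library.

Expression of a TE family is the sum of reads mapping to any genomic copy of
that family (primary alignments only); this module turns per-copy alignments
into a families x samples count matrix, optionally restricted to sense or
antisense alignments (the orientation split is what the small-RNA analyses
use).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

__all__ = [
    "AlignmentRecord",
    "FamilyCountMatrix",
    "count_by_family",
    "read_sam_alignments",
    "read_alignment_tsv",
    "build_count_matrix",
]

ORIENTATIONS = ("both", "sense", "antisense")


@dataclass(frozen=True)
class AlignmentRecord:
    """One primary alignment of a read to a TE copy.

    ``pos_5prime`` is the 0-based position of the read's 5' end on the
    target's forward coordinates (leftmost base for sense reads, rightmost
    for antisense reads). ``weight`` supports pre-collapsed identical-read
    tables.
    """

    read_id: str
    target_copy: str
    pos_5prime: int
    strand: str  # "sense" | "antisense"
    read_length: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.strand not in ("sense", "antisense"):
            raise ValueError(f"strand must be sense/antisense, got {self.strand!r}")
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")


@dataclass
class FamilyCountMatrix:
    """Families x samples count matrix with an orientation tag."""

    counts: pd.DataFrame
    orientation: str = "both"

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("family/sample labels must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="family")

    @classmethod
    def from_tsv(cls, path: str | Path, orientation: str = "both") -> "FamilyCountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="family", comment="#")
        return cls(counts=df, orientation=orientation)


def count_by_family(
    alignments: Iterable[AlignmentRecord],
    copy_to_family: Mapping[str, str],
    orientation: str = "both",
    families: Iterable[str] | None = None,
) -> pd.Series:
    """Sum alignment weights per family (one count-matrix column).

    Families without alignments report 0. All ``target_copy`` values must be
    present in *copy_to_family*; unknown copies raise ``KeyError`` listing
    them. With ``orientation="both"``, the column total equals the summed
    weight of all alignments.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    if families is None:
        families = sorted(set(copy_to_family.values()))
    totals = {fam: 0.0 for fam in families}
    unknown = set()
    for aln in alignments:
        fam = copy_to_family.get(aln.target_copy)
        if fam is None:
            unknown.add(aln.target_copy)
            continue
        if orientation != "both" and aln.strand != orientation:
            continue
        totals[fam] = totals.get(fam, 0.0) + aln.weight
    if unknown:
        raise KeyError(f"alignments reference copies absent from the library: {sorted(unknown)}")
    return pd.Series(totals, name=orientation).sort_index()


def read_sam_alignments(path: str | Path, library_copies: set[str] | None = None) -> list[AlignmentRecord]:
    """Read primary alignments from a SAM/BAM file.

    Unmapped, secondary and supplementary records are skipped. A read on the
    reverse strand is antisense to the TE copy and its 5' end is the
    rightmost aligned base. If *library_copies* is given, the header's
    reference names must be a subset of it.
    """
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        refs = set(sam.references)
        if library_copies is not None:
            extra = refs - set(library_copies)
            if extra:
                raise ValueError(
                    f"SAM header references not in the TE library: {sorted(extra)[:5]}"
                )
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_reverse:
                strand = "antisense"
                pos5 = aln.reference_end - 1
            else:
                strand = "sense"
                pos5 = aln.reference_start
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    target_copy=aln.reference_name,
                    pos_5prime=pos5,
                    strand=strand,
                    read_length=aln.query_length or aln.infer_read_length() or 0,
                )
            )
    return records


def read_alignment_tsv(path: str | Path) -> list[AlignmentRecord]:
    """Read alignments from the simplified tabular format.

    Columns: read_id, target_copy, pos_5prime, strand, read_length and an
    optional weight (default 1).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "weight" not in df.columns:
        df["weight"] = 1.0
    return [
        AlignmentRecord(
            read_id=str(row.read_id),
            target_copy=str(row.target_copy),
            pos_5prime=int(row.pos_5prime),
            strand=str(row.strand),
            read_length=int(row.read_length),
            weight=float(row.weight),
        )
        for row in df.itertuples(index=False)
    ]


def build_count_matrix(
    columns: Mapping[str, pd.Series], orientation: str = "both"
) -> FamilyCountMatrix:
    """Assemble per-sample count columns into a :class:`FamilyCountMatrix`."""
    df = pd.DataFrame(columns).fillna(0.0)
    return FamilyCountMatrix(counts=df, orientation=orientation)
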