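"""piRNA processing: size selection, miRNA normalization, ping-pong signature.

piRNAs are 23-30 nt germline small RNAs; the secondary ("ping-pong")
amplification cycle produces sense/antisense piRNA pairs whose 5' ends
overlap by exactly 10 nt. Its statistical footprint in a read set is an
enrichment of the 10-nt bin of the sense/antisense 5'-overlap histogram; the
signature is called significant when the z-score of that bin against the
other overlap lengths exceeds 2.58 (two-sided normal 1% point).

Read tables are pandas DataFrames with columns ``family``, ``strand``
(sense/antisense relative to the TE consensus), ``pos_5prime`` (0-based
forward-strand coordinate of the 5' base; for an antisense read this is its
rightmost covered base), ``read_length`` and ``weight``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SmallRNARead",
    "PingPongResult",
    "READ_COLUMNS",
    "reads_to_frame",
    "filter_pirna_size",
    "normalize_by_mirna",
    "fold_difference_flags",
    "overlap_histogram",
    "pingpong_zscore",
    "family_pingpong",
    "count_reads_by_family",
]

READ_COLUMNS = ("family", "strand", "pos_5prime", "read_length", "weight")

PIRNA_MIN_LEN = 23
PIRNA_MAX_LEN = 30
PINGPONG_Z_THRESHOLD = 2.58


@dataclass(frozen=True)
class SmallRNARead:
    family: str
    strand: str  # sense | antisense
    pos_5prime: int
    read_length: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.strand not in ("sense", "antisense"):
            raise ValueError(f"strand must be sense/antisense, got {self.strand!r}")
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")


@dataclass(frozen=True)
class PingPongResult:
    """Overlap-10 enrichment z-score and its significance call."""

    z10: float
    significant: bool
    degenerate: bool  # background sd == 0 (or empty histogram)


def reads_to_frame(reads) -> pd.DataFrame:
    """Normalize a read collection to the standard DataFrame layout."""
    if isinstance(reads, pd.DataFrame):
        df = reads.copy()
        if "weight" not in df.columns:
            df["weight"] = 1.0
        return df[list(READ_COLUMNS)]
    return pd.DataFrame(
        [(r.family, r.strand, r.pos_5prime, r.read_length, r.weight) for r in reads],
        columns=list(READ_COLUMNS),
    )


def filter_pirna_size(reads, min_len: int = PIRNA_MIN_LEN, max_len: int = PIRNA_MAX_LEN) -> pd.DataFrame:
    """Retain reads with min_len <= length <= max_len (both inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    df = reads_to_frame(reads)
    return df[(df["read_length"] >= min_len) & (df["read_length"] <= max_len)].reset_index(drop=True)


def normalize_by_mirna(raw_counts, mirna_totals, scale: float = 1e6) -> pd.DataFrame:
    """Normalize small-RNA counts by per-sample miRNA-mapped read totals.

    abundance = raw * scale / mirna_total, i.e. reads per *scale* (default
    per-million) miRNA-mapped reads. *mirna_totals* maps sample -> positive
    total; a zero or negative total is an error.
    """
    df = raw_counts.counts if hasattr(raw_counts, "counts") else raw_counts
    totals = pd.Series(mirna_totals).reindex(df.columns)
    if totals.isna().any():
        missing = list(df.columns[totals.isna()])
        raise ValueError(f"miRNA totals missing for samples: {missing}")
    if (totals <= 0).any():
        bad = list(df.columns[totals <= 0])
        raise ValueError(f"miRNA totals must be > 0; offending samples: {bad}")
    return df * scale / totals


def fold_difference_flags(norm_a, norm_b, fold: float = 2.0, pseudo: float = 1.0):
    """Flag families whose normalized piRNA abundance differs >= *fold*-fold.

    Returns "higher_in_A" when (A + pseudo)/(B + pseudo) >= fold,
    "higher_in_B" symmetrically, else "similar". Scalar inputs return a
    string; array-likes return a numpy array of flags.
    """
    a = np.asarray(norm_a, dtype=float)
    b = np.asarray(norm_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("abundances must be >= 0")
    ratio = (a + pseudo) / (b + pseudo)
    flags = np.where(ratio >= fold, "higher_in_A", np.where(ratio <= 1.0 / fold, "higher_in_B", "similar"))
    if flags.ndim == 0:
        return str(flags)
    return flags


def overlap_histogram(sense, antisense, max_overlap: int = 30) -> pd.Series:
    """Weighted tally of sense/antisense 5'-end overlaps.

    For a sense read s and an antisense read a (both 5' positions in forward
    coordinates), the overlap is ``o = a.pos_5prime - s.pos_5prime + 1``;
    weight(s) x weight(a) is tallied into bin o for o in [1, max_overlap].
    o = 10 is the canonical ping-pong pair. Pairs outside the range are
    ignored.
    """
    s = reads_to_frame(sense)
    a = reads_to_frame(antisense)
    hist = np.zeros(max_overlap + 1)
    if len(s) and len(a):
        s_w = s.groupby("pos_5prime")["weight"].sum()
        a_w = a.groupby("pos_5prime")["weight"].sum()
        a_map = a_w.to_dict()
        for pos, w in s_w.items():
            for o in range(1, max_overlap + 1):
                aw = a_map.get(pos + o - 1)
                if aw is not None:
                    hist[o] += w * aw
    return pd.Series(hist[1:], index=pd.RangeIndex(1, max_overlap + 1, name="overlap"), name="pairs")


def pingpong_zscore(hist: pd.Series, threshold: float = PINGPONG_Z_THRESHOLD) -> PingPongResult:
    """z-score of the 10-nt overlap bin against all other overlap lengths.

    z10 = (h[10] - mean(h[o != 10])) / population sd(h[o != 10]). A zero
    background sd (including the all-zero histogram) yields a degenerate,
    non-significant result.
    """
    h = hist.astype(float)
    if 10 not in h.index:
        raise ValueError("histogram must cover overlap length 10")
    background = h.drop(index=10).to_numpy()
    sd = background.std()  # population sd
    if sd == 0:
        # flat background: a perfectly uniform histogram has no enrichment
        # (z10 = 0); any deviation of the 10-nt bin is unquantifiable
        z10 = 0.0 if h.loc[10] == background.mean() else float("nan")
        return PingPongResult(z10=z10, significant=False, degenerate=True)
    z10 = float((h.loc[10] - background.mean()) / sd)
    return PingPongResult(z10=z10, significant=z10 > threshold, degenerate=False)


def family_pingpong(
    reads,
    min_len: int = PIRNA_MIN_LEN,
    max_len: int = PIRNA_MAX_LEN,
    max_overlap: int = 30,
    threshold: float = PINGPONG_Z_THRESHOLD,
) -> pd.DataFrame:
    """Per-family ping-pong signature over size-selected reads.

    Returns a DataFrame indexed by family with ``z10``, ``significant`` and
    ``degenerate`` columns.
    """
    df = filter_pirna_size(reads, min_len, max_len)
    rows = {}
    for family, group in df.groupby("family"):
        hist = overlap_histogram(
            group[group["strand"] == "sense"],
            group[group["strand"] == "antisense"],
            max_overlap=max_overlap,
        )
        res = pingpong_zscore(hist, threshold=threshold)
        rows[family] = {"z10": res.z10, "significant": res.significant, "degenerate": res.degenerate}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "family"
    return out.sort_index()


def count_reads_by_family(reads, orientation: str = "both") -> pd.Series:
    """Sum read weights per family, optionally restricted to one strand."""
    df = reads_to_frame(reads)
    if orientation != "both":
        df = df[df["strand"] == orientation]
    return df.groupby("family")["weight"].sum()
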