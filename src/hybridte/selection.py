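"""Pairwise selection screening of protein-coding genes.

Implements Nei-Gojobori (1986) counting of synonymous (S) and nonsynonymous
(N) sites and differences on a two-sequence codon alignment, with
Jukes-Cantor multiple-hit correction, the resulting dN/dS ratio (omega), a
relaxed-selection classification (omega > 0.3), and a generic likelihood-
ratio-test comparator for externally computed site-model log-likelihoods.

Site counting uses mutational-fate fractions: at each codon position the
synonymous fraction is the share of the three possible single-base changes
that preserve the amino acid; changes creating stop codons count as
nonsynonymous, so S + N = 3 x (compared codons) exactly. Codons differing at
several positions are resolved by averaging over all minimal substitution
pathways, excluding pathways that pass through a stop codon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Data import CodonTable
from scipy import stats

__all__ = [
    "CodonAlignmentPair",
    "DnDsResult",
    "LRTResult",
    "GENETIC_CODE",
    "ng86_dnds",
    "classify_selection",
    "lrt",
    "jukes_cantor",
]

_BASES = "ACGT"
_table = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid for the universal genetic code, stops as "*"
GENETIC_CODE = {**_table.forward_table, **{c: "*" for c in _table.stop_codons}}

RELAXED_OMEGA_THRESHOLD = 0.3


def _syn_site_fraction(codon: str) -> float:
    """Synonymous-site count of one codon (mutational-fate fractions).

    Sum over the three positions of (synonymous single-base changes)/3;
    changes to stop codons are nonsynonymous.
    """
    aa = GENETIC_CODE[codon]
    syn = 0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if GENETIC_CODE[alt] == aa and GENETIC_CODE[alt] != "*":
                syn += 1
    return syn / 3.0


_SYN_SITES = {c: _syn_site_fraction(c) for c in GENETIC_CODE if GENETIC_CODE[c] != "*"}


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged over all minimal substitution pathways; pathways through stop
    codons are excluded (if every pathway is blocked, all are used).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        current = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1:]
            if GENETIC_CODE[current] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            if GENETIC_CODE[nxt] == "*" and nxt != c2:
                through_stop = True
            current = nxt
        (blocked if through_stop else valid).append((sd, nd))
    paths = valid if valid else blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


@dataclass(frozen=True)
class CodonAlignmentPair:
    """Aligned CDS pair for one gene (equal length, divisible by 3)."""

    gene: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(f"{self.gene}: aligned sequences differ in length")
        if len(self.seq_a) % 3 != 0:
            raise ValueError(f"{self.gene}: alignment length not divisible by 3")


@dataclass(frozen=True)
class DnDsResult:
    gene: str
    n_codons: int  # comparable (ungapped, unambiguous) codons
    S: float  # synonymous sites (average of the two sequences)
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences
    pS: float
    pN: float
    dS: float  # JC-corrected (NaN when saturated or S == 0)
    dN: float
    omega: float  # dN/dS, NaN when dS == 0 or undefined


@dataclass(frozen=True)
class LRTResult:
    stat: float
    df: int
    pvalue: float
    significant: bool


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - 4p/3); NaN when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _comparable_codons(pair: CodonAlignmentPair) -> list[tuple[int, str, str]]:
    n = len(pair.seq_a) // 3
    out = []
    for k in range(n):
        ca = pair.seq_a[3 * k: 3 * k + 3].upper()
        cb = pair.seq_b[3 * k: 3 * k + 3].upper()
        if any(b not in _BASES for b in ca + cb):
            continue  # gap or ambiguity: excluded pairwise
        stop_a = GENETIC_CODE[ca] == "*"
        stop_b = GENETIC_CODE[cb] == "*"
        if stop_a or stop_b:
            if k == n - 1:
                continue  # terminal stop codon: not compared
            raise ValueError(f"{pair.gene or 'alignment'}: internal stop codon at codon index {k}")
        out.append((k, ca, cb))
    return out


def ng86_dnds(pair: CodonAlignmentPair) -> DnDsResult:
    """Nei-Gojobori (1986) pairwise dN/dS with Jukes-Cantor correction.

    Sites are counted per sequence and averaged; differences are averaged
    over minimal substitution pathways (stop-crossing pathways excluded).
    omega is NaN (flagged undefined) when dS is 0 or either rate is
    saturated (p >= 3/4). Raises on an internal stop codon or when no codon
    is comparable.
    """
    codons = _comparable_codons(pair)
    if not codons:
        raise ValueError(f"{pair.gene or 'alignment'}: no comparable codons")
    s_sites_a = sum(_SYN_SITES[ca] for _, ca, _ in codons)
    s_sites_b = sum(_SYN_SITES[cb] for _, _, cb in codons)
    S = (s_sites_a + s_sites_b) / 2.0
    N = 3.0 * len(codons) - S
    Sd = Nd = 0.0
    for _, ca, cb in codons:
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else float("nan")
    pN = Nd / N if N > 0 else float("nan")
    dS = jukes_cantor(pS) if S > 0 else float("nan")
    dN = jukes_cantor(pN) if N > 0 else float("nan")
    if not math.isnan(dS) and dS > 0 and not math.isnan(dN):
        omega = dN / dS
    else:
        omega = float("nan")
    return DnDsResult(
        gene=pair.gene, n_codons=len(codons), S=S, N=N, Sd=Sd, Nd=Nd,
        pS=pS, pN=pN, dS=dS, dN=dN, omega=omega,
    )


def classify_selection(omega: float, threshold: float = RELAXED_OMEGA_THRESHOLD) -> str | None:
    """Classify a pairwise omega estimate.

    purifying (omega <= threshold), relaxed (threshold < omega <= 1),
    positive_candidate (omega > 1). An undefined (NaN) omega returns None.
    """
    if omega is None or math.isnan(omega):
        return None
    if omega > 1.0:
        return "positive_candidate"
    if omega > threshold:
        return "relaxed"
    return "purifying"


def lrt(lnl_null: float, lnl_alt: float, df: int = 2, alpha: float = 0.02) -> LRTResult:
    """Likelihood-ratio test of nested site models.

    stat = max(0, 2 (lnL_alt - lnL_null)), compared to the chi-square upper
    tail with *df* degrees of freedom; significant iff p < alpha.
    """
    if df <= 0:
        raise ValueError("df must be a positive integer")
    if not (math.isfinite(lnl_null) and math.isfinite(lnl_alt)):
        raise ValueError("log-likelihoods must be finite")
    stat = max(0.0, 2.0 * (lnl_alt - lnl_null))
    pvalue = float(stats.chi2.sf(stat, df=df))
    return LRTResult(stat=stat, df=df, pvalue=pvalue, significant=pvalue < alpha)
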