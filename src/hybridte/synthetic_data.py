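"""Synthetic inputs with known ground truth for every pipeline stage.

Generators emulate, at desk scale, the statistical structure of the study's
real inputs so the whole pipeline is testable without downloads:

* :func:`gen_repeatmasker_annotations` — RepeatMasker ``.out`` files for the
  two parental genomes, containing clean TE insertions, fragmented LTR
  elements (flank/internal/flank triples and block-split fragments),
  sub-100-nt insertions, non-TE repeat classes, and species-suffixed family
  names, together with the curated library the curation stage must recover
  exactly.
* :func:`gen_count_matrix` — negative-binomial RNA-seq counts for the two
  parents and the two reciprocal hybrids with a known per-family expression
  category (parent-like / additive / deregulated / not_de).
* :func:`gen_two_group_counts` — a plain two-condition NB design with a
  known DE fraction, for FDR/power characterization.
* :func:`gen_smallrna` — per-family sense/antisense small-RNA 5'-position
  tables with a tunable ping-pong (exact 10-nt 5' overlap) pair fraction,
  contaminating read lengths outside 23-30 nt, and per-sample miRNA totals.
* :func:`gen_codon_pair` — a gapless codon alignment evolved at a known
  omega (synonymous proposals accepted at rate 1, nonsynonymous at rate
  omega, stops rejected).

All generators are deterministic in (design, seed): the same arguments give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .selection import GENETIC_CODE, CodonAlignmentPair
from .telibrary import TEInsertion, classify_te_order

__all__ = [
    "SimulationDesign",
    "AnnotationDesign",
    "gen_repeatmasker_annotations",
    "gen_count_matrix",
    "gen_two_group_counts",
    "gen_smallrna",
    "gen_codon_pair",
    "GENOTYPES",
]

GENOTYPES = ("Dari", "Dmwri", "H_mw_a", "H_a_mw")
HYBRIDS = ("H_mw_a", "H_a_mw")

CATEGORY_CHOICES = (
    "not_de",
    "parentA_like",
    "parentW_like",
    "additive",
    "deregulated_over",
    "deregulated_under",
)

_SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


# ---------------------------------------------------------------------------
# RepeatMasker annotations
# ---------------------------------------------------------------------------

_ORDER_CLASSES = {
    "LTR": "LTR/Gypsy",
    "LINE": "LINE/Jockey",
    "TIR": "DNA/TcMar-Tc1",
    "RC": "RC/Helitron",
}
_FAMILY_STEMS = {
    "LTR": ("Gypsy", "Copia"),
    "LINE": ("Jockey", "BS"),
    "TIR": ("BARI", "REP"),
    "RC": ("Helitron",),
}
_NONTE_CLASSES = ("Simple_repeat", "Satellite", "Low_complexity", "tRNA", "rRNA", "Unknown")
_SPECIES_SUFFIX = {"Dmoj": "-Dmoj", "Dari": "-Dari"}

_RM_HEADER = (
    "   SW   perc perc perc  query     position in query    matching repeat        position in repeat\n"
    "score   div. del. ins.  sequence  begin end   (left)   repeat   class/family  begin end (left)  ID\n"
    "\n"
)


@dataclass
class AnnotationDesign:
    """Composition of a synthetic two-genome RepeatMasker annotation set."""

    n_shared_families: int = 8
    n_exclusive_dmoj: int = 3
    n_exclusive_dari: int = 2
    copies_per_family: int = 2
    n_fragmented_ltr: int = 2  # LTR flank/internal/flank triples per species
    n_block_split: int = 2  # insertions split into 2 fragments sharing an ID
    n_short: int = 3  # sub-100-nt insertions (curated away)
    n_nonte: int = 4  # banned-class records per species
    n_suffixed: int = 3  # insertions written with a species-suffixed name
    element_len: int = 1500
    spacing: int = 6000  # > merge gap so distinct elements never merge


def _family_list(design: AnnotationDesign) -> tuple[list, list, list]:
    """Deterministic family name/order assignment (shared, Dmoj-only, Dari-only)."""
    def make(n: int, tag: str) -> list[tuple[str, str]]:
        fams = []
        orders = list(_FAMILY_STEMS)
        for i in range(n):
            order = orders[i % len(orders)]
            stem = _FAMILY_STEMS[order][i % len(_FAMILY_STEMS[order])]
            fams.append((f"{stem}-{tag}{i + 1}", order))
        return fams

    return make(design.n_shared_families, "S"), make(design.n_exclusive_dmoj, "M"), make(design.n_exclusive_dari, "A")


def gen_repeatmasker_annotations(
    design: AnnotationDesign | None = None, seed: int = 0
) -> tuple[dict, dict]:
    """Generate ``.out`` text per species plus the curated-library truth.

    Returns ``(out_texts, truth)`` where ``out_texts`` maps species ->
    RepeatMasker ``.out`` file content and ``truth`` contains:

    * ``insertions``: species -> list of :class:`TEInsertion` the curation
      stage must recover (0-based half-open spans);
    * ``families``: family -> {"te_order", "present_in"};
    * ``tallies``: expected shared/exclusive family counts.
    """
    design = design or AnnotationDesign()
    rng = np.random.default_rng(seed)
    shared, excl_m, excl_a = _family_list(design)
    species_families = {
        "Dmoj": shared + excl_m,
        "Dari": shared + excl_a,
    }

    out_texts: dict[str, str] = {}
    truth_insertions: dict[str, list[TEInsertion]] = {}
    for species, fam_list in species_families.items():
        lines: list[str] = []
        kept: list[TEInsertion] = []
        cursor = 1000
        block = 1
        scaffold = f"{species}_scf1"

        def emit(name, cls, begin, end, strand, block_id):
            div = rng.uniform(1.0, 25.0)
            lines.append(
                f"{rng.integers(200, 5000):5d} {div:5.1f}  {rng.uniform(0,5):4.1f}  {rng.uniform(0,5):4.1f}  "
                f"{scaffold} {begin} {end} (0) {'+' if strand == '+' else 'C'} "
                f"{name} {cls} 1 {end - begin + 1} (0) {block_id}"
            )

        # queue of special roles to distribute over insertions
        ltr_left = design.n_fragmented_ltr
        split_left = design.n_block_split
        suffix_left = design.n_suffixed
        for fam, order in fam_list:
            cls = _ORDER_CLASSES[order]
            for _copy in range(design.copies_per_family):
                strand = "+" if rng.random() < 0.5 else "-"
                begin = cursor
                length = design.element_len + int(rng.integers(0, 500))
                if order == "LTR" and ltr_left > 0:
                    # flank / internal / flank, separate blocks, gaps < merge gap
                    ltr_left -= 1
                    ltr_len = 250
                    gap = 40
                    int_len = length
                    b1, e1 = begin, begin + ltr_len - 1
                    b2, e2 = e1 + gap + 1, e1 + gap + int_len
                    b3, e3 = e2 + gap + 1, e2 + gap + ltr_len
                    emit(f"{fam}_LTR", cls, b1, e1, strand, block)
                    emit(f"{fam}-int", cls, b2, e2, strand, block + 1)
                    emit(f"{fam}_LTR", cls, b3, e3, strand, block + 2)
                    block += 3
                    end = e3
                elif split_left > 0:
                    split_left -= 1
                    mid = begin + length // 2
                    emit(fam, cls, begin, mid, strand, block)
                    emit(fam, cls, mid + 30, begin + length - 1, strand, block)
                    block += 1
                    end = begin + length - 1
                else:
                    name = fam
                    if suffix_left > 0:
                        suffix_left -= 1
                        name = fam + _SPECIES_SUFFIX[species]
                    emit(name, cls, begin, begin + length - 1, strand, block)
                    block += 1
                    end = begin + length - 1
                kept.append(
                    TEInsertion(
                        insertion_id=f"{species}:{scaffold}:{begin - 1}-{end}:{strand}",
                        family=fam,
                        te_order=order,
                        scaffold=scaffold,
                        start=begin - 1,
                        end=end,
                        strand=strand,
                        source_species=species,
                    )
                )
                cursor = end + design.spacing

        # sub-100-nt insertions of existing families: curated away
        for i in range(design.n_short):
            fam, order = fam_list[i % len(fam_list)]
            short_len = int(rng.integers(40, 100))
            emit(fam, _ORDER_CLASSES[order], cursor, cursor + short_len - 1, "+", block)
            block += 1
            cursor += short_len + design.spacing

        # non-TE repeats: curated away
        for i in range(design.n_nonte):
            cls = _NONTE_CLASSES[i % len(_NONTE_CLASSES)]
            name = "(ATCG)n" if cls == "Simple_repeat" else f"{cls}_rep{i}"
            emit(name, cls, cursor, cursor + 400, "+", block)
            block += 1
            cursor += 400 + design.spacing

        out_texts[species] = _RM_HEADER + "\n".join(lines) + "\n"
        truth_insertions[species] = kept

    families: dict[str, dict] = {}
    for species, insertions in truth_insertions.items():
        for ins in insertions:
            fam = families.setdefault(ins.family, {"te_order": ins.te_order, "present_in": set()})
            fam["present_in"].add(species)
    shared_n = sum(1 for f in families.values() if len(f["present_in"]) == 2)
    tallies = {
        "shared": shared_n,
        "exclusive_Dmoj": sum(1 for f in families.values() if f["present_in"] == {"Dmoj"}),
        "exclusive_Dari": sum(1 for f in families.values() if f["present_in"] == {"Dari"}),
    }
    truth = {"insertions": truth_insertions, "families": families, "tallies": tallies}
    return out_texts, truth


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


@dataclass
class SimulationDesign:
    """Parent/hybrid NB count design with known category structure.

    ``effect_lfc`` is the log2 separation between any two distinct
    expression levels in the design (parents differ by it for parent-like
    families, each parent sits ``effect_lfc`` from the additive hybrid, and
    deregulated hybrids sit ``effect_lfc`` beyond both parents).
    """

    n_families: int = 300
    category_probs: dict = field(
        default_factory=lambda: {
            "not_de": 0.40,
            "parentA_like": 0.18,
            "parentW_like": 0.18,
            "additive": 0.12,
            "deregulated_over": 0.06,
            "deregulated_under": 0.06,
        }
    )
    effect_lfc: float = 2.0
    mean_range: tuple = (100.0, 800.0)
    dispersion: float = 0.05
    n_replicates: int = 3
    seed: int = 0


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, alpha) with Var = mu + alpha mu^2 via gamma-Poisson mixture."""
    if alpha <= 0:
        return rng.poisson(mean)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mean * alpha)
    return rng.poisson(lam)


def gen_count_matrix(design: SimulationDesign | None = None):
    """NB counts for 4 genotypes x replicates with known category structure.

    Parent A is *D. arizonae* (``Dari``), parent W is *D. m. wrigleyi*
    (``Dmwri``). Per category (e = effect_lfc, mu = baseline mean):

    * not_de:            A = W = H = mu
    * parentA_like:      W = mu, A = mu * 2^(+-e), H = A
    * parentW_like:      A = mu, W = mu * 2^(+-e), H = W
    * additive:          A = mu * 2^e, W = mu * 2^-e, H = mu (geometric mean)
    * deregulated_over:  A = W = mu, H = mu * 2^e
    * deregulated_under: A = W = mu, H = mu * 2^-e

    Both reciprocal hybrids share the same per-family mean. Returns
    ``(counts, truth, samples)``: a families x samples DataFrame, a truth
    DataFrame (category and the per-genotype means), and a sample sheet.
    """
    design = design or SimulationDesign()
    rng = np.random.default_rng(design.seed)
    cats = list(design.category_probs)
    probs = np.array([design.category_probs[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    categories = rng.choice(cats, size=design.n_families, p=probs)
    mu = np.exp(rng.uniform(np.log(design.mean_range[0]), np.log(design.mean_range[1]), design.n_families))
    sign = rng.choice([-1.0, 1.0], size=design.n_families)
    e = design.effect_lfc

    mean_a = mu.copy()
    mean_w = mu.copy()
    mean_h = mu.copy()
    for i, cat in enumerate(categories):
        if cat == "parentA_like":
            mean_a[i] = mu[i] * 2 ** (sign[i] * e)
            mean_h[i] = mean_a[i]
        elif cat == "parentW_like":
            mean_w[i] = mu[i] * 2 ** (sign[i] * e)
            mean_h[i] = mean_w[i]
        elif cat == "additive":
            mean_a[i] = mu[i] * 2**e
            mean_w[i] = mu[i] * 2**-e
        elif cat == "deregulated_over":
            mean_h[i] = mu[i] * 2**e
        elif cat == "deregulated_under":
            mean_h[i] = mu[i] * 2**-e

    genotype_means = {"Dari": mean_a, "Dmwri": mean_w, "H_mw_a": mean_h, "H_a_mw": mean_h}
    columns = {}
    sample_rows = []
    for genotype in GENOTYPES:
        for rep in range(1, design.n_replicates + 1):
            name = f"{genotype}_r{rep}"
            columns[name] = _nb_draw(rng, genotype_means[genotype], design.dispersion)
            sample_rows.append({"sample_id": name, "genotype": genotype, "replicate": rep})

    families = [f"fam{i:04d}" for i in range(design.n_families)]
    counts = pd.DataFrame(columns, index=pd.Index(families, name="family"))
    truth = pd.DataFrame(
        {
            "category": categories,
            "mean_Dari": mean_a,
            "mean_Dmwri": mean_w,
            "mean_hybrid": mean_h,
        },
        index=counts.index,
    )
    samples = pd.DataFrame(sample_rows)
    return counts, truth, samples


def gen_two_group_counts(
    n_families: int = 2000,
    frac_de: float = 0.0,
    lfc: float = 2.0,
    mean_range: tuple = (100.0, 800.0),
    dispersion: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
):
    """Two-condition NB design with a known DE fraction.

    A fraction *frac_de* of families gets a true log2 fold change of
    +-*lfc* (random sign) between groups A and B. Returns ``(counts, truth)``
    with sample columns ``A_r*``/``B_r*`` and truth columns ``is_de`` and
    ``true_lfc``.
    """
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), n_families))
    is_de = rng.random(n_families) < frac_de
    true_lfc = np.where(is_de, rng.choice([-1.0, 1.0], n_families) * lfc, 0.0)
    mean_a = mu
    mean_b = mu * 2**true_lfc
    columns = {}
    for rep in range(1, n_replicates + 1):
        columns[f"A_r{rep}"] = _nb_draw(rng, mean_a, dispersion)
    for rep in range(1, n_replicates + 1):
        columns[f"B_r{rep}"] = _nb_draw(rng, mean_b, dispersion)
    families = [f"fam{i:04d}" for i in range(n_families)]
    counts = pd.DataFrame(columns, index=pd.Index(families, name="family"))
    truth = pd.DataFrame({"is_de": is_de, "true_lfc": true_lfc}, index=counts.index)
    return counts, truth


# ---------------------------------------------------------------------------
# Small RNA reads
# ---------------------------------------------------------------------------


def gen_smallrna(
    families: list[str],
    n_pairs: int = 500,
    pingpong_fraction: float = 0.5,
    seed: int = 0,
    position_range: int = 20000,
    contaminant_fraction: float = 0.2,
    samples: list[str] | None = None,
):
    """Sense/antisense small-RNA read tables with a known ping-pong fraction.

    Per family, *n_pairs* sense/antisense read pairs are placed: a fraction
    *pingpong_fraction* with an exact 10-nt 5' overlap, the rest with
    overlaps uniform on [1, 30] \\ {10}. Read lengths are uniform on
    [23, 30]; an extra *contaminant_fraction* x n_pairs reads carry lengths
    in 18-22 / 31-35 nt so the size filter is always exercised. Per-sample
    miRNA-mapped totals (~1e6) are drawn for normalization.

    Returns ``(reads, mirna_totals, truth)``: a read DataFrame (family,
    strand, pos_5prime, read_length, weight), a Series of miRNA totals and a
    per-family truth DataFrame.
    """
    if not 0.0 <= pingpong_fraction <= 1.0:
        raise ValueError("pingpong_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    samples = samples or ["s1"]
    background_overlaps = np.array([o for o in range(1, 31) if o != 10])
    rows = []
    for family in families:
        n_pp = int(round(pingpong_fraction * n_pairs))
        offsets = np.concatenate(
            [
                np.full(n_pp, 10),
                rng.choice(background_overlaps, size=n_pairs - n_pp),
            ]
        )
        sense_pos = rng.integers(0, position_range, size=n_pairs)
        anti_pos = sense_pos + offsets - 1
        lengths = rng.integers(23, 31, size=2 * n_pairs)
        for p, ln in zip(sense_pos, lengths[:n_pairs]):
            rows.append((family, "sense", int(p), int(ln), 1.0))
        for p, ln in zip(anti_pos, lengths[n_pairs:]):
            rows.append((family, "antisense", int(p), int(ln), 1.0))
        n_cont = int(round(contaminant_fraction * n_pairs))
        cont_lengths = rng.choice(np.concatenate([np.arange(18, 23), np.arange(31, 36)]), size=n_cont)
        cont_pos = rng.integers(0, position_range, size=n_cont)
        cont_strand = rng.choice(["sense", "antisense"], size=n_cont)
        for p, ln, st in zip(cont_pos, cont_lengths, cont_strand):
            rows.append((family, str(st), int(p), int(ln), 1.0))
    reads = pd.DataFrame(rows, columns=["family", "strand", "pos_5prime", "read_length", "weight"])
    mirna_totals = pd.Series(
        rng.integers(800_000, 1_200_000, size=len(samples)).astype(float), index=samples, name="mirna_total"
    )
    truth = pd.DataFrame(
        {"pingpong_fraction": pingpong_fraction, "n_pairs": n_pairs},
        index=pd.Index(families, name="family"),
    )
    return reads, mirna_totals, truth


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------


def gen_codon_pair(
    omega: float,
    branch_length: float = 0.2,
    n_codons: int = 3000,
    seed: int = 0,
    gene: str = "synthetic",
) -> tuple[CodonAlignmentPair, dict]:
    """Evolve a gapless codon-alignment pair at a known omega.

    The ancestor is drawn uniformly over the 61 sense codons; one lineage
    accumulates ``Poisson(branch_length * n_codons)`` accepted substitutions
    (so *branch_length* is the expected pairwise divergence in substitutions
    per codon). Single-base changes are proposed uniformly; synonymous
    proposals are accepted with relative rate 1, nonsynonymous with rate
    *omega*, and changes to stop codons are rejected.

    Returns the alignment pair plus a truth dict (omega, counts of accepted
    synonymous/nonsynonymous substitutions).
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    codons = [
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    ]
    seq_a = "".join(codons)
    derived = list(codons)
    n_target = int(rng.poisson(branch_length * n_codons))
    accepted = n_syn = n_nonsyn = 0
    bases = "ACGT"
    while accepted < n_target:
        k = int(rng.integers(0, n_codons))
        pos = int(rng.integers(0, 3))
        codon = derived[k]
        new_base = bases[int(rng.integers(0, 4))]
        if new_base == codon[pos]:
            continue
        candidate = codon[:pos] + new_base + codon[pos + 1:]
        if GENETIC_CODE[candidate] == "*":
            continue
        synonymous = GENETIC_CODE[candidate] == GENETIC_CODE[codon]
        if not synonymous and rng.random() >= omega:
            continue
        derived[k] = candidate
        accepted += 1
        if synonymous:
            n_syn += 1
        else:
            n_nonsyn += 1
    pair = CodonAlignmentPair(gene=gene, seq_a=seq_a, seq_b="".join(derived))
    truth = {
        "omega": omega,
        "branch_length": branch_length,
        "n_codons": n_codons,
        "n_substitutions": accepted,
        "n_synonymous": n_syn,
        "n_nonsynonymous": n_nonsyn,
    }
    return pair, truth
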