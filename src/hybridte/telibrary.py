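"""Curation of RepeatMasker repeat annotations into a two-species TE library.

The curation pipeline mirrors the standard practice for building a
transposable-element (TE) reference from RepeatMasker ``.out`` files of two
closely related genomes:

1. parse the ``.out`` table (:func:`parse_repeatmasker_out`);
2. drop annotations that are not TEs — simple/low-complexity repeats,
   satellites, structural RNAs, unclassified repeats
   (:func:`filter_non_te`);
3. merge fragments of the same insertion — fragments sharing a RepeatMasker
   block ID, and LTR flank / internal-region records of the same LTR element
   that lie adjacent on a scaffold (:func:`merge_fragments`);
4. drop merged insertions shorter than a minimum length (default 100 nt,
   :func:`filter_min_length`);
5. canonicalize family names by stripping trailing species suffixes such as
   ``-Dmoj`` so that homologous families from the two genomes collapse into
   one (:func:`canonical_family_name`);
6. combine the per-species insertion sets into a single library with
   shared/exclusive family accounting (:func:`build_library`).

Coordinates are 1-based inclusive in RepeatMasker files (kept as such on
:class:`RepeatRecord`) and 0-based half-open internally on
:class:`TEInsertion`; writers convert back.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, TextIO

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "RepeatRecord",
    "TEInsertion",
    "TEFamily",
    "TELibrary",
    "RepeatMaskerParseError",
    "DEFAULT_BANNED_CLASSES",
    "DEFAULT_SUFFIX_PATTERN",
    "parse_repeatmasker_out",
    "filter_non_te",
    "merge_fragments",
    "filter_min_length",
    "canonical_family_name",
    "classify_te_order",
    "build_library",
    "write_library_fasta",
    "family_table",
    "insertion_table",
]

VALID_SPECIES = ("Dmoj", "Dari")

#: Repeat classes removed during curation. Matching is on the top-level
#: class token (text before "/") as well as on the exact token, so both
#: "Simple_repeat" and "LTR/Gypsy"-style values behave as expected.
#: "(ATCG)n"-style nucleotide-enriched regions carry the Simple_repeat class
#: in RepeatMasker output and are covered by that token.
DEFAULT_BANNED_CLASSES = frozenset(
    {
        "Simple_repeat",
        "Satellite",
        "Low_complexity",
        "tRNA",
        "rRNA",
        "Unknown",
        "ARTEFACT",
    }
)

#: Trailing species-suffix token stripped from raw family names
#: (e.g. "Gypsy-1-Dmoj" -> "Gypsy-1").
DEFAULT_SUFFIX_PATTERN = r"-D[a-z]{3}$"

#: Maximum gap (nt) between an LTR flank and the internal region of the same
#: element for them to be merged into one insertion.
DEFAULT_MAX_GAP = 5000

_LTR_FLANK_RE = re.compile(r"^(?P<base>.+?)[-_](?:5'?|3'?)?LTR$", re.IGNORECASE)
_LTR_INTERNAL_RE = re.compile(r"^(?P<base>.+?)[-_](?:I|int)$", re.IGNORECASE)


class RepeatMaskerParseError(ValueError):
    """Raised for a malformed RepeatMasker .out data line."""


@dataclass(frozen=True)
class RepeatRecord:
    """One RepeatMasker annotation line (1-based inclusive coordinates)."""

    scaffold: str
    begin: int
    end: int
    strand: str
    repeat_name: str
    repeat_class: str
    divergence_pct: float
    block_id: str

    def __post_init__(self) -> None:
        if self.begin > self.end:
            raise ValueError(f"begin > end for {self.repeat_name}: {self.begin} > {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.divergence_pct < 0:
            raise ValueError("divergence_pct must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.begin + 1


@dataclass(frozen=True)
class TEInsertion:
    """A curated TE insertion (0-based half-open internal coordinates)."""

    insertion_id: str
    family: str
    te_order: str
    scaffold: str
    start: int
    end: int
    strand: str
    source_species: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TEFamily:
    name: str
    te_order: str
    present_in: set = field(default_factory=set)
    n_copies: dict = field(default_factory=dict)


@dataclass
class TELibrary:
    """Merged two-species TE library with shared/exclusive accounting."""

    families: dict  # name -> TEFamily
    insertions: list  # of TEInsertion
    tallies: dict  # {"shared": int, "exclusive_Dmoj": int, "exclusive_Dari": int}

    @property
    def n_families(self) -> int:
        return len(self.families)


def parse_repeatmasker_out(stream: TextIO | Iterable[str]) -> list[RepeatRecord]:
    """Parse a RepeatMasker ``.out`` stream into :class:`RepeatRecord` objects.

    The format has 3 header lines (two column-name lines and a blank line)
    followed by whitespace-delimited records. Strand ``C`` (complement) maps
    to ``-``. Positions are preserved 1-based inclusive.

    Raises :class:`RepeatMaskerParseError` naming the line number for any
    malformed data line.
    """
    records: list[RepeatRecord] = []
    for lineno, line in enumerate(stream, start=1):
        if lineno <= 3:
            continue  # header block
        stripped = line.strip()
        if not stripped:
            continue
        fields = stripped.split()
        if len(fields) < 15:
            raise RepeatMaskerParseError(
                f"line {lineno}: expected >= 15 whitespace-delimited fields, got {len(fields)}"
            )
        try:
            divergence = float(fields[1])
            begin = int(fields[5])
            end = int(fields[6])
        except ValueError as exc:
            raise RepeatMaskerParseError(f"line {lineno}: non-numeric coordinate field ({exc})") from None
        strand = fields[8]
        if strand == "C":
            strand = "-"
        if strand not in ("+", "-"):
            raise RepeatMaskerParseError(f"line {lineno}: unrecognized strand {fields[8]!r}")
        try:
            records.append(
                RepeatRecord(
                    scaffold=fields[4],
                    begin=begin,
                    end=end,
                    strand=strand,
                    repeat_name=fields[9],
                    repeat_class=fields[10],
                    divergence_pct=divergence,
                    block_id=fields[14],
                )
            )
        except ValueError as exc:
            raise RepeatMaskerParseError(f"line {lineno}: {exc}") from None
    return records


def filter_non_te(
    records: list[RepeatRecord],
    banned_classes: frozenset[str] | set[str] = DEFAULT_BANNED_CLASSES,
) -> list[RepeatRecord]:
    """Remove records whose repeat class is not a transposable element.

    A record is removed when its full class string, or its top-level token
    (text before the first ``/``), is in *banned_classes*. Order preserved.
    """
    banned = set(banned_classes)
    kept = []
    for rec in records:
        top = rec.repeat_class.split("/", 1)[0]
        if rec.repeat_class in banned or top in banned:
            continue
        kept.append(rec)
    return kept


def canonical_family_name(raw_name: str, suffix_pattern: str = DEFAULT_SUFFIX_PATTERN) -> str:
    """Strip trailing species-suffix tokens from a family name.

    ``"Gypsy-1-Dmoj" -> "Gypsy-1"``. Applied repeatedly so the result is
    idempotent even for doubly suffixed names.
    """
    pattern = re.compile(suffix_pattern)
    name = raw_name
    while True:
        stripped = pattern.sub("", name)
        if stripped == name or not stripped:
            return name if not stripped else stripped
        name = stripped


def classify_te_order(repeat_class: str) -> str:
    """Map a RepeatMasker class/family string to a TE order.

    LTR and LINE retrotransposons keep their names; DNA (TIR) transposons map
    to ``TIR``; rolling-circle Helitrons to ``RC``; everything else (SINEs,
    rare classes) to ``other``.
    """
    top = repeat_class.split("/", 1)[0]
    if top == "LTR":
        return "LTR"
    if top == "LINE":
        return "LINE"
    if top in ("DNA", "TIR"):
        return "TIR"
    if top == "RC":
        return "RC"
    return "other"


def _ltr_part(name: str) -> tuple[str, str]:
    """Split an LTR-element record name into (element base, part).

    part is "flank" for ``X_LTR``-style names, "internal" for ``X-int``-style
    names, and "whole" otherwise (base = name).
    """
    m = _LTR_FLANK_RE.match(name)
    if m:
        return m.group("base"), "flank"
    m = _LTR_INTERNAL_RE.match(name)
    if m:
        return m.group("base"), "internal"
    return name, "whole"


@dataclass
class _Fragment:
    scaffold: str
    strand: str
    start: int  # 0-based half-open
    end: int
    base: str
    parts: set
    repeat_class: str


def merge_fragments(
    records: list[RepeatRecord],
    species: str = "Dmoj",
    max_gap: int = DEFAULT_MAX_GAP,
    suffix_pattern: str = DEFAULT_SUFFIX_PATTERN,
) -> list[TEInsertion]:
    """Merge annotation fragments into TE insertions for one genome.

    Two merge rules (and only these) apply:

    * records sharing a RepeatMasker block ID on the same scaffold/strand
      are one insertion (fragments of one interrupted copy);
    * an LTR flank record (``X_LTR``) and the internal region of the same
      element (``X-int``/``X_I``) adjacent on the same scaffold/strand within
      *max_gap* nt merge into a single ``X`` insertion; chains
      (LTR–internal–LTR) collapse fully.

    Everything else becomes a singleton insertion. The merged span is the
    coordinate union of the inputs. Family names are canonicalized (species
    suffix stripped) on the way out.
    """
    # Pass 1: group by block_id within (scaffold, strand).
    by_block: dict[tuple, list[RepeatRecord]] = {}
    order: list[tuple] = []
    for i, rec in enumerate(records):
        key = (rec.scaffold, rec.strand, rec.block_id)
        if key not in by_block:
            by_block[key] = []
            order.append(key)
        by_block[key].append(rec)

    fragments: list[_Fragment] = []
    for key in order:
        group = by_block[key]
        start = min(r.begin for r in group) - 1
        end = max(r.end for r in group)
        # Prefer a non-flank name for the merged fragment's identity.
        bases = [_ltr_part(r.repeat_name) for r in group]
        parts = {p for _, p in bases}
        base_names = {b for b, _ in bases}
        base = sorted(base_names)[0]
        cls = group[0].repeat_class
        fragments.append(
            _Fragment(
                scaffold=key[0], strand=key[1], start=start, end=end,
                base=base, parts=parts, repeat_class=cls,
            )
        )

    # Pass 2: chain-merge adjacent LTR flank/internal fragments of one element.
    fragments.sort(key=lambda f: (f.scaffold, f.strand, f.start, f.end))
    merged: list[_Fragment] = []
    for frag in fragments:
        if merged:
            prev = merged[-1]
            same_locus = (
                prev.scaffold == frag.scaffold
                and prev.strand == frag.strand
                and frag.start - prev.end <= max_gap
            )
            pairable = prev.base == frag.base and (
                ("flank" in prev.parts and "internal" in frag.parts)
                or ("internal" in prev.parts and "flank" in frag.parts)
            )
            if same_locus and pairable:
                prev.end = max(prev.end, frag.end)
                prev.parts |= frag.parts
                continue
        merged.append(replace_fragment(frag))

    insertions = []
    for i, frag in enumerate(merged):
        family = canonical_family_name(frag.base, suffix_pattern)
        insertions.append(
            TEInsertion(
                insertion_id=f"{species}:{frag.scaffold}:{frag.start}-{frag.end}:{frag.strand}",
                family=family,
                te_order=classify_te_order(frag.repeat_class),
                scaffold=frag.scaffold,
                start=frag.start,
                end=frag.end,
                strand=frag.strand,
                source_species=species,
            )
        )
    return insertions


def replace_fragment(frag: _Fragment) -> _Fragment:
    # shallow copy so chain-merging never mutates the input list's objects
    return _Fragment(
        scaffold=frag.scaffold, strand=frag.strand, start=frag.start,
        end=frag.end, base=frag.base, parts=set(frag.parts),
        repeat_class=frag.repeat_class,
    )


def filter_min_length(insertions: list[TEInsertion], min_len: int = 100) -> list[TEInsertion]:
    """Drop merged insertions shorter than *min_len* nt (>= min_len kept)."""
    return [ins for ins in insertions if ins.length >= min_len]


def build_library(
    insertions_by_species: Mapping[str, list[TEInsertion]],
    order_conflict: str = "error",
) -> TELibrary:
    """Combine per-species insertion sets into one library.

    Family names must already be canonical and length-filtered. ``present_in``
    is the union of source species; tallies count families shared between the
    two species and exclusive to each, and always sum to the family total.

    *order_conflict* controls what happens when the same canonical family
    arrives with different TE orders from the two species: ``"error"``
    (default) raises; ``"majority"`` keeps the order with more copies.
    """
    unknown = set(insertions_by_species) - set(VALID_SPECIES)
    if unknown:
        raise ValueError(
            f"unknown species key(s) {sorted(unknown)}; expected subset of {VALID_SPECIES}"
        )
    if order_conflict not in ("error", "majority"):
        raise ValueError("order_conflict must be 'error' or 'majority'")

    families: dict[str, TEFamily] = {}
    all_insertions: list[TEInsertion] = []
    order_votes: dict[str, dict[str, int]] = {}
    for species, insertions in insertions_by_species.items():
        for ins in insertions:
            all_insertions.append(ins)
            fam = families.get(ins.family)
            if fam is None:
                fam = TEFamily(name=ins.family, te_order=ins.te_order)
                families[ins.family] = fam
                order_votes[ins.family] = {}
            fam.present_in.add(species)
            fam.n_copies[species] = fam.n_copies.get(species, 0) + 1
            votes = order_votes[ins.family]
            votes[ins.te_order] = votes.get(ins.te_order, 0) + 1

    for name, votes in order_votes.items():
        if len(votes) > 1:
            if order_conflict == "error":
                raise ValueError(
                    f"family {name!r} has conflicting TE orders across species: {sorted(votes)}"
                )
            families[name].te_order = max(votes.items(), key=lambda kv: (kv[1], kv[0]))[0]

    shared = sum(1 for f in families.values() if len(f.present_in) == 2)
    excl = {
        sp: sum(1 for f in families.values() if f.present_in == {sp})
        for sp in VALID_SPECIES
    }
    tallies = {
        "shared": shared,
        "exclusive_Dmoj": excl["Dmoj"],
        "exclusive_Dari": excl["Dari"],
    }
    assert shared + excl["Dmoj"] + excl["Dari"] == len(families)
    return TELibrary(families=families, insertions=all_insertions, tallies=tallies)


def write_library_fasta(
    library: TELibrary,
    genomes: Mapping[str, Mapping[str, str]],
    handle: TextIO,
) -> int:
    """Write one FASTA entry per insertion, extracted from the genomes.

    *genomes* maps species -> {scaffold -> sequence}. Minus-strand insertions
    are reverse-complemented. The header encodes insertion id, family, order
    and species. Returns the number of entries written. Raises ``KeyError`` /
    ``ValueError`` naming the insertion for a missing scaffold or
    out-of-range coordinates.
    """
    n = 0
    for ins in library.insertions:
        genome = genomes.get(ins.source_species)
        if genome is None or ins.scaffold not in genome:
            raise KeyError(
                f"insertion {ins.insertion_id}: scaffold {ins.scaffold!r} absent "
                f"from {ins.source_species} genome"
            )
        scaffold_seq = genome[ins.scaffold]
        if ins.end > len(scaffold_seq):
            raise ValueError(
                f"insertion {ins.insertion_id}: end {ins.end} beyond scaffold "
                f"length {len(scaffold_seq)}"
            )
        seq = scaffold_seq[ins.start:ins.end]
        if ins.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        handle.write(
            f">{ins.insertion_id} family={ins.family} order={ins.te_order} "
            f"species={ins.source_species}\n{seq}\n"
        )
        n += 1
    return n


def family_table(library: TELibrary) -> pd.DataFrame:
    """Family-level summary (name, order, presence, per-species copy counts)."""
    rows = []
    for fam in sorted(library.families.values(), key=lambda f: f.name):
        rows.append(
            {
                "family": fam.name,
                "te_order": fam.te_order,
                "present_in": ",".join(sorted(fam.present_in)),
                "n_copies_Dmoj": fam.n_copies.get("Dmoj", 0),
                "n_copies_Dari": fam.n_copies.get("Dari", 0),
            }
        )
    return pd.DataFrame(rows, columns=["family", "te_order", "present_in", "n_copies_Dmoj", "n_copies_Dari"])


def insertion_table(library: TELibrary) -> pd.DataFrame:
    """BED-like insertion table (0-based half-open coordinates)."""
    rows = [
        {
            "scaffold": ins.scaffold,
            "start": ins.start,
            "end": ins.end,
            "insertion_id": ins.insertion_id,
            "family": ins.family,
            "te_order": ins.te_order,
            "strand": ins.strand,
            "species": ins.source_species,
        }
        for ins in library.insertions
    ]
    return pd.DataFrame(
        rows,
        columns=["scaffold", "start", "end", "insertion_id", "family", "te_order", "strand", "species"],
    )
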