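# Methods

`hybridte` analyzes transposable-element (TE) expression and its
piRNA-mediated regulation in the gonads of interspecific *Drosophila*
hybrids (*D. arizonae* x *D. mojavensis wrigleyi* and the reciprocal
cross). This note documents the models and procedures each module
implements, the defaults and why, what the synthetic-data generators do and
do not emulate, and the numerical choices made where the design was open.

## TE library curation (`telibrary`)

RepeatMasker `.out` annotations of the two parental genomes are curated
into a family-level TE library:

1. **Non-TE removal.** Records whose class string — or its top-level token
   before `/` — is one of `Simple_repeat`, `Satellite`, `Low_complexity`,
   `tRNA`, `rRNA`, `Unknown`, `ARTEFACT` are dropped. Nucleotide-enriched
   regions such as `(ATCG)n` carry the `Simple_repeat` class in RepeatMasker
   output and are covered by that token; matching is on class tokens rather
   than display labels because that is what the file stores.
2. **Fragment merging.** Two rules, applied within one scaffold and strand:
   fragments sharing a RepeatMasker block ID always merge (pieces of one
   interrupted copy), and an LTR flank record (`X_LTR`, `X-LTR`,
   `X_5LTR`/`X_3LTR`) merges with the internal region of the same element
   (`X-int`, `X_I`) when adjacent within a configurable gap, default
   5,000 nt. Chains (LTR–internal–LTR) collapse fully; two solo LTRs never
   merge. The merged span is the coordinate union. The gap default reflects
   typical LTR element sizes in *Drosophila*; the upstream annotation tools
   do not expose a published value, so it is a parameter.
3. **Length filter.** Merged insertions shorter than 100 nt are removed;
   exactly 100 nt is kept. Filtering after merging means fragments that
   jointly reach 100 nt survive, which matches filtering *insertions*
   rather than raw records.
4. **Family canonicalization.** Trailing species suffixes matching
   `-D[a-z]{3}` (configurable regex) are stripped repeatedly
   (`Gypsy-1-Dmoj` → `Gypsy-1`), collapsing homologous families annotated
   separately in the two genomes.
5. **Accounting.** Families are keyed by canonical name; presence is the
   union over species, and the shared / exclusive-per-species tallies
   always sum to the family total. A family arriving with conflicting TE
   orders from the two species is an error by default (a `majority`
   override exists) because it usually indicates an annotation clash worth
   inspecting, not averaging away.

Coordinates are 1-based inclusive in files and 0-based half-open
internally; writers convert back. TE orders are derived from the class
string (LTR, LINE, DNA→TIR, RC/Helitron→RC, else other).

## Family-level counting (`tecount`)

A family's expression is the sum of read weights over primary alignments to
any of its copies. Secondary/supplementary/unmapped SAM records are
ignored; multimapper placement is whatever the aligner reported as primary.
Reverse-strand alignments are antisense to the TE consensus and their 5'
end is the rightmost aligned base. Counts satisfy, by construction,
sense + antisense = both and permutation/concatenation additivity; these
are tested as invariants. The `weight` field lets the small-RNA path use
collapsed identical-read tables.

## Differential expression (`diffexpr`)

A deliberately compact reimplementation of the standard negative-binomial
DE workflow (the full empirical-Bayes machinery of the established
packages is out of scope; agreement with them is checked on simulations,
not assumed):

* **Normalization** — median-of-ratios size factors computed over families
  with all-positive counts; a `pseudo_reference` fallback (counts + 0.5)
  exists for degenerate matrices. Factors are defined up to a common
  constant; only their ratios matter downstream.
* **Dispersion** — NB variance is mu + alpha mu^2. The raw per-family
  estimate pools within-group moments:
  `alpha_raw = max(0, sum_g (n_g-1)(var_g - mean_g)) / sum_g (n_g-1) mean_g^2`
  on normalized counts (>= 2 replicates per group required). A trend
  `alpha(mu) = a0 + a1/mu` is fit by least squares over families with
  positive raw estimates, and the final value is a 50/50 log-scale average
  of raw and trend with raw floored at the trend. The floor is the point of
  the shrinkage: with 3 replicates the moment estimator returns 0 for a
  large share of genuinely overdispersed families, and treating those zeros
  as signal destroys type-I-error control; estimates above the trend keep
  their own information.
* **Wald test** — the two-group NB GLM decomposes into per-group mean fits,
  solved by a vectorized Newton iteration on the log scale with size
  factors as offsets; the standard error comes from the Fisher information
  `sum mu/(1+alpha mu)` of each group. A prior count of 0.5 is added to
  every count before fitting to stabilize fold changes of low-count
  families (set it to 0 for the unpenalized fit; in the alpha→0 limit that
  fit agrees with a Poisson GLM to numerical precision). Families with no
  reads in either group are reported not testable.
* **Multiple testing** — Benjamini–Hochberg step-up (via statsmodels).
* **DE call** — padj < 0.01 (strict) and |log2FC| >= 1 (inclusive), the
  thresholds used throughout this study system.
* **Direction bias** — over- vs under-expressed DE counts are compared to a
  50:50 expectation with a 1-df chi-square goodness-of-fit,
  `X2 = (n_over - n_under)^2/(n_over + n_under)`. The construction is a
  design choice: a single X2 per contrast summarizing fold-change
  direction bias.

Operating characteristics are part of the test suite: on null simulations
(2,000 families, 3 vs 3) the padj < 0.01 call rate stays below 2%, and
families with a true |log2FC| of 2 at moderate expression are recovered
above 90%.

## Hybrid expression categories (`hybridclass`)

Each family is tested hybrid-vs-parent-A (*D. arizonae*) and
hybrid-vs-parent-W (*D. m. wrigleyi*); the status pair maps to:

| vs A      | vs W      | category      |
|-----------|-----------|---------------|
| not_de    | not_de    | not_de        |
| not_de    | DE        | parentA_like  |
| DE        | not_de    | parentW_like  |
| DE        | DE, same direction | deregulated (direction kept) |
| DE        | DE, opposite       | additive      |

This is the only mapping consistent with the four verbal definitions:
"deregulated" requires divergence from *both* parents in one direction,
"additive" means sitting between them, and a family indistinguishable from
one parent is "like" that parent. Percentages are reported over families DE
against at least one parent, rounded half away from zero at the requested
precision. The parent-A-vs-parent-W contrast is deliberately not consulted;
only the two hybrid contrasts enter the rule.

## piRNA processing and ping-pong detection (`pirna`)

Reads of 23–30 nt (inclusive) are retained as piRNAs. Family counts are
normalized per million miRNA-mapped reads (`raw x 1e6 / mirna_total`); the
scale constant is a documented choice, as only ratios between samples are
interpreted. Two-sample abundance comparisons use a two-fold rule with a
pseudo-count of 1 to keep zero abundances finite:
`higher_in_A iff (A+1)/(B+1) >= 2`.

The ping-pong signature is computed within a family on the consensus
forward coordinate system: for every sense read s and antisense read a
(both 5' positions in forward coordinates, an antisense read's 5' base
being its rightmost covered base), the overlap is
`o = a.pos5 - s.pos5 + 1`, and weight products are tallied into bins
1..30. The canonical ping-pong pair lands at o = 10. The z-score is
`z10 = (h[10] - mean(h[o != 10])) / popsd(h[o != 10])`, significant at
z10 > 2.58 (the two-sided 1% normal point). A flat background is
degenerate: z10 is 0 when the 10-nt bin equals it, undefined otherwise,
and never significant. All sense/antisense pairs are tallied, not only
generated partners, so random position coincidences contribute a uniform
background the z-score absorbs.

## Selection screening (`selection`)

Pairwise dN/dS uses Nei–Gojobori (1986) counting, a transparent surrogate
for ML codon models that is adequate at the shallow divergence of this
species pair (~1.5 My): synonymous site counts per codon are mutational-fate
fractions (share of the three single-base changes per position preserving
the amino acid, changes to stops counted nonsynonymous so
S + N = 3 x codons exactly), averaged over the two sequences; differences
at multi-position codons are averaged over all minimal substitution
pathways, excluding pathways through stop codons (all pathways are used if
every one is blocked). Proportions are Jukes–Cantor corrected,
`d = -(3/4) ln(1 - 4p/3)`, flagged undefined at p >= 3/4. omega = dN/dS is
undefined when dS = 0. Codons with gaps or ambiguity codes in either
sequence are excluded pairwise; a terminal aligned stop codon is skipped,
an internal stop is an error naming the codon.

Classification: omega <= 0.3 purifying, 0.3 < omega <= 1 relaxed negative
selection, omega > 1 positive-selection candidate. Site models (M1a/M2a,
M7/M8) are not implemented; the LRT comparator consumes externally computed
log-likelihoods, with `stat = max(0, 2 dlnL)` against chi-square(df = 2)
and significance at p < 0.02 (critical value -2 ln 0.02 ≈ 7.824).

## Synthetic data (`synthetic_data`)

Generators carry explicit ground truth and are byte-deterministic in
(design, seed).

* **Annotations** — per species: clean insertions (~1.5–2 kb) of shared and
  exclusive families across the four TE orders, LTR elements split into
  flank/internal/flank records, block-split fragments, sub-100-nt copies,
  non-TE classes, and species-suffixed names. Elements are spaced 6 kb
  apart so only the designed merges occur; curation must reproduce the
  truth spans exactly.
* **Counts** — NB counts (gamma–Poisson) for parents and both reciprocal
  hybrids, 3 replicates each (the minimal design supporting dispersion
  estimation), baseline means log-uniform on [100, 800], dispersion 0.05 —
  values typical of bulk RNA-seq at moderate depth. Category structure:
  parent-like hybrids equal one parent while parents differ by the effect
  size (default |log2FC| = 2, the smallest effect the DE rule should call
  comfortably); additive hybrids sit at the parents' geometric mean —
  "intermediate" is not otherwise quantified and the geometric mean is
  symmetric on the log2 scale the test uses — with parents 2x the effect
  apart so each hybrid-parent contrast stays callable; deregulated hybrids
  sit one effect beyond both (equal) parents.
* **Small RNA** — per family, n sense/antisense pairs with an exact 10-nt
  5' overlap for a tunable fraction, remaining overlaps uniform on
  [1,30]\{10}; lengths uniform on 23–30 plus 20% contaminant reads at
  18–22/31–35 nt so the size filter is always exercised; positions uniform
  on 20 kb. miRNA totals ~1e6.
* **Codon pairs** — ancestor uniform over sense codons; one lineage
  accumulates Poisson(branch_length x codons) accepted substitutions, with
  nonsynonymous proposals thinned by omega and stops rejected.
  branch_length is total pairwise divergence (default 0.2 substitutions
  per codon — enough differences for stable counting, well below
  saturation).

What the generators do **not** emulate: sequencing error, multimapping
ambiguity between related families, copy-number differences between
genomes, GC/length biases, piRNA 1U/10A nucleotide bias, codon-usage and
transition/transversion asymmetries. Passing tests therefore demonstrate
correctness of the implemented statistics under their own model
assumptions, not robustness to every artifact of real libraries.

## Problem sizes

Simulation-backed checks run at desk scale, chosen so each completes in
seconds while leaving comfortable statistical margins: 2,000 families for
null/power DE characterization, 400 families for category recovery, 100
seeds x 500 read pairs for ping-pong operating characteristics, 20 seeds x
3,000 codons per omega for dN/dS recovery.

## Known limitations

* The DE module is a simplified reimplementation: no shrunken fold-change
  estimator, outlier replacement, independent filtering, or multi-factor
  designs. Numerical equality with the established NB DE packages is not a
  goal; directional agreement is cross-checked against one of them on
  simulated data.
* NG86 underestimates omega slightly when nonsynonymous opportunities
  blocked by stop codons are counted as sites (~5% at omega = 1, visible in
  the recovery numbers); the bias is well inside the tolerances used.
* The ping-pong z-score inherits the usual small-count instability when
  families have very few overlapping pairs; degenerate backgrounds are
  flagged rather than scored.
* Real-data entry points (SAM/BAM, `.out`, FASTA) are format-complete but
  the pipeline driver's end-to-end path is exercised on synthetic inputs.
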