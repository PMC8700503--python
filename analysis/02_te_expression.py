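"""Differential TE expression: parents against each other, hybrids vs parents.

Simulates family-level NB counts for the two parents and both reciprocal
hybrids (known category structure), then runs every contrast the downstream
classification needs: parent-vs-parent (with the over/under bias test) and
each hybrid against each parent. DE rule: padj < 0.01 and |log2FC| >= 1.

Run: python analysis/02_te_expression.py [--seed N] [--outdir results]
"""

import argparse
from pathlib import Path

from hybridte import diffexpr as de
from hybridte import synthetic_data as sd


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--outdir", default="results")
    parser.add_argument("--n-families", type=int, default=300)
    args = parser.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    design = sd.SimulationDesign(n_families=args.n_families, seed=args.seed)
    counts, truth, samples = sd.gen_count_matrix(design)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    truth.to_csv(outdir / "counts_truth.tsv", sep="\t")
    samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    cols = {g: [f"{g}_r{r}" for r in range(1, design.n_replicates + 1)] for g in sd.GENOTYPES}

    # parents: D. arizonae over D. m. wrigleyi, plus directional bias
    parent_de = de.de_contrast(counts, cols["Dmwri"], cols["Dari"])
    parent_de.to_csv(outdir / "de_Dari_vs_Dmwri.tsv", sep="\t")
    n_over = int((parent_de["status"] == "over").sum())
    n_under = int((parent_de["status"] == "under").sum())
    n_de = n_over + n_under
    print(f"parents: {n_de}/{len(parent_de)} families DE "
          f"({100 * n_de / len(parent_de):.1f}%), {n_over} over / {n_under} under in D. arizonae")
    if n_de:
        bias = de.bias_test(n_over, n_under)
        print(f"direction bias vs 50:50: X2 = {bias.chi2:.3f}, p = {bias.pvalue:.3g}")

    for hybrid in sd.HYBRIDS:
        for parent in ("Dari", "Dmwri"):
            res = de.de_contrast(counts, cols[parent], cols[hybrid])
            res.to_csv(outdir / f"de_{hybrid}_vs_{parent}.tsv", sep="\t")
            n = int((res["status"] != "not_de").sum())
            print(f"{hybrid} vs {parent}: {n} DE families ({100 * n / len(res):.1f}%)")
    print(f"wrote per-contrast tables under {outdir}/")


if __name__ == "__main__":
    main()
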