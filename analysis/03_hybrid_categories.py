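"""Classify hybrid TE expression into the four parental-comparison categories.

Consumes the hybrid-vs-parent DE tables written by 02_te_expression.py (or
regenerates them), assigns each family to arizonae-like / wrigleyi-like /
additive / deregulated, summarizes counts and percentages per reciprocal
hybrid, and scores the assignment against the generating truth.

Run: python analysis/03_hybrid_categories.py [--seed N] [--outdir results]
"""

import argparse
from pathlib import Path

import pandas as pd

from hybridte import diffexpr as de
from hybridte import hybridclass as hc
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
    counts, truth, _ = sd.gen_count_matrix(design)
    cols = {g: [f"{g}_r{r}" for r in range(1, design.n_replicates + 1)] for g in sd.GENOTYPES}
    true_cat = truth["category"].replace(
        {"deregulated_over": "deregulated", "deregulated_under": "deregulated"}
    )

    rows = []
    for hybrid in sd.HYBRIDS:
        de_vs_a = Path(outdir / f"de_{hybrid}_vs_Dari.tsv")
        de_vs_w = Path(outdir / f"de_{hybrid}_vs_Dmwri.tsv")
        if de_vs_a.exists() and de_vs_w.exists():
            da = pd.read_csv(de_vs_a, sep="\t", index_col="family")
            dw = pd.read_csv(de_vs_w, sep="\t", index_col="family")
        else:
            da = de.de_contrast(counts, cols["Dari"], cols[hybrid])
            dw = de.de_contrast(counts, cols["Dmwri"], cols[hybrid])
        calls = hc.classify_frame(da, dw)
        calls.to_csv(outdir / f"categories_{hybrid}.tsv", sep="\t")
        summary = hc.summarize_categories(calls)
        accuracy = float((calls["category"] == true_cat).mean())
        print(f"{hybrid}: {summary.n_classified} families DE vs >= 1 parent")
        for cat in ("parentA_like", "parentW_like", "additive", "deregulated"):
            print(f"  {cat:13s} {summary.counts[cat]:4d} ({summary.percentages[cat]}%)")
        print(f"  truth recovery: {100 * accuracy:.1f}%")
        for cat in summary.counts:
            rows.append({
                "hybrid": hybrid, "category": cat, "count": summary.counts[cat],
                "percent": summary.percentages.get(cat), "recovery": accuracy,
            })
    pd.DataFrame(rows).to_csv(outdir / "category_summary.tsv", sep="\t", index=False)
    print(f"wrote {outdir}/category_summary.tsv")


if __name__ == "__main__":
    main()
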