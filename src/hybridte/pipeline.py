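"""End-to-end pipeline driver and configuration.

Chains the stages — library curation, family counting, differential
expression, hybrid category classification, piRNA quantification with
ping-pong detection, and dN/dS selection screening — over synthetic inputs
(generated from the configured seed) or pre-computed input tables. All
thresholds default to the study's values: DE at padj < 0.01 with
|log2FC| >= 1, piRNA size window 23-30 nt, ping-pong z > 2.58, relaxed
selection at omega > 0.3, LRT at chi-square df 2 / alpha 0.02.
"""

from __future__ import annotations

import io
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import diffexpr, hybridclass, pirna, selection, synthetic_data, telibrary

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline"]

log = logging.getLogger("hybridte")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    outdir: str = "results"
    seed: int = 0
    # DE thresholds
    alpha: float = 0.01
    lfc_min: float = 1.0
    # piRNA
    pirna_min_len: int = 23
    pirna_max_len: int = 30
    pingpong_z: float = 2.58
    pirna_fold: float = 2.0
    # selection
    omega_threshold: float = 0.3
    lrt_df: int = 2
    lrt_alpha: float = 0.02
    # library curation
    min_insertion_len: int = 100
    merge_max_gap: int = 5000
    # synthetic design sizes
    n_families: int = 300
    n_replicates: int = 3
    effect_lfc: float = 2.0
    dispersion: float = 0.05
    smallrna_pairs: int = 500
    pingpong_fraction: float = 0.5
    dnds_genes: dict = field(
        default_factory=lambda: {"gene_purifying": 0.1, "gene_relaxed": 0.45, "gene_neutral": 1.0}
    )

    def validate(self) -> None:
        positive = {
            "alpha": self.alpha,
            "lfc_min": self.lfc_min,
            "pirna_min_len": self.pirna_min_len,
            "pirna_max_len": self.pirna_max_len,
            "pingpong_z": self.pingpong_z,
            "pirna_fold": self.pirna_fold,
            "omega_threshold": self.omega_threshold,
            "lrt_df": self.lrt_df,
            "lrt_alpha": self.lrt_alpha,
            "min_insertion_len": self.min_insertion_len,
            "n_families": self.n_families,
            "n_replicates": self.n_replicates,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if self.alpha >= 1 or self.lrt_alpha >= 1:
            raise ConfigError("significance levels must be < 1")
        if self.pirna_min_len > self.pirna_max_len:
            raise ConfigError("pirna_min_len must be <= pirna_max_len")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _write_tsv(df: pd.DataFrame, path: Path, params: dict, index_label: str | None = None) -> None:
    """TSV with header comments recording the parameters that produced it."""
    with open(path, "w") as fh:
        for key, value in params.items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, sep="\t", index=index_label is not None, index_label=index_label)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic-input pipeline; returns paths of the outputs.

    Stage outputs are written under ``config.outdir``; a run log records the
    package version, all parameters and the seed. Rerunning with an
    identical config reproduces identical tables.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("hybridte %s", __version__)
        for key, value in asdict(config).items():
            log.info("param %s = %s", key, value)

        # --- stage 1: TE library curation -------------------------------
        out_texts, truth = synthetic_data.gen_repeatmasker_annotations(seed=config.seed)
        insertions_by_species = {}
        for species, text in out_texts.items():
            records = telibrary.parse_repeatmasker_out(io.StringIO(text))
            records = telibrary.filter_non_te(records)
            merged = telibrary.merge_fragments(records, species=species, max_gap=config.merge_max_gap)
            insertions_by_species[species] = telibrary.filter_min_length(merged, config.min_insertion_len)
        library = telibrary.build_library(insertions_by_species)
        params = {"seed": config.seed, "min_insertion_len": config.min_insertion_len}
        _write_tsv(telibrary.family_table(library), outdir / "library_families.tsv", params)
        _write_tsv(telibrary.insertion_table(library), outdir / "library_insertions.tsv", params)
        outputs["library_families"] = outdir / "library_families.tsv"
        log.info(
            "library: %d families (%d shared, %d Dmoj-only, %d Dari-only)",
            library.n_families, library.tallies["shared"],
            library.tallies["exclusive_Dmoj"], library.tallies["exclusive_Dari"],
        )

        # --- stage 2: counts + DE + categories ---------------------------
        design = synthetic_data.SimulationDesign(
            n_families=config.n_families,
            effect_lfc=config.effect_lfc,
            dispersion=config.dispersion,
            n_replicates=config.n_replicates,
            seed=config.seed,
        )
        counts, truth_cats, samples = synthetic_data.gen_count_matrix(design)
        _write_tsv(counts, outdir / "counts.tsv", {"seed": config.seed}, index_label="family")
        sample_cols = {
            g: [f"{g}_r{r}" for r in range(1, config.n_replicates + 1)]
            for g in synthetic_data.GENOTYPES
        }
        de_params = {"alpha": config.alpha, "lfc_min": config.lfc_min, "seed": config.seed}

        parent_de = diffexpr.de_contrast(
            counts, sample_cols["Dmwri"], sample_cols["Dari"],
            alpha=config.alpha, lfc_min=config.lfc_min,
        )
        bias = diffexpr.bias_test(
            int((parent_de["status"] == "over").sum()), int((parent_de["status"] == "under").sum())
        )
        log.info("parents Dari-vs-Dmwri: %d over, %d under, bias chi2=%.3f p=%.3g",
                 bias.n_over, bias.n_under, bias.chi2, bias.pvalue)
        _write_tsv(parent_de, outdir / "de_parents.tsv", de_params, index_label="family")

        for hybrid in synthetic_data.HYBRIDS:
            de_vs_a = diffexpr.de_contrast(
                counts, sample_cols["Dari"], sample_cols[hybrid],
                alpha=config.alpha, lfc_min=config.lfc_min,
            )
            de_vs_w = diffexpr.de_contrast(
                counts, sample_cols["Dmwri"], sample_cols[hybrid],
                alpha=config.alpha, lfc_min=config.lfc_min,
            )
            calls = hybridclass.classify_frame(de_vs_a, de_vs_w)
            summary = hybridclass.summarize_categories(calls)
            _write_tsv(calls, outdir / f"categories_{hybrid}.tsv", de_params, index_label="family")
            summary_df = pd.DataFrame(
                {
                    "count": pd.Series(summary.counts),
                    "percent": pd.Series(summary.percentages),
                }
            )
            _write_tsv(summary_df, outdir / f"category_summary_{hybrid}.tsv", de_params, index_label="category")
            outputs[f"categories_{hybrid}"] = outdir / f"categories_{hybrid}.tsv"
            log.info("%s categories: %s", hybrid, summary.counts)

        # --- stage 3: piRNA + ping-pong ----------------------------------
        families = list(counts.index[:20])
        reads, mirna_totals, _ = synthetic_data.gen_smallrna(
            families, n_pairs=config.smallrna_pairs,
            pingpong_fraction=config.pingpong_fraction, seed=config.seed,
        )
        filtered = pirna.filter_pirna_size(reads, config.pirna_min_len, config.pirna_max_len)
        raw = pirna.count_reads_by_family(filtered).to_frame("s1")
        norm = pirna.normalize_by_mirna(raw, mirna_totals)
        pp = pirna.family_pingpong(
            reads, config.pirna_min_len, config.pirna_max_len, threshold=config.pingpong_z
        )
        pirna_params = {
            "min_len": config.pirna_min_len, "max_len": config.pirna_max_len,
            "pingpong_z": config.pingpong_z, "seed": config.seed,
        }
        _write_tsv(norm, outdir / "pirna_normalized.tsv", pirna_params, index_label="family")
        _write_tsv(pp, outdir / "pingpong.tsv", pirna_params, index_label="family")
        outputs["pingpong"] = outdir / "pingpong.tsv"
        log.info("ping-pong significant in %d/%d families", int(pp["significant"].sum()), len(pp))

        # --- stage 4: selection screening --------------------------------
        rows = []
        for i, (gene, omega) in enumerate(sorted(config.dnds_genes.items())):
            pair, _ = synthetic_data.gen_codon_pair(
                omega=omega, branch_length=0.2, n_codons=1500,
                seed=config.seed + i + 1, gene=gene,
            )
            res = selection.ng86_dnds(pair)
            rows.append(
                {
                    "gene": gene, "S": res.S, "N": res.N, "Sd": res.Sd, "Nd": res.Nd,
                    "dN": res.dN, "dS": res.dS, "omega": res.omega,
                    "class": selection.classify_selection(res.omega, config.omega_threshold),
                }
            )
        dnds_df = pd.DataFrame(rows).set_index("gene")
        _write_tsv(dnds_df, outdir / "dnds.tsv",
                   {"omega_threshold": config.omega_threshold, "seed": config.seed},
                   index_label="gene")
        outputs["dnds"] = outdir / "dnds.tsv"
        log.info("dnds: %s", {r["gene"]: round(r["omega"], 3) for r in rows})
    finally:
        log.removeHandler(handler)
        handler.close()
    outputs["log"] = log_path
    return outputs
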