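"""End-to-end reproducible runs.

Ties the stages together: simulate the hybrid-cross experiment, build
strain pseudo-genomes and transcriptomes, assign reads at 0 mismatches,
quantify per-SNP / per-gene allelic expression, and compare genotype
groups.  Every stage's inputs and outputs are serialized into the run
directory, all randomness derives from the single config seed, and a
rerun with the same config is byte-identical (text outputs).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .assign import TranscriptomeIndex, assign_all
from .group_stats import (
    embryo_mean_paternal,
    order_genes_by_reference_group,
    pairwise_tests,
)
from .pseudogenome import substitute_snps, strain_transcriptome, transcript_variants
from .quantify import informative_across_samples, quantify_embryo, snp_table, count_snp_alleles
from .simulate import (
    DEFAULT_SILENCING,
    GENOTYPES,
    EmbryoSimSpec,
    default_xci_mix,
    make_toy_reference,
    simulate_embryo,
)

log = logging.getLogger("hybridxci")

#: embryos sequenced per genotype group in the default design
DEFAULT_GROUPS = {"fl/fl": 4, "fl/-": 4, "-/-": 4, "m-/-": 5, "mz-/-": 3}


@dataclass
class RunConfig:
    """Configuration of a full simulated experiment.

    The default design is a desk-scale mirror of the study: five
    genotype groups (4/4/4 controls and zygotic mutants, 5 maternal-null,
    3 maternal+zygotic-null female embryos), ~60 genes split between one
    autosome and the X, one SNP per 250 bp of transcribed sequence, and
    strict 0-mismatch allelic mapping with a 10-read SNP filter.
    """

    seed: int = 0
    n_autosomal_genes: int = 40
    n_x_genes: int = 20
    gene_len: int = 500
    snp_rate: float = 1 / 250
    n_exons: int = 2
    read_len: int = 50
    mean_depth: float = 800.0
    error_rate: float = 0.005
    dispersion: float = 0.1
    n_cells: int = 64
    min_snp_reads: int = 10
    index_k: int = 25
    groups: dict = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    silencing_efficiency: dict = field(default_factory=lambda: dict(DEFAULT_SILENCING))
    xci_mix_overrides: dict = field(default_factory=dict)
    make_plots: bool = True

    def validate(self) -> None:
        for g in self.groups:
            if g not in GENOTYPES:
                raise ValueError(f"unknown genotype group {g!r}")
        if self.min_snp_reads < 1:
            raise ValueError("min_snp_reads must be >= 1")
        if self.index_k > self.read_len:
            raise ValueError("index_k must not exceed read_len")
        if not self.groups:
            raise ValueError("at least one genotype group required")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def xci_mix_for(self, genotype: str, sex: str = "XX") -> dict:
        if genotype in self.xci_mix_overrides:
            return dict(self.xci_mix_overrides[genotype])
        return default_xci_mix(genotype, sex)


def _embryo_specs(config: RunConfig) -> list:
    """Per-embryo simulation specs with seeds derived from the run seed."""
    n_total = sum(config.groups.values())
    seeds = np.random.default_rng(config.seed).integers(0, 2**31, size=n_total)
    specs = []
    i = 0
    for genotype in sorted(config.groups, key=GENOTYPES.index):
        for rep in range(1, config.groups[genotype] + 1):
            tag = genotype.replace("/", "").replace("-", "n")
            specs.append(
                EmbryoSimSpec(
                    embryo_id=f"{tag}_e{rep}",
                    genotype=genotype,
                    sex="XX",
                    n_cells=config.n_cells,
                    xci_mix=config.xci_mix_for(genotype),
                    silencing_efficiency=dict(config.silencing_efficiency),
                    mean_depth=config.mean_depth,
                    error_rate=config.error_rate,
                    seed=int(seeds[i]),
                    read_len=config.read_len,
                    dispersion=config.dispersion,
                )
            )
            i += 1
    return specs


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full pipeline into ``outdir``; returns the summary dict.

    Stage order: reference simulation → pseudo-genomes/transcriptomes →
    per-embryo read simulation → 0-mismatch assignment → per-SNP and
    per-gene quantification → informative-gene intersection → group
    statistics and heat-map matrix.  All text outputs are deterministic
    for a fixed config.
    """
    config.validate()
    out = Path(outdir)
    for sub in ("reference", "pseudogenomes", "embryos", "assignments", "quantification", "results"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    # --- stage 1: toy reference ------------------------------------------
    genomes, variants, genes = make_toy_reference(
        n_autosomal_genes=config.n_autosomal_genes,
        n_x_genes=config.n_x_genes,
        gene_len=config.gene_len,
        snp_rate=config.snp_rate,
        seed=config.seed,
        n_exons=config.n_exons,
    )
    hio.write_genome_fasta(out / "reference" / "reference.fa", genomes)
    hio.write_vcf(out / "reference" / "variants.vcf", variants,
                  {c: len(g) for c, g in genomes.items()})
    hio.write_gtf(out / "reference" / "genes.gtf", genes)
    log.info("reference: %d genes, %d SNPs", len(genes), len(variants))

    # --- stage 2: pseudo-genomes -----------------------------------------
    mat_genome = substitute_snps(genomes, variants, "maternal")
    pat_genome = substitute_snps(genomes, variants, "paternal")
    mat_tx = strain_transcriptome(mat_genome, genes)
    pat_tx = strain_transcriptome(pat_genome, genes)
    hio.write_fasta(out / "pseudogenomes" / "maternal.fa", mat_genome.sequences)
    hio.write_fasta(out / "pseudogenomes" / "paternal.fa", pat_genome.sequences)
    hio.write_fasta(out / "pseudogenomes" / "maternal_tx.fa", mat_tx)
    hio.write_fasta(out / "pseudogenomes" / "paternal_tx.fa", pat_tx)

    tvars = transcript_variants(genes, variants)
    mat_index = TranscriptomeIndex(mat_tx, k=config.index_k)
    pat_index = TranscriptomeIndex(pat_tx, k=config.index_k)

    # --- stages 3-5: per-embryo simulate, assign, quantify ----------------
    specs = _embryo_specs(config)
    tables: dict = {}
    sample_groups: dict = {}
    attrition_rows = []
    for spec in specs:
        sim = simulate_embryo(spec, genes, variants, genomes, transcriptomes=(mat_tx, pat_tx))
        hio.write_fastq(out / "embryos" / f"{spec.embryo_id}.fastq",
                        [(r.read_id, r.sequence) for r in sim.reads])
        truth_df = pd.DataFrame(
            [
                {"read_id": t.read_id, "gene_id": t.gene_id,
                 "allele_of_origin": t.allele_of_origin,
                 "overlaps_variant": t.overlaps_variant}
                for t in sim.truth
            ]
        )
        hio.write_tsv(out / "embryos" / f"{spec.embryo_id}.truth.tsv", truth_df, index=False)

        assignments, mapped_total = assign_all(
            ((r.read_id, r.sequence) for r in sim.reads), mat_index, pat_index
        )
        assign_df = pd.DataFrame(
            [
                {"read_id": a.read_id, "status": a.status,
                 "gene_id": a.gene_id or "", "offset": -1 if a.offset is None else a.offset,
                 "strand": a.strand or "", "read_len": a.read_len}
                for a in assignments
            ]
        )
        hio.write_tsv(out / "assignments" / f"{spec.embryo_id}.tsv", assign_df, index=False)

        tab = quantify_embryo(assignments, mapped_total, genes, variants,
                              min_snp_reads=config.min_snp_reads, tvars=tvars)
        snps = snp_table(count_snp_alleles(assignments, genes, variants, tvars=tvars),
                         config.min_snp_reads)
        hio.write_tsv(out / "quantification" / f"{spec.embryo_id}.genes.tsv", tab)
        hio.write_tsv(out / "quantification" / f"{spec.embryo_id}.snps.tsv", snps, index=False)
        tables[spec.embryo_id] = tab
        sample_groups[spec.embryo_id] = spec.genotype
        status_counts = assign_df["status"].value_counts().to_dict()
        attrition_rows.append(
            {"embryo_id": spec.embryo_id, "genotype": spec.genotype,
             "reads": len(assignments), "mapped": mapped_total,
             **{s: int(status_counts.get(s, 0)) for s in
                ("maternal", "paternal", "shared", "multimapped", "unmapped")},
             "informative_genes": int((tab["n_informative_snps"] >= 1).sum())}
        )
        log.info("embryo %s (%s): %d reads, %d mapped", spec.embryo_id, spec.genotype,
                 len(assignments), mapped_total)
    attrition = pd.DataFrame(attrition_rows)
    hio.write_tsv(out / "results" / "attrition.tsv", attrition, index=False)

    # --- stage 6: cross-sample analysis -----------------------------------
    informative = informative_across_samples(tables)
    x_genes = [g for g in informative
               if tables[specs[0].embryo_id].loc[g, "chrom_class"] == "X"]
    if not x_genes:
        raise RuntimeError("no X-linked gene is informative in all samples")

    matrix = pd.DataFrame(
        {eid: tab.loc[x_genes, "mean_paternal_pct"] for eid, tab in tables.items()}
    )
    order = order_genes_by_reference_group(matrix, sample_groups, "fl/fl")
    matrix = matrix.loc[order]
    hio.write_tsv(out / "results" / "heatmap_matrix.tsv", matrix)

    means = {
        eid: embryo_mean_paternal(tab, x_genes) for eid, tab in tables.items()
    }
    means_df = pd.DataFrame(
        [{"embryo_id": e, "genotype": sample_groups[e], "mean_paternal_pct_x": m}
         for e, m in means.items()]
    )
    hio.write_tsv(out / "results" / "embryo_means.tsv", means_df, index=False)

    group_values = {
        g: [means[e] for e in means if sample_groups[e] == g] for g in config.groups
    }
    welch = pairwise_tests(group_values, method="welch")
    hio.write_tsv(out / "results" / "pairwise_welch.tsv", welch, index=False)

    # normalized maternal/paternal expression split, Student's tests
    split_rows = []
    for eid, tab in tables.items():
        sub = tab.loc[x_genes]
        split_rows.append(
            {"embryo_id": eid, "genotype": sample_groups[eid],
             "maternal_norm_mean": float(sub["maternal_norm"].mean()),
             "paternal_norm_mean": float(sub["paternal_norm"].mean())}
        )
    split_df = pd.DataFrame(split_rows)
    hio.write_tsv(out / "results" / "expression_split.tsv", split_df, index=False)
    student_tabs = {}
    for col in ("maternal_norm_mean", "paternal_norm_mean"):
        vals = {g: split_df.loc[split_df["genotype"] == g, col].tolist()
                for g in config.groups}
        student_tabs[col] = pairwise_tests(vals, method="student")
        hio.write_tsv(out / "results" / f"student_{col}.tsv", student_tabs[col], index=False)

    group_means = {g: float(np.mean(v)) for g, v in group_values.items()}
    summary = {
        "n_embryos": len(specs),
        "n_genes": len(genes),
        "n_variants": len(variants),
        "n_informative_all_samples": len(informative),
        "n_informative_x": len(x_genes),
        "group_mean_paternal_pct_x": group_means,
        "pairwise_welch": welch.drop(columns=["p_bonferroni"], errors="ignore")
        .to_dict(orient="records"),
    }
    with open(out / "results" / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    if config.make_plots:
        _plot_heatmap(matrix, sample_groups, out / "results" / "heatmap.png")
    return summary


def _plot_heatmap(matrix: pd.DataFrame, sample_groups: dict, path) -> None:
    """Allelic heat map (genes x samples, % paternal) in the style of the
    figure-3/4 panels: 0% maternal-only (red) to 100% paternal-only (blue)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.35 * matrix.shape[1]), max(3.0, 0.18 * matrix.shape[0]))
    )
    im = ax.imshow(matrix.values, aspect="auto", cmap="RdBu", vmin=0, vmax=100)
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(
        [f"{c}\n({sample_groups.get(c, '?')})" for c in matrix.columns], fontsize=6,
        rotation=90,
    )
    ax.set_yticks(range(matrix.shape[0]))
    ax.set_yticklabels(matrix.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="% paternal expression")
    ax.set_title("X-linked allelic expression")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
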