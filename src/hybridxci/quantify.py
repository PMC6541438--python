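"""Per-SNP and per-gene allelic quantification.

Implements the allelic measurement chain: count maternal/paternal reads
over every SNP site, retain sites with at least ``min_snp_reads``
(default 10) SNP-overlapping reads, average retained sites' paternal
percentages (unweighted) into a gene-level allelic ratio, call genes
with >=1 retained site *informative*, and split each gene's
reads-per-million expression into maternal and paternal components:

    paternal_norm = total_norm * mean_paternal_pct / 100
    maternal_norm = total_norm - paternal_norm

Shared (SNP-free) reads count toward gene totals but never toward any
SNP; multimapped and unmapped reads count toward nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pseudogenome import transcript_variants

DEFAULT_MIN_SNP_READS = 10
NORM_SCALE = 1e6  # reads per million mapped


@dataclass
class SnpAlleleCount:
    """Allelic read counts over one SNP site (transcript coordinates)."""

    gene_id: str
    chrom: str
    pos: int
    tpos: int
    maternal_reads: int = 0
    paternal_reads: int = 0

    @property
    def total(self) -> int:
        return self.maternal_reads + self.paternal_reads

    @property
    def paternal_pct(self) -> float | None:
        """Paternal percentage, undefined (None) for an uncovered site."""
        if self.total == 0:
            return None
        return 100.0 * self.paternal_reads / self.total

    def retained(self, min_reads: int = DEFAULT_MIN_SNP_READS) -> bool:
        return self.total >= min_reads


@dataclass
class GeneAllelicExpression:
    """Per-gene allelic summary for one sample."""

    gene_id: str
    chrom_class: str
    n_informative_snps: int
    mean_paternal_pct: float | None
    totalreads: int
    total_norm: float
    maternal_norm: float | None
    paternal_norm: float | None

    @property
    def informative(self) -> bool:
        return self.n_informative_snps >= 1


def count_snp_alleles(assignments, genes, variants, tvars=None) -> list:
    """Count allelic reads over every exonic SNP site.

    Each maternal/paternal read increments, on its assigned haplotype,
    every SNP whose transcript position falls inside the read's matched
    span.  Every exonic variant appears in the output, uncovered sites
    with (0, 0) counts.
    """
    if tvars is None:
        tvars = transcript_variants(genes, variants)
    counts: dict = {}
    order = []
    for gene in genes:
        for tv in tvars.get(gene.gene_id, []):
            key = (gene.gene_id, tv.variant.chrom, tv.variant.pos)
            counts[key] = SnpAlleleCount(
                gene_id=gene.gene_id, chrom=tv.variant.chrom, pos=tv.variant.pos, tpos=tv.tpos
            )
            order.append(key)
    tpos_by_gene = {
        gid: [(tv.tpos, (gid, tv.variant.chrom, tv.variant.pos)) for tv in tvs]
        for gid, tvs in tvars.items()
    }
    for a in assignments:
        if a.status not in ("maternal", "paternal") or a.gene_id is None:
            continue
        for tpos, key in tpos_by_gene.get(a.gene_id, []):
            if a.offset <= tpos < a.offset + a.read_len:
                c = counts[key]
                if a.status == "maternal":
                    c.maternal_reads += 1
                else:
                    c.paternal_reads += 1
    return [counts[k] for k in order]


def gene_allelic_ratio(snp_counts, min_reads: int = DEFAULT_MIN_SNP_READS):
    """Gene-level allelic ratio: unweighted mean over retained SNP sites.

    Returns ``(mean_paternal_pct, n_informative_snps)``; the mean is
    ``None`` for a non-informative gene (no SNP site reaching the read
    threshold) — a state, not an error.
    """
    pcts = [c.paternal_pct for c in snp_counts if c.retained(min_reads)]
    if not pcts:
        return None, 0
    return float(np.mean(pcts)), len(pcts)


def allelic_expression(gene_id: str, chrom_class: str, totalreads: int, mapped_total: int,
                       mean_paternal_pct: float | None,
                       n_informative_snps: int = 0) -> GeneAllelicExpression:
    """Normalized expression split into maternal and paternal components.

    ``total_norm`` is reads-per-million mapped; the paternal component
    is the total scaled by the gene's SNP-derived paternal proportion
    and the maternal component is the remainder, so the two always add
    back to the total.  A gene without an allelic ratio keeps its total
    but has undefined components.
    """
    if mapped_total <= 0:
        raise ValueError("mapped_total must be positive")
    total_norm = NORM_SCALE * totalreads / mapped_total
    if mean_paternal_pct is None:
        maternal_norm = paternal_norm = None
    else:
        paternal_norm = total_norm * mean_paternal_pct / 100.0
        maternal_norm = total_norm - paternal_norm
    return GeneAllelicExpression(
        gene_id=gene_id,
        chrom_class=chrom_class,
        n_informative_snps=n_informative_snps,
        mean_paternal_pct=mean_paternal_pct,
        totalreads=totalreads,
        total_norm=total_norm,
        maternal_norm=maternal_norm,
        paternal_norm=paternal_norm,
    )


def quantify_embryo(assignments, mapped_total: int, genes, variants,
                    min_snp_reads: int = DEFAULT_MIN_SNP_READS,
                    tvars=None) -> pd.DataFrame:
    """Full per-gene allelic quantification of one sample.

    Returns a DataFrame indexed by gene_id with columns chrom_class,
    n_informative_snps, mean_paternal_pct, totalreads, total_norm,
    maternal_norm, paternal_norm.  Gene totals count uniquely placed
    reads of any status (maternal, paternal, shared).
    """
    if tvars is None:
        tvars = transcript_variants(genes, variants)
    snp_counts = count_snp_alleles(assignments, genes, variants, tvars=tvars)
    by_gene: dict = {}
    for c in snp_counts:
        by_gene.setdefault(c.gene_id, []).append(c)
    totals: dict = {g.gene_id: 0 for g in genes}
    for a in assignments:
        if a.status in ("maternal", "paternal", "shared") and a.gene_id in totals:
            totals[a.gene_id] += 1
    rows = []
    for gene in genes:
        mean_pct, n_inf = gene_allelic_ratio(by_gene.get(gene.gene_id, []), min_snp_reads)
        chrom_class = "autosome" if gene.silencing_class == "autosomal" else "X"
        g = allelic_expression(
            gene.gene_id, chrom_class, totals[gene.gene_id], mapped_total, mean_pct, n_inf
        )
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom_class": g.chrom_class,
                "n_informative_snps": g.n_informative_snps,
                "mean_paternal_pct": np.nan if g.mean_paternal_pct is None else g.mean_paternal_pct,
                "totalreads": g.totalreads,
                "total_norm": g.total_norm,
                "maternal_norm": np.nan if g.maternal_norm is None else g.maternal_norm,
                "paternal_norm": np.nan if g.paternal_norm is None else g.paternal_norm,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def snp_table(snp_counts, min_reads: int = DEFAULT_MIN_SNP_READS) -> pd.DataFrame:
    """Per-SNP counts as a DataFrame with retention flags."""
    rows = [
        {
            "gene_id": c.gene_id,
            "chrom": c.chrom,
            "pos": c.pos,
            "tpos": c.tpos,
            "maternal_reads": c.maternal_reads,
            "paternal_reads": c.paternal_reads,
            "total": c.total,
            "paternal_pct": np.nan if c.paternal_pct is None else c.paternal_pct,
            "retained": c.retained(min_reads),
        }
        for c in snp_counts
    ]
    return pd.DataFrame(rows)


def informative_across_samples(tables: dict) -> list:
    """Genes informative (>=1 retained SNP) in *every* sample.

    ``tables`` maps sample id to a ``quantify_embryo`` DataFrame.  The
    returned list keeps the gene order of the first table, so the
    result is stable.  Emits a warning if the intersection is empty.
    """
    if not tables:
        raise ValueError("need at least one sample table")
    items = list(tables.values())
    keep = None
    for tab in items:
        inf = set(tab.index[tab["n_informative_snps"] >= 1])
        keep = inf if keep is None else keep & inf
    ordered = [g for g in items[0].index if g in keep]
    if not ordered:
        warnings.warn("no gene is informative in all samples", stacklevel=2)
    return ordered
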