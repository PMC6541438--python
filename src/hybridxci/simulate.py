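"""Synthetic hybrid-cross experiment generator.

Builds a toy two-chromosome reference (one autosome, one X), a panel of
biallelic strain-discriminating SNPs at roughly one SNP per 250 bp of
transcribed sequence, gene models, and per-embryo RNA-seq read sets with
a full allele-of-origin truth table.  The generator encodes the
X-inactivation regimes of a maternal-vs-zygotic PRC2 loss-of-function
cross: imprinted XCI (paternal X inactive in every cell), mosaic random
XCI, biallelic Xist induction, and ectopic maternal-X Xist in males.

Every draw is taken from a single :class:`numpy.random.Generator`
seeded from the spec, so the generated bundle is bit-reproducible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

DNA = "ACGT"

#: genotype vocabulary of the cross (floxed control, zygotic het/null,
#: maternal-null, maternal+zygotic-null)
GENOTYPES = ("fl/fl", "fl/-", "-/-", "m-/-", "mz-/-")

#: per-cell X-inactivation states
XCI_STATES = ("paternal_X_inactive", "maternal_X_inactive", "both_Xist", "no_Xist")

#: states a male (single, maternally inherited X) cell may occupy
XY_STATES = ("maternal_X_inactive", "no_Xist")

SILENCING_CLASSES = ("subject", "escaper", "autosomal")


@dataclass(frozen=True)
class ToyGenome:
    """A toy chromosome: name, uppercase ACGT sequence, and class (X or autosome)."""

    chrom_name: str
    sequence: str
    chrom_class: str  # "X" | "autosome"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.chrom_name}: empty sequence")
        if set(self.sequence) - set(DNA + "N"):
            raise ValueError(f"{self.chrom_name}: non-ACGTN characters in sequence")
        if self.chrom_class not in ("X", "autosome"):
            raise ValueError(f"{self.chrom_name}: bad chrom_class {self.chrom_class!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class StrainVariant:
    """One biallelic SNV distinguishing the maternal and paternal strains.

    ``pos`` is 1-based (VCF convention).  The maternal allele may equal
    the reference base (the maternal 129/S1-like strain is close to the
    reference); the two strain alleles always differ.
    """

    chrom: str
    pos: int
    ref_allele: str
    maternal_allele: str
    paternal_allele: str

    def __post_init__(self):
        for name in ("ref_allele", "maternal_allele", "paternal_allele"):
            a = getattr(self, name)
            if len(a) != 1 or a not in DNA:
                raise ValueError(f"{self.chrom}:{self.pos}: {name}={a!r} is not a single ACGT base")
        if self.maternal_allele == self.paternal_allele:
            raise ValueError(
                f"{self.chrom}:{self.pos}: maternal and paternal alleles are identical "
                "(site is not strain-discriminating)"
            )
        if self.pos < 1:
            raise ValueError(f"{self.chrom}:{self.pos}: position must be 1-based")

    def allele(self, strain: str) -> str:
        if strain == "maternal":
            return self.maternal_allele
        if strain == "paternal":
            return self.paternal_allele
        raise ValueError(f"unknown strain {strain!r}")


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: sorted, non-overlapping 1-based closed exon intervals."""

    gene_id: str
    chrom: str
    strand: str
    exon_intervals: tuple  # ((start, end), ...) 1-based closed
    is_xist_like: bool = False
    silencing_class: str = "autosomal"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.silencing_class not in SILENCING_CLASSES:
            raise ValueError(f"{self.gene_id}: bad silencing_class {self.silencing_class!r}")
        if not self.exon_intervals:
            raise ValueError(f"{self.gene_id}: gene needs at least one exon")
        prev_end = 0
        for start, end in self.exon_intervals:
            if start <= prev_end:
                raise ValueError(f"{self.gene_id}: exons must be sorted and non-overlapping")
            if end < start:
                raise ValueError(f"{self.gene_id}: exon end < start")
            prev_end = end

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exon_intervals)

    @property
    def span(self) -> tuple:
        return self.exon_intervals[0][0], self.exon_intervals[-1][1]

    def exonic_positions(self):
        """Yield 1-based genomic positions of exonic bases, genomic order."""
        for start, end in self.exon_intervals:
            yield from range(start, end + 1)


@dataclass(frozen=True)
class EmbryoSimSpec:
    """Everything needed to simulate one embryo's RNA-seq read set.

    ``xci_mix`` gives the proportions of cells in each X-inactivation
    state; cells are drawn once per embryo and reads are sampled from
    random cells.  ``silencing_efficiency`` maps silencing class to the
    fraction by which expression from an inactive X is reduced (1.0 =
    complete silencing).  ``mean_depth`` is the expected read count for
    a gene expressed from both alleles at full strength.
    """

    embryo_id: str
    genotype: str
    sex: str  # "XX" | "XY"
    n_cells: int
    xci_mix: dict
    silencing_efficiency: dict
    mean_depth: float = 100.0
    error_rate: float = 0.0
    seed: int = 0
    read_len: int = 50
    dispersion: float = 0.1

    def validate(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"{self.embryo_id}: unknown genotype {self.genotype!r}")
        if self.sex not in ("XX", "XY"):
            raise ValueError(f"{self.embryo_id}: sex must be XX or XY")
        if self.n_cells < 1:
            raise ValueError(f"{self.embryo_id}: n_cells must be positive")
        unknown = set(self.xci_mix) - set(XCI_STATES)
        if unknown:
            raise ValueError(f"{self.embryo_id}: unknown XCI states {sorted(unknown)}")
        total = sum(self.xci_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.embryo_id}: xci_mix proportions sum to {total}, not 1")
        if any(p < 0 for p in self.xci_mix.values()):
            raise ValueError(f"{self.embryo_id}: negative xci_mix proportion")
        if self.sex == "XY":
            bad = {s for s, p in self.xci_mix.items() if p > 0 and s not in XY_STATES}
            if bad:
                raise ValueError(
                    f"{self.embryo_id}: XY embryos have no paternal X; states {sorted(bad)} invalid"
                )
        for cls, eff in self.silencing_efficiency.items():
            if cls not in SILENCING_CLASSES:
                raise ValueError(f"{self.embryo_id}: unknown silencing class {cls!r}")
            if not 0.0 <= eff <= 1.0:
                raise ValueError(f"{self.embryo_id}: silencing_efficiency[{cls}]={eff} outside [0,1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError(f"{self.embryo_id}: error_rate outside [0,1)")


@dataclass(frozen=True)
class ReadTruth:
    """Ground-truth record for one simulated read."""

    read_id: str
    gene_id: str
    allele_of_origin: str  # "maternal" | "paternal"
    overlaps_variant: bool


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str


@dataclass
class SimulatedEmbryo:
    """One simulated embryo: reads, per-read truth, and per-gene truth table."""

    spec: EmbryoSimSpec
    reads: list
    truth: list
    cell_state_counts: Counter
    #: per-gene dict gene_id -> {"maternal_reads", "paternal_reads", "expected_paternal_fraction"}
    truth_table: dict = field(default_factory=dict)

    @property
    def realized_xci_mix(self) -> dict:
        n = sum(self.cell_state_counts.values())
        return {s: c / n for s, c in self.cell_state_counts.items()}


# ---------------------------------------------------------------------------
# defaults encoding the biology of the cross


#: Default silencing efficiencies.  Genes subject to XCI are fully
#: silenced on the inactive X; escapers retain 70% of active-X output
#: from the inactive X; autosomal genes are untouched.
DEFAULT_SILENCING = {"subject": 1.0, "escaper": 0.3, "autosomal": 0.0}


def default_xci_mix(genotype: str, sex: str = "XX") -> dict:
    """Default per-cell XCI state proportions for each genotype.

    Controls and zygotic mutants undergo imprinted XCI (paternal X
    inactive in every cell).  Maternal-null females choose an X at
    random per cell; maternal+zygotic-null females additionally show
    biallelic Xist induction and cells that fail to upregulate Xist.
    Maternal-null males ectopically induce Xist on their single
    (maternal) X in most cells.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    if sex == "XY":
        if genotype in ("m-/-", "mz-/-"):
            return {"maternal_X_inactive": 0.9, "no_Xist": 0.1}
        return {"no_Xist": 1.0}
    if genotype in ("fl/fl", "fl/-", "-/-"):
        return {"paternal_X_inactive": 1.0}
    if genotype == "m-/-":
        return {"paternal_X_inactive": 0.5, "maternal_X_inactive": 0.5}
    # mz-/-: stronger mosaicism with biallelic and Xist-negative cells
    return {
        "paternal_X_inactive": 0.35,
        "maternal_X_inactive": 0.35,
        "both_Xist": 0.2,
        "no_Xist": 0.1,
    }


def allele_weights(gene: GeneModel, state: str, spec: EmbryoSimSpec) -> tuple:
    """Relative (maternal, paternal) expression weights of ``gene`` in a
    cell in XCI state ``state``.

    An active X allele has weight 1, a silenced allele ``1 - s`` for its
    class's silencing efficiency ``s``.  The Xist-like gene is expressed
    from inactive X chromosomes only.  Autosomes are always (1, 1).
    Males carry only the maternal X, so every X-linked paternal weight
    is 0.
    """
    if gene.silencing_class == "autosomal":
        return (1.0, 1.0)
    s = spec.silencing_efficiency.get(gene.silencing_class, 0.0)
    if spec.sex == "XY":
        if gene.is_xist_like:
            return (1.0, 0.0) if state == "maternal_X_inactive" else (0.0, 0.0)
        if state == "maternal_X_inactive":
            return (1.0 - s, 0.0)
        return (1.0, 0.0)
    if gene.is_xist_like:
        return {
            "paternal_X_inactive": (0.0, 1.0),
            "maternal_X_inactive": (1.0, 0.0),
            "both_Xist": (1.0, 1.0),
            "no_Xist": (0.0, 0.0),
        }[state]
    return {
        "paternal_X_inactive": (1.0, 1.0 - s),
        "maternal_X_inactive": (1.0 - s, 1.0),
        "both_Xist": (1.0 - s, 1.0 - s),
        "no_Xist": (1.0, 1.0),
    }[state]


def expected_paternal_fraction(gene: GeneModel, spec: EmbryoSimSpec, state_probs: dict | None = None) -> float:
    """Analytic expected paternal read fraction implied by an XCI mix.

    Reads are accepted in proportion to total (maternal + paternal)
    expression weight in the sampled cell, so the expectation is
    ``sum_s p_s * w_p(s) / sum_s p_s * (w_m(s) + w_p(s))``.  Returns
    ``nan`` for a gene with no expression under the mix (e.g. the
    Xist-like gene when no cell expresses Xist).
    """
    probs = spec.xci_mix if state_probs is None else state_probs
    num = den = 0.0
    for state, p in probs.items():
        wm, wp = allele_weights(gene, state, spec)
        num += p * wp
        den += p * (wm + wp)
    return num / den if den > 0 else float("nan")


# ---------------------------------------------------------------------------
# reference construction


def _split_exon_lengths(gene_len: int, n_exons: int) -> list:
    base = gene_len // n_exons
    lens = [base] * n_exons
    lens[0] += gene_len - base * n_exons
    return lens


def make_toy_reference(
    n_autosomal_genes: int,
    n_x_genes: int,
    gene_len: int = 1000,
    snp_rate: float = 1 / 250,
    seed: int = 0,
    n_exons: int = 2,
    intron_len: int = 200,
    spacer_len: int = 300,
    escaper_fraction: float = 0.15,
    maternal_divergence: float = 0.1,
):
    """Generate a toy reference: chromosomes, strain SNPs, and gene models.

    One autosome (``chr1``) and one X (``chrX``) are built, with genes
    laid out on alternating strands and separated by intergenic spacers.
    SNPs are placed per exonic base at rate ``snp_rate`` (default one
    per 250 bp, the strain-pair density in transcribed sequence); any
    gene that receives no SNP has its placement redrawn until it holds
    at least one, so every gene is potentially informative.  Exactly one
    X-linked gene is flagged Xist-like; a fraction of the remaining X
    genes are escapers.  At a fraction ``maternal_divergence`` of SNP
    sites the maternal strain (not the paternal) deviates from the
    reference base.

    Returns ``(genomes, variants, genes)`` where genomes is a dict
    keyed by chromosome name.
    """
    if n_autosomal_genes < 1 or n_x_genes < 1:
        raise ValueError("need at least one gene per chromosome class")
    if not 0.0 < snp_rate < 1.0:
        raise ValueError(f"snp_rate {snp_rate} outside (0, 1)")
    if gene_len < n_exons:
        raise ValueError("gene_len shorter than exon count")
    rng = np.random.default_rng(seed)

    exon_lens = _split_exon_lengths(gene_len, n_exons)
    genes: list[GeneModel] = []
    chrom_lengths: dict[str, int] = {}

    for chrom, cls, n_genes, prefix in (
        ("chr1", "autosome", n_autosomal_genes, "ag"),
        ("chrX", "X", n_x_genes, "xg"),
    ):
        cursor = spacer_len  # 0-based cursor; first exon starts at cursor+1
        for i in range(n_genes):
            exons = []
            for elen in exon_lens:
                exons.append((cursor + 1, cursor + elen))
                cursor += elen + intron_len
            cursor -= intron_len  # no intron after the last exon
            cursor += spacer_len
            genes.append(
                GeneModel(
                    gene_id=f"{prefix}{i + 1:03d}",
                    chrom=chrom,
                    strand="+" if i % 2 == 0 else "-",
                    exon_intervals=tuple(exons),
                    silencing_class="autosomal" if cls == "autosome" else "subject",
                )
            )
        chrom_lengths[chrom] = cursor + spacer_len

    # one Xist-like gene plus escapers on the X
    x_ids = [g.gene_id for g in genes if g.chrom == "chrX"]
    xist_id = x_ids[len(x_ids) // 2]
    other_x = [gid for gid in x_ids if gid != xist_id]
    n_escapers = int(round(escaper_fraction * len(other_x)))
    escaper_ids = set(
        rng.choice(other_x, size=n_escapers, replace=False) if n_escapers else []
    )
    for idx, g in enumerate(genes):
        if g.gene_id == xist_id:
            # the Xist-like gene escapes silencing by definition: it is
            # transcribed from the inactive X
            genes[idx] = replace(g, is_xist_like=True, silencing_class="escaper")
        elif g.gene_id in escaper_ids:
            genes[idx] = replace(g, silencing_class="escaper")

    genomes = {
        chrom: ToyGenome(
            chrom_name=chrom,
            sequence="".join(rng.choice(list(DNA), size=length)),
            chrom_class="autosome" if chrom == "chr1" else "X",
        )
        for chrom, length in chrom_lengths.items()
    }

    variants: list[StrainVariant] = []
    for g in genes:
        seq = genomes[g.chrom].sequence
        exonic = np.fromiter(g.exonic_positions(), dtype=np.int64)
        while True:  # redraw until the gene holds >=1 SNP
            hit = exonic[rng.random(exonic.size) < snp_rate]
            if hit.size:
                break
        for pos in hit.tolist():
            ref = seq[pos - 1]
            alts = [b for b in DNA if b != ref]
            if rng.random() < maternal_divergence:
                mat = alts[rng.integers(3)]
                others = [b for b in DNA if b != mat]
                pat = others[rng.integers(3)]
            else:
                mat = ref
                pat = alts[rng.integers(3)]
            variants.append(StrainVariant(g.chrom, int(pos), ref, mat, pat))
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return genomes, variants, genes


# ---------------------------------------------------------------------------
# embryo read simulation


def _mutate(seq: str, positions: np.ndarray, rng) -> str:
    s = list(seq)
    for p in positions.tolist():
        choices = [b for b in DNA if b != s[p]]
        s[p] = choices[rng.integers(3)]
    return "".join(s)


def simulate_embryo(spec: EmbryoSimSpec, genes, variants, reference, transcriptomes=None):
    """Simulate one embryo's reads with a per-read allele-of-origin truth table.

    Reads are exact substrings of the maternal or paternal mature
    transcript (exons concatenated, sense strand), then perturbed by
    uniform substitution errors at ``spec.error_rate``.  Per-gene raw
    counts are negative binomial around ``mean_depth``; each read is
    attributed to a uniformly drawn cell whose XCI state sets the
    relative maternal/paternal expression weights, reads are accepted in
    proportion to total weight (so silenced genes yield fewer reads and
    a fully silenced gene yields none), and the allele of origin is
    drawn from the weight ratio.

    ``transcriptomes`` may carry precomputed ``(maternal, paternal)``
    per-gene transcript dicts to avoid rebuilding pseudo-genomes.
    Returns a :class:`SimulatedEmbryo`.
    """
    from .pseudogenome import substitute_snps, strain_transcriptome, transcript_variants

    spec.validate()
    if transcriptomes is None:
        mat_tx = strain_transcriptome(substitute_snps(reference, variants, "maternal"), genes)
        pat_tx = strain_transcriptome(substitute_snps(reference, variants, "paternal"), genes)
    else:
        mat_tx, pat_tx = transcriptomes
    tvars = transcript_variants(genes, variants)

    rng = np.random.default_rng(spec.seed)
    states = list(XCI_STATES)
    probs = np.array([spec.xci_mix.get(s, 0.0) for s in states])
    cell_states = rng.choice(len(states), size=spec.n_cells, p=probs / probs.sum())
    state_counts = Counter(states[i] for i in cell_states.tolist())

    r_disp = 1.0 / spec.dispersion if spec.dispersion > 0 else None

    reads: list[SimRead] = []
    truth: list[ReadTruth] = []
    truth_table: dict = {}

    for gene in genes:
        snp_tpos = np.array([tv.tpos for tv in tvars.get(gene.gene_id, [])], dtype=np.int64)
        wm = np.empty(len(states))
        wp = np.empty(len(states))
        for i, st in enumerate(states):
            wm[i], wp[i] = allele_weights(gene, st, spec)
        # maximum total weight: both alleles fully active (one in males for X genes)
        x_linked = gene.silencing_class != "autosomal"
        max_total = 1.0 if (spec.sex == "XY" and x_linked) else 2.0

        if r_disp is None:
            n_draw = rng.poisson(spec.mean_depth)
        else:
            p_nb = r_disp / (r_disp + spec.mean_depth)
            n_draw = rng.negative_binomial(r_disp, p_nb)
        n_mat = n_pat = 0
        if n_draw > 0:
            cells = rng.integers(0, spec.n_cells, size=n_draw)
            st_idx = cell_states[cells]
            tot = wm[st_idx] + wp[st_idx]
            keep = rng.random(n_draw) < tot / max_total
            st_idx = st_idx[keep]
            tot = tot[keep]
            if st_idx.size:
                is_pat = rng.random(st_idx.size) < (wp[st_idx] / np.where(tot > 0, tot, 1.0))
                for j in range(st_idx.size):
                    allele = "paternal" if is_pat[j] else "maternal"
                    tx = (pat_tx if is_pat[j] else mat_tx)[gene.gene_id]
                    L = min(spec.read_len, len(tx))
                    start = int(rng.integers(0, len(tx) - L + 1))
                    seq = tx[start : start + L]
                    if spec.error_rate > 0:
                        errs = np.flatnonzero(rng.random(L) < spec.error_rate)
                        if errs.size:
                            seq = _mutate(seq, errs, rng)
                    overlaps = bool(((snp_tpos >= start) & (snp_tpos < start + L)).any())
                    rid = f"{spec.embryo_id}:{gene.gene_id}:{n_mat + n_pat}"
                    reads.append(SimRead(rid, seq))
                    truth.append(ReadTruth(rid, gene.gene_id, allele, overlaps))
                    if is_pat[j]:
                        n_pat += 1
                    else:
                        n_mat += 1
        realized = {s: c / spec.n_cells for s, c in state_counts.items()}
        truth_table[gene.gene_id] = {
            "maternal_reads": n_mat,
            "paternal_reads": n_pat,
            "expected_paternal_fraction": expected_paternal_fraction(gene, spec, realized),
        }

    return SimulatedEmbryo(
        spec=spec,
        reads=reads,
        truth=truth,
        cell_state_counts=state_counts,
        truth_table=truth_table,
    )
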