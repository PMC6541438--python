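"""Synthetic-data generator: determinism, SNP density, XCI regimes."""

import numpy as np
import pytest

from hybridxci import (
    EmbryoSimSpec,
    default_xci_mix,
    expected_paternal_fraction,
    make_toy_reference,
    simulate_embryo,
)
from hybridxci.io import write_fasta, write_gtf, write_vcf
from hybridxci.simulate import DEFAULT_SILENCING, GENOTYPES
from hybridxci.pseudogenome import strain_transcriptome, substitute_snps

from conftest import make_spec


def bundle_bytes(genomes, variants, genes, tmp_path):
    out = []
    for name, writer, args in (
        ("ref.fa", write_fasta, {c: g.sequence for c, g in genomes.items()}),
        ("var.vcf", write_vcf, variants),
        ("genes.gtf", write_gtf, genes),
    ):
        p = tmp_path / name
        if name == "var.vcf":
            writer(p, args, {c: len(g) for c, g in genomes.items()})
        else:
            writer(p, args)
        out.append(p.read_bytes())
    return out


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    a = make_toy_reference(3, 3, gene_len=400, seed=42)
    b = make_toy_reference(3, 3, gene_len=400, seed=42)
    (tmp_path / "a").mkdir(), (tmp_path / "b").mkdir()
    assert bundle_bytes(*a, tmp_path / "a") == bundle_bytes(*b, tmp_path / "b")
    c = make_toy_reference(3, 3, gene_len=400, seed=43)
    assert bundle_bytes(*c, tmp_path / "b") != bundle_bytes(*a, tmp_path / "a")


def test_every_gene_has_an_exonic_snp_and_one_xist_like():
    genomes, variants, genes = make_toy_reference(5, 4, gene_len=250, seed=7)
    exonic = {g.gene_id: set(g.exonic_positions()) for g in genes}
    per_gene = {
        g.gene_id: sum(1 for v in variants if v.chrom == g.chrom and v.pos in exonic[g.gene_id])
        for g in genes
    }
    assert all(n >= 1 for n in per_gene.values())
    xist = [g for g in genes if g.is_xist_like]
    assert len(xist) == 1 and xist[0].chrom == "chrX"


def test_snp_density_matches_one_per_250bp():
    """At the default rate a 1 kb transcribed gene carries ~4 SNPs."""
    _, variants, genes = make_toy_reference(30, 30, gene_len=1000, seed=3)
    mean_snps = len(variants) / len(genes)
    # 60 genes x 1000 bp, rate 1/250: expect 4 +- 3 SD of the per-gene mean
    sd = np.sqrt(4 / len(genes))
    assert abs(mean_snps - 4) < 3 * sd + 0.2  # small bump for the >=1 redraw bias


def test_variant_records_are_discriminating_and_in_range():
    genomes, variants, _ = make_toy_reference(4, 4, gene_len=300, seed=9)
    for v in variants:
        assert v.maternal_allele != v.paternal_allele
        assert genomes[v.chrom].sequence[v.pos - 1] == v.ref_allele


@pytest.mark.parametrize("bad_kw", [
    {"xci_mix": {"paternal_X_inactive": 0.5}},  # doesn't sum to 1
    {"xci_mix": {"bogus_state": 1.0}},
    {"sex": "XY", "xci_mix": {"paternal_X_inactive": 1.0}},  # no paternal X in males
    {"silencing": {"subject": 1.5, "escaper": 0.0, "autosomal": 0.0}},
])
def test_invalid_specs_are_rejected(bad_kw):
    with pytest.raises(ValueError):
        make_spec(**bad_kw).validate()


def test_imprinted_regime_all_subject_reads_maternal(small_reference, flfl_embryo):
    """Complete imprinted XCI: subject X genes maternal-only, Xist-like paternal-only."""
    _, _, genes = small_reference
    cls = {g.gene_id: g for g in genes}
    for t in flfl_embryo.truth:
        g = cls[t.gene_id]
        if g.is_xist_like:
            assert t.allele_of_origin == "paternal"
        elif g.silencing_class == "subject":
            assert t.allele_of_origin == "maternal"


def test_error_free_reads_are_substrings_of_a_parental_transcript(
        small_reference, strain_bundle, flfl_embryo):
    """Brute-force substring check of every error-free read."""
    _, _, mat_tx, pat_tx = strain_bundle
    truth = {t.read_id: t for t in flfl_embryo.truth}
    for r in flfl_embryo.reads:
        t = truth[r.read_id]
        tx = (mat_tx if t.allele_of_origin == "maternal" else pat_tx)[t.gene_id]
        assert r.sequence in tx


def test_truth_fraction_converges_to_analytic_expectation(small_reference, strain_bundle):
    """Realized paternal fractions sit within 3 binomial SD of the
    cell-mix-implied expectation at depth 2000."""
    genomes, variants, genes = small_reference
    _, _, mat_tx, pat_tx = strain_bundle
    spec = make_spec(
        genotype="m-/-", mean_depth=2000.0, seed=21,
        xci_mix={"paternal_X_inactive": 0.5, "maternal_X_inactive": 0.5},
    )
    sim = simulate_embryo(spec, genes, variants, genomes, transcriptomes=(mat_tx, pat_tx))
    mix = sim.realized_xci_mix
    for g in genes:
        row = sim.truth_table[g.gene_id]
        n = row["maternal_reads"] + row["paternal_reads"]
        if n == 0:
            continue
        p_exp = expected_paternal_fraction(g, spec, mix)
        sd = np.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(row["paternal_reads"] / n - p_exp) < 3 * sd + 1e-12, g.gene_id


def test_random_xci_truth_fraction_near_half(small_reference, strain_bundle):
    genomes, variants, genes = small_reference
    _, _, mat_tx, pat_tx = strain_bundle
    spec = make_spec(
        genotype="m-/-", mean_depth=800.0, seed=13, n_cells=10_000,
        xci_mix={"paternal_X_inactive": 0.5, "maternal_X_inactive": 0.5},
    )
    sim = simulate_embryo(spec, genes, variants, genomes, transcriptomes=(mat_tx, pat_tx))
    subj = [g.gene_id for g in genes if g.silencing_class == "subject"]
    m = sum(sim.truth_table[g]["maternal_reads"] for g in subj)
    p = sum(sim.truth_table[g]["paternal_reads"] for g in subj)
    frac = p / (m + p)
    assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / (m + p)) + 0.02


def test_male_ectopic_xist_reads_exist_and_are_maternal(small_reference, strain_bundle):
    """Maternal-null XY embryos express the Xist-like gene from their sole
    (maternal) X; every X-linked read is maternal."""
    genomes, variants, genes = small_reference
    _, _, mat_tx, pat_tx = strain_bundle
    spec = make_spec(genotype="m-/-", sex="XY", seed=17,
                     xci_mix=default_xci_mix("m-/-", "XY"))
    sim = simulate_embryo(spec, genes, variants, genomes, transcriptomes=(mat_tx, pat_tx))
    xist_id = next(g.gene_id for g in genes if g.is_xist_like)
    xist_reads = [t for t in sim.truth if t.gene_id == xist_id]
    assert xist_reads and all(t.allele_of_origin == "maternal" for t in xist_reads)
    x_ids = {g.gene_id for g in genes if g.silencing_class != "autosomal"}
    assert all(t.allele_of_origin == "maternal" for t in sim.truth if t.gene_id in x_ids)


def test_zero_expression_gene_yields_zero_reads(small_reference, strain_bundle):
    """With no Xist-expressing cells the Xist-like gene is silent, not an error."""
    genomes, variants, genes = small_reference
    _, _, mat_tx, pat_tx = strain_bundle
    spec = make_spec(genotype="fl/fl", seed=19, xci_mix={"no_Xist": 1.0})
    sim = simulate_embryo(spec, genes, variants, genomes, transcriptomes=(mat_tx, pat_tx))
    xist_id = next(g.gene_id for g in genes if g.is_xist_like)
    row = sim.truth_table[xist_id]
    assert row["maternal_reads"] == 0 and row["paternal_reads"] == 0


def test_default_mix_defined_for_every_genotype():
    for g in GENOTYPES:
        for sex in ("XX", "XY"):
            mix = default_xci_mix(g, sex)
            assert abs(sum(mix.values()) - 1.0) < 1e-12
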