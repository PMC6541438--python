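"""Per-SNP counting, the >=10-read filter, gene ratios, expression split."""

import numpy as np
import pandas as pd
import pytest

from hybridxci import (
    allelic_expression,
    assign_all,
    count_snp_alleles,
    gene_allelic_ratio,
    informative_across_samples,
    quantify_embryo,
    simulate_embryo,
)
from hybridxci.assign import ReadAssignment
from hybridxci.quantify import SnpAlleleCount
from hybridxci.simulate import GeneModel, StrainVariant

from conftest import make_spec


def snp(gene="g1", pos=100, tpos=10, m=0, p=0):
    return SnpAlleleCount(gene_id=gene, chrom="chr1", pos=pos, tpos=tpos,
                          maternal_reads=m, paternal_reads=p)


def test_paternal_pct_definition():
    assert snp(m=5, p=5).paternal_pct == 50.0
    assert snp(m=0, p=0).paternal_pct is None
    c = snp(m=3, p=1)
    assert c.paternal_pct == 25.0 and c.paternal_pct + 75.0 == 100.0


@pytest.mark.parametrize("total,retained", [(9, False), (10, True), (11, True)])
def test_snp_retention_boundary_is_inclusive_at_10(total, retained):
    """Sites need at least 10 SNP-overlapping reads; 10 itself is kept."""
    assert snp(m=total, p=0).retained(10) is retained


def test_filter_monotonicity():
    """Lowering the threshold never drops a retained SNP."""
    counts = [snp(m=a, p=b) for a, b in [(4, 5), (5, 5), (20, 0), (0, 1)]]
    for hi in range(2, 15):
        kept_hi = {id(c) for c in counts if c.retained(hi)}
        kept_lo = {id(c) for c in counts if c.retained(hi - 1)}
        assert kept_hi <= kept_lo


def test_gene_ratio_is_unweighted_mean_of_retained_snps():
    counts = [snp(pos=1, m=9, p=1), snp(pos=2, m=7, p=3), snp(pos=3, m=5, p=4)]
    # third SNP has 9 reads -> dropped; mean of 10% and 30% = 20%
    mean, n = gene_allelic_ratio(counts, min_reads=10)
    assert mean == pytest.approx(20.0) and n == 2
    mean1, n1 = gene_allelic_ratio([snp(m=2, p=8)], min_reads=10)
    assert mean1 == pytest.approx(80.0) and n1 == 1
    assert gene_allelic_ratio([snp(m=4, p=4)], min_reads=10) == (None, 0)


def test_read_covering_two_snps_increments_both():
    """Cross-checked against a brute-force interval intersection."""
    gene = GeneModel("g1", "chr1", "+", ((1, 100),), silencing_class="autosomal")
    variants = [
        StrainVariant("chr1", 20, "A", "A", "G"),
        StrainVariant("chr1", 30, "A", "A", "G"),
        StrainVariant("chr1", 90, "A", "A", "G"),
    ]
    # read spans transcript positions [10, 60): covers tpos 19 and 29, not 89
    a = ReadAssignment("r1", "maternal", gene_id="g1", offset=10, strand="+", read_len=50)
    counts = count_snp_alleles([a], [gene], variants)
    by_pos = {c.pos: c for c in counts}
    brute = {
        v.pos: int(10 <= (v.pos - 1) < 60) for v in variants
    }
    for pos, c in by_pos.items():
        assert c.maternal_reads == brute[pos] and c.paternal_reads == 0
    assert len(counts) == 3  # uncovered SNP present with (0,0)


def test_shared_reads_touch_no_snp():
    gene = GeneModel("g1", "chr1", "+", ((1, 100),), silencing_class="autosomal")
    variants = [StrainVariant("chr1", 20, "A", "A", "G")]
    a = ReadAssignment("r1", "shared", gene_id="g1", offset=0, strand="+", read_len=100)
    counts = count_snp_alleles([a], [gene], variants)
    assert counts[0].total == 0


def test_expression_split_worked_example():
    g = allelic_expression("g", "X", totalreads=200, mapped_total=10**6,
                           mean_paternal_pct=25.0, n_informative_snps=1)
    assert g.total_norm == pytest.approx(200.0)
    assert g.paternal_norm == pytest.approx(50.0)
    assert g.maternal_norm == pytest.approx(150.0)
    z = allelic_expression("g", "X", 200, 10**6, 0.0, 1)
    assert z.paternal_norm == 0.0 and z.maternal_norm == z.total_norm
    with pytest.raises(ValueError):
        allelic_expression("g", "X", 1, 0, 50.0)


def test_split_conservation_within_1e9_relative(small_reference, strain_bundle,
                                                indices, flfl_embryo):
    assignments, mapped = assign_all(
        ((r.read_id, r.sequence) for r in flfl_embryo.reads), *indices
    )
    genomes, variants, genes = small_reference
    tab = quantify_embryo(assignments, mapped, genes, variants)
    ok = tab.dropna(subset=["maternal_norm"])
    resid = (ok["maternal_norm"] + ok["paternal_norm"] - ok["total_norm"]).abs()
    assert (resid <= 1e-9 * ok["total_norm"].clip(lower=1e-300)).all()
    # totals over genes: sum(total_norm) = 1e6 * assigned/mapped
    assigned = tab["totalreads"].sum()
    assert tab["total_norm"].sum() == pytest.approx(1e6 * assigned / mapped)


def test_recovery_of_simulated_allelic_fractions(small_reference, strain_bundle, indices):
    """Gene-level mean paternal % recovers the truth-table fraction within
    3 SD of the SNP-averaged binomial approximation (depth 500, no errors)."""
    genomes, variants, genes = small_reference
    _, _, mat_tx, pat_tx = strain_bundle
    spec = make_spec(embryo_id="rec", genotype="m-/-", mean_depth=500.0, seed=23,
                     xci_mix={"paternal_X_inactive": 0.5, "maternal_X_inactive": 0.5})
    sim = simulate_embryo(spec, genes, variants, genomes, transcriptomes=(mat_tx, pat_tx))
    assignments, mapped = assign_all(
        ((r.read_id, r.sequence) for r in sim.reads), *indices
    )
    tab = quantify_embryo(assignments, mapped, genes, variants)
    for g in genes:
        row = tab.loc[g.gene_id]
        if row["n_informative_snps"] < 1:
            continue
        t = sim.truth_table[g.gene_id]
        n = t["maternal_reads"] + t["paternal_reads"]
        p_true = t["paternal_reads"] / n
        # SNP-level counts are subsamples of the gene's reads; approximate
        # each SNP's coverage by the allelic reads over that site
        n_eff = max(n * 50 / g.exonic_length, 10)
        sd = np.sqrt(max(p_true * (1 - p_true), 1e-4) / n_eff)
        assert abs(row["mean_paternal_pct"] / 100 - p_true) < 3 * sd + 0.02, g.gene_id


def test_informative_in_all_samples_requires_every_sample():
    def tab(inf):
        return pd.DataFrame(
            {"n_informative_snps": inf},
            index=[f"g{i}" for i in range(len(inf))],
        )

    tables = {
        "s1": tab([1, 1, 0, 2]),
        "s2": tab([1, 0, 0, 3]),
        "s3": tab([2, 1, 0, 1]),
        "s4": tab([1, 1, 1, 0]),
    }
    # g0 informative everywhere; g1 in 3 of 4 -> excluded; g3 in 3 of 4 -> excluded
    assert informative_across_samples(tables) == ["g0"]
    assert informative_across_samples({"s1": tab([1, 0, 1, 1])}) == ["g0", "g2", "g3"]


def test_informative_intersection_matches_brute_force_on_random_fixtures():
    rng = np.random.default_rng(17)
    genes = [f"g{i}" for i in range(30)]
    for _ in range(20):
        tables = {
            f"s{j}": pd.DataFrame(
                {"n_informative_snps": rng.integers(0, 3, size=30)}, index=genes
            )
            for j in range(rng.integers(1, 6))
        }
        expected = set(genes)
        for t in tables.values():
            expected &= {g for g in genes if t.loc[g, "n_informative_snps"] >= 1}
        got = informative_across_samples(tables)
        assert set(got) == expected
        assert got == [g for g in genes if g in expected]  # stable order


def test_empty_intersection_warns():
    t1 = pd.DataFrame({"n_informative_snps": [1, 0]}, index=["a", "b"])
    t2 = pd.DataFrame({"n_informative_snps": [0, 1]}, index=["a", "b"])
    with pytest.warns(UserWarning, match="informative"):
        assert informative_across_samples({"s1": t1, "s2": t2}) == []
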