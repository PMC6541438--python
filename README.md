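# hybridxci

Allele-specific expression analysis of X-chromosome inactivation (XCI) in
hybrid mouse embryos — with a fully synthetic hybrid-cross generator, so the
entire pipeline runs and is tested without any external data.

## The problem

In mice, preimplantation embryos silence the paternally inherited X
chromosome (*imprinted* XCI), whereas embryos that lack oocyte-derived
(maternal) PRC2/EED protein instead upregulate *Xist* on either X and switch
to *random* XCI. Detecting this switch from RNA-seq of individual hybrid
embryos — maternal *M. musculus* 129/S1-like × paternal *M. molossinus*
JF1/Ms-like, ~1 SNP per 250 bp of transcribed sequence — requires measuring,
gene by gene, what fraction of expression comes from each parental X.

`hybridxci` implements that measurement chain for people who study allelic
imbalance in hybrid crosses:

1. **Pseudo-genomes** — substitute each strain's SNP alleles into the
   reference, giving two in-silico parental genomes and transcriptomes
   (`substitute_snps`, `strain_transcriptome`).
2. **0-mismatch allelic assignment** — match every read exactly against both
   strain transcriptomes; a read matching one strain at a single locus is
   allelic, the same locus in both strains is *shared* (SNP-free), more than
   one locus is *multimapped* and excluded (`assign_read`, `assign_all`).
3. **Allelic quantification** — count allelic reads over each SNP, retain
   sites with ≥ 10 SNP-overlapping reads, average retained sites' paternal
   percentages into the gene-level allelic ratio, call genes with ≥ 1
   retained site *informative*, and split reads-per-million expression as

   `paternal_norm = total_norm × %paternal/100`, `maternal_norm = total_norm − paternal_norm`

   (`quantify_embryo`, `informative_across_samples`).
4. **Group statistics** — Welch's two-sample t-tests on per-embryo mean
   allelic ratios across genotype groups (*Eed*&nbsp;fl/fl, fl/−, −/−, m−/−,
   mz−/−), two-tailed Student's t-tests for proportion/intensity data, and
   heat-map gene ordering by the control group (`welch_test`,
   `pairwise_tests`, `order_genes_by_reference_group`).
5. **Allele-specific Xist FISH probe design** — per SNP, two detection
   oligos (one per strain, Quasar 570/670) with the polymorphic base at
   position 5 from the 5′ end, plus a mask oligo that leaves a 9–10 nt free
   hybridization window around the SNP (`design_probe_panel`,
   `validate_discrimination`).
6. **IF intensity quantification** — DAPI-threshold nucleus segmentation,
   background-region subtraction, per-embryo averaging, and stage binning by
   cell count (`segment_nuclei`, `measure_embryo`, `stage_embryo`).
7. **Synthetic data** — a seeded generator for the whole experiment:
   reference, SNPs, gene models, per-cell XCI states (imprinted, random
   mosaic, biallelic Xist, ectopic male Xist), reads with a per-read
   allele-of-origin truth table (`make_toy_reference`, `simulate_embryo`).

## Worked example

```python
from hybridxci import (
    EmbryoSimSpec, TranscriptomeIndex, assign_all, make_toy_reference,
    quantify_embryo, simulate_embryo,
)
from hybridxci.pseudogenome import substitute_snps, strain_transcriptome

genomes, variants, genes = make_toy_reference(
    n_autosomal_genes=4, n_x_genes=4, gene_len=500, seed=7)
mat_tx = strain_transcriptome(substitute_snps(genomes, variants, "maternal"), genes)
pat_tx = strain_transcriptome(substitute_snps(genomes, variants, "paternal"), genes)

spec = EmbryoSimSpec(
    embryo_id="demo", genotype="m-/-", sex="XX", n_cells=64,
    xci_mix={"paternal_X_inactive": 0.5, "maternal_X_inactive": 0.5},  # random XCI
    silencing_efficiency={"subject": 1.0, "escaper": 0.3, "autosomal": 0.0},
    mean_depth=600.0, error_rate=0.0, seed=7)
sim = simulate_embryo(spec, genes, variants, genomes, transcriptomes=(mat_tx, pat_tx))

idx = (TranscriptomeIndex(mat_tx), TranscriptomeIndex(pat_tx))
assignments, mapped = assign_all(((r.read_id, r.sequence) for r in sim.reads), *idx)
print(quantify_embryo(assignments, mapped, genes, variants).round(2))
```

prints

```
        chrom_class  n_informative_snps  mean_paternal_pct  totalreads  total_norm  maternal_norm  paternal_norm
gene_id
ag001      autosome                   2              50.54         380   108509.42       53663.46       54845.97
ag002      autosome                   1              44.44         584   166761.85       92645.47       74116.38
ag003      autosome                   2              49.70         666   190177.04       95662.50       94514.55
ag004      autosome                   2              40.61         626   178755.00      106163.93       72591.07
xg001             X                   1              48.28         243    69388.92       35890.82       33498.10
xg002             X                   2              65.12         247    70531.13       24604.64       45926.49
xg003             X                   1              30.56         317    90519.70       62860.90       27658.80
xg004             X                   1              66.00         439   125356.94       42621.36       82735.58
```

This embryo was simulated under *random* XCI (each cell silences either X
with probability ½), so both autosomal and X-linked genes hover around 50%
paternal expression; the per-gene scatter on the X reflects the finite
64-cell mosaic. Under the imprinted default (`genotype="fl/fl"`,
`xci_mix={"paternal_X_inactive": 1.0}`) X-linked subject genes drop to ~0%
paternal while the Xist-like gene is ~100% paternal. `total_norm` is
reads-per-million mapped, and `maternal_norm + paternal_norm == total_norm`
for every informative gene.

The same stages are available as a CLI:

```sh
hybridxci run --seed 1 --outdir runs/demo      # full 20-embryo experiment
hybridxci simulate --seed 1 --outdir sim/      # individual stages
hybridxci build-pseudogenomes --reference sim/reference.fa \
    --vcf sim/variants.vcf --gtf sim/genes.gtf --outdir pg/
hybridxci assign --fastq sim/reads.fastq --maternal-tx pg/maternal_tx.fa \
    --paternal-tx pg/paternal_tx.fa --out assign.tsv
```

## Layout

```
src/hybridxci/
  simulate.py      synthetic hybrid-cross generator + domain types
  pseudogenome.py  SNP substitution, strain transcriptomes
  assign.py        exact-match index, 0-mismatch allelic assignment
  quantify.py      per-SNP counts, filters, gene ratios, expression split
  group_stats.py   Welch/Student tests, pairwise tables, gene ordering
  probes.py        allele-specific FISH probe + mask design
  imaging.py       nucleus segmentation and IF intensity quantification
  pipeline.py      end-to-end seeded runs
  cli.py           `hybridxci` command-line interface
```

See `docs/methods.md` for the model, parameter defaults, and limitations.
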