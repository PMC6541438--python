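# Methods

## Scope and model

`hybridxci` analyses allele-specific expression (ASE) in a hybrid mouse
cross in which the maternal haplotype is 129/S1-like (close to the
reference genome) and the paternal haplotype is JF1/Ms-like (*M.
molossinus*, ~1 SNP per 250 bp of transcribed sequence). The biological
readout is the fraction of each X-linked gene's expression arising from the
paternal X, which separates *imprinted* X-inactivation (paternal X silent
in every cell; paternal fraction near 0 for genes subject to XCI, near 1
for Xist) from *random* X-inactivation (each cell silences either X;
paternal fraction near ½).

The pipeline operates in transcript space. Reads are matched exactly
against the two strain transcriptomes rather than spliced-aligned to a
genome: the property that matters for ASE — a read overlapping a SNP
matches exactly one strain at zero mismatches — is preserved, while
splice-aware alignment (a solved problem for standard tools) is out of
scope. The price is that this package cannot ingest reads spanning unknown
junctions or indel-containing regions; it is a measurement core and a test
bed, not an aligner.

## Allelic measurement chain

1. **Pseudo-genomes.** Each strain genome is the reference with that
   strain's SNV alleles substituted (`pseudogenome.substitute_snps`).
   Substitution validates that the record's reference allele matches the
   genome base and rejects duplicates, indels, and variants on `N`;
   chromosome lengths are invariant. Per-gene transcripts are exon
   concatenations, reverse-complemented for minus-strand genes, so the two
   strain transcripts of a gene are equal-length and differ exactly at its
   exonic SNPs.
2. **Assignment.** Reads are classified by exhaustive exact matching
   against both transcriptomes, both orientations
   (`assign.TranscriptomeIndex` seeds on the first k-mer, k = 25 by
   default, and verifies the full read, which finds all occurrences).
   Classification is a partition: `maternal` / `paternal` (single locus in
   one strain), `shared` (the same single locus in both strains — a
   SNP-free span, impossible for a SNP-overlapping read at 0 mismatches),
   `multimapped` (more than one locus anywhere, including two placements
   within one gene; excluded from everything), `unmapped`. Orientation is
   searched but never used for assignment, since allele identity is
   strand-agnostic. Any sequencing error makes a read unmapped rather than
   mis-assigned.
3. **Quantification.** Each allelic read increments every SNP inside its
   matched span on its haplotype. Sites with ≥ `min_snp_reads` (default
   10, boundary inclusive) are retained; the gene-level ratio is the
   *unweighted* mean of retained sites' paternal percentages; genes with
   ≥ 1 retained site are *informative*; cross-sample analyses intersect
   informative sets over all samples. Expression is normalized to
   reads-per-million mapped (`mapped` = uniquely placed reads of any
   status); the 10⁶ scale is a convention that cancels in every ratio.
   The maternal/paternal split multiplies the normalized total by the
   SNP-derived paternal proportion, so the two components reconstruct the
   total exactly.
4. **Statistics.** Allelic-ratio comparisons between genotype groups use
   Welch's two-sample t-test (unequal variances/sizes across groups);
   normalized-expression and imaging proportion comparisons use the
   pooled-variance two-tailed Student's t-test. Both are two-tailed, raw
   (uncorrected) p-values, mirroring how such pairwise group tables are
   reported; a Bonferroni column is emitted as clearly-extra output.
   Identical constant groups return t = 0, p = 1 by convention. Heat-map
   rows are ordered by the control-group (fl/fl) mean ratio, ties broken
   lexicographically.

## Synthetic experiment

The generator (`simulate`) emulates the study design rather than any real
dataset. Defaults, chosen once:

| Parameter | Default | Why |
|---|---|---|
| genotype groups | fl/fl 4, fl/− 4, −/− 4, m−/− 5, mz−/− 3 | the study's per-group embryo counts |
| genes | 40 autosomal + 20 X-linked | desk-scale; one gene flagged Xist-like, 15% of the other X genes escapers |
| `gene_len` | 500 exonic bp (2 exons) | with `mean_depth` below, a typical SNP site comfortably clears the 10-read filter, as in real blastocyst libraries |
| `snp_rate` | 1/250 per exonic bp | the strain pair's density in transcribed RNA; placement is redrawn until every gene holds ≥ 1 SNP |
| `mean_depth` | 800 reads | expected count for a fully biallelic gene; negative binomial with dispersion 0.1 (a standard overdispersed choice — no count model is claimed by the study) |
| `read_len` | 50 nt, single-end, sense strand | the real libraries were 50 bp paired-end; single-end suffices for allelic logic and is noted as a fidelity reduction |
| `error_rate` | 0.005 substitutions/base | Illumina-scale; errored reads fail 0-mismatch mapping by design |
| `n_cells` | 64 | blastocyst scale; cell states are drawn once per embryo, reads sample cells uniformly |
| silencing efficiency | subject 1.0, escaper 0.3, autosomal 0.0 | complete silencing for XCI-subject genes gives the clean imprinted pattern; escapers retain 70% inactive-X output |
| XCI mixes | fl/fl, fl/−, −/−: imprinted (paternal X inactive, all cells); m−/−: 50/50 random; mz−/−: 0.35/0.35 + 0.20 biallelic Xist + 0.10 Xist-negative; m−/− males: 0.9 ectopic maternal-X Xist | the regimes observed for these genotypes |

Mechanics: per gene, a raw read count is drawn, each read is attributed to
a random cell, accepted with probability proportional to the cell's total
(maternal + paternal) expression weight for that gene — so silencing
reduces yield and a fully silent gene yields zero reads — and its allele is
drawn from the weight ratio. An active allele has weight 1, a silenced one
1 − s; the Xist-like gene is expressed only from inactive X chromosomes
(both under biallelic Xist, neither in Xist-negative cells); males carry
only the maternal X; autosomes are always 1:1. Every read records its
haplotype of origin and whether it spans a SNP, and the per-gene truth
table carries the analytic expected paternal fraction implied by the
embryo's realized cell-state mix
(`Σ p_s·w_p(s) / Σ p_s·(w_m(s)+w_p(s))`), which read-level fractions
approach at binomial rate.

What the generator does **not** model — and what passing tests therefore do
not show about real data: splicing isoforms and junction reads, indels and
structural variation, mapping bias between strains, fragment/GC biases,
PCR duplicates, paired-end geometry, base-quality structure, cross-cell
expression heterogeneity beyond the XCI state, and any Xist-specific
repeat-driven mappability loss.

## Probe design

Detection oligos are reverse complements of the 28-nt (configurable)
strain-transcript window that places the SNP at base 5 from the oligo's 5′
end; the two strain oligos of a SNP differ only there (SNPs whose window
contains a second SNP are excluded). One unlabeled mask per SNP is
complementary to the oligo's 3′ portion, leaving a free window of 10 nt
(9 allowed) that always contains the SNP; the masked region is outside the
window and thus strain-invariant, so a single mask serves both oligos —
10 nM mask against 2 × 5 nM detection oligos, a 1:1 pairing ratio. When
more usable SNPs exist than probes requested (default 5 per allele), the
panel is chosen by greedy max-spacing along the transcript to spread the
signal; oligo length and spacing are package conventions, as no
thermodynamic criteria are part of the procedure. `validate_discrimination`
checks every free window: perfect reverse-complement match to its own
strain, exactly one mismatch (the SNP) to the alternate.

## IF quantification

2D multi-channel images are segmented on the DAPI channel: Otsu threshold
(pluggable), removal of sub-16-pixel specks, connected components. Per
nucleus and channel, the mean intensity minus the mean of a user-supplied
non-nuclear background rectangle (which must not intersect any ROI) gives
the corrected value; the embryo value is the unweighted mean over nuclei.
Background subtraction is linear: scaling the image scales corrected means,
offsets cancel. Touching nuclei merge into one ROI — the known limitation
of plain threshold segmentation. Stage bins by cell count: 2–3 → ~2-cell,
4–5 → ~4-cell, 6–10 → ~8-cell, 14–19 → ~16-cell; anything else (1, 11–13,
≥ 20) is `unstaged` rather than forced into a nearest bin. The original
procedure was voxel-based on z-stacks; this 2D re-implementation is a
stated fidelity reduction.

## Numerical choices and degenerate inputs

- All randomness flows through one `numpy` `Generator` per seeded unit
  (reference, embryo, image); per-embryo seeds are derived from the run
  seed, so full runs are byte-reproducible.
- Zero-coverage SNPs have an undefined (not 0) paternal percentage;
  non-informative genes are a state, not an error; an empty
  informative-in-all-samples intersection warns and returns empty.
- `mapped_total = 0` is a hard error for normalization; a zero-expression
  gene is fine (zero reads).
- Split conservation holds to ≤ 10⁻⁹ relative tolerance (it is one
  subtraction).
- Ties in gene ordering break lexicographically; sort order is invariant
  to input row permutation.
- Reads shorter than the index k-mer fall back to full-scan lookup; reads
  containing `N` can never match at 0 mismatches and come back unmapped.

## Known limitations

Transcript-space matching (no junctions/indels), gene-level multimapper
definition (two placements in one gene count as multimapping — a
conservative reading of "all multi-mapping reads excluded"), no
mapping-bias correction, no beta-binomial shrinkage of allelic ratios, no
multiple-testing correction in the primary outputs, 2D-only imaging, and a
simulator whose distributional choices (negative binomial counts, uniform
errors) are conventions of this package, not claims about the biology.
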