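"""Strain pseudo-genome construction.

Substitutes strain SNP alleles into the reference to produce the two
in-silico parental genomes (maternal 129/S1-like, paternal JF1/Ms-like)
and derives per-gene mature-transcript sequences from each.  Only SNVs
are handled, so every pseudo-chromosome has exactly the reference
length and differs from it at the substituted positions alone.
"""

from __future__ import annotations

from dataclasses import dataclass

from .simulate import GeneModel, StrainVariant, ToyGenome

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMP)[::-1]

STRAIN_LABELS = ("maternal", "paternal")


@dataclass(frozen=True)
class StrainGenome:
    """One strain's pseudo-genome: label plus per-chromosome sequences."""

    strain_label: str
    sequences: dict  # chrom -> str

    def __post_init__(self):
        if self.strain_label not in STRAIN_LABELS:
            raise ValueError(f"strain_label must be one of {STRAIN_LABELS}")


@dataclass(frozen=True)
class TranscriptVariant:
    """A variant lifted into transcript coordinates (0-based, 5'->3').

    Alleles are given in transcript orientation, i.e. complemented for
    minus-strand genes.
    """

    gene_id: str
    tpos: int
    variant: StrainVariant
    maternal_base: str
    paternal_base: str

    def base(self, strain: str) -> str:
        return self.maternal_base if strain == "maternal" else self.paternal_base


def substitute_snps(reference, variants, which: str) -> StrainGenome:
    """Build one strain genome by substituting that strain's SNP alleles.

    ``reference`` maps chromosome name to :class:`ToyGenome`.  Every
    variant must lie within its chromosome and carry a ``ref_allele``
    matching the reference base at its position; a mismatch or a
    duplicated position is a hard error because it signals inconsistent
    inputs.  Variants on reference ``N`` bases are rejected.
    """
    if which not in STRAIN_LABELS:
        raise ValueError(f"which must be one of {STRAIN_LABELS}, got {which!r}")
    buffers = {}
    for chrom, genome in reference.items():
        seq = genome.sequence if isinstance(genome, ToyGenome) else str(genome)
        buffers[chrom] = bytearray(seq, "ascii")
    seen = set()
    for v in variants:
        if v.chrom not in buffers:
            raise ValueError(f"variant {v.chrom}:{v.pos}: unknown chromosome")
        buf = buffers[v.chrom]
        if not 1 <= v.pos <= len(buf):
            raise ValueError(f"variant {v.chrom}:{v.pos}: outside chromosome (len {len(buf)})")
        key = (v.chrom, v.pos)
        if key in seen:
            raise ValueError(f"variant {v.chrom}:{v.pos}: duplicate position")
        seen.add(key)
        ref_base = chr(buf[v.pos - 1])
        if ref_base == "N":
            raise ValueError(f"variant {v.chrom}:{v.pos}: reference base is N")
        if ref_base != v.ref_allele:
            raise ValueError(
                f"variant {v.chrom}:{v.pos}: ref_allele {v.ref_allele!r} does not match "
                f"reference base {ref_base!r}"
            )
        buf[v.pos - 1] = ord(v.allele(which))
    return StrainGenome(which, {c: b.decode("ascii") for c, b in buffers.items()})


def strain_transcriptome(genome, genes) -> dict:
    """Per-gene mature transcript sequences (exons concatenated, 5'->3').

    Minus-strand genes are reverse-complemented.  ``genome`` may be a
    :class:`StrainGenome`, a dict of :class:`ToyGenome` (the reference),
    or a plain chrom->sequence dict.
    """
    if isinstance(genome, StrainGenome):
        seqs = genome.sequences
    else:
        seqs = {
            c: (g.sequence if isinstance(g, ToyGenome) else str(g)) for c, g in genome.items()
        }
    out = {}
    for gene in genes:
        if gene.chrom not in seqs:
            raise ValueError(f"{gene.gene_id}: chromosome {gene.chrom} absent from genome")
        chrom_seq = seqs[gene.chrom]
        parts = []
        for start, end in gene.exon_intervals:
            if end > len(chrom_seq):
                raise ValueError(f"{gene.gene_id}: exon ({start},{end}) out of chromosome bounds")
            parts.append(chrom_seq[start - 1 : end])
        tx = "".join(parts)
        out[gene.gene_id] = reverse_complement(tx) if gene.strand == "-" else tx
    return out


def transcript_variants(genes, variants) -> dict:
    """Lift exonic variants into transcript coordinates for each gene.

    Returns gene_id -> list of :class:`TranscriptVariant` sorted by
    transcript position.  Intronic/intergenic variants are dropped (they
    cannot be seen by transcript-space reads).
    """
    by_chrom: dict = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    out: dict = {g.gene_id: [] for g in genes}
    for gene in genes:
        tlen = gene.exonic_length
        offset = 0
        for start, end in gene.exon_intervals:
            for v in by_chrom.get(gene.chrom, []):
                if start <= v.pos <= end:
                    fwd = offset + (v.pos - start)
                    if gene.strand == "+":
                        tpos, mat, pat = fwd, v.maternal_allele, v.paternal_allele
                    else:
                        tpos = tlen - 1 - fwd
                        mat = v.maternal_allele.translate(_COMP)
                        pat = v.paternal_allele.translate(_COMP)
                    out[gene.gene_id].append(
                        TranscriptVariant(gene.gene_id, tpos, v, mat, pat)
                    )
            offset += end - start + 1
        out[gene.gene_id].sort(key=lambda tv: tv.tpos)
    return out
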