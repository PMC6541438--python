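"""Reading and writing of the standard file formats.

FASTA, VCF v4.2, GTF, FASTQ (Phred+33) and TSV.  The VCF carries the
strain alleles in ``MAT``/``PAT`` INFO fields (REF is the reference
base; the maternal 129/S1-like allele usually but not always equals
REF — the convention is documented in the header).  Writers emit
records in deterministic order so that identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import pandas as pd
import pysam
from Bio import SeqIO

from .simulate import GeneModel, StrainVariant, ToyGenome

FASTA_WIDTH = 60


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(path, records: dict) -> None:
    """Write name -> sequence pairs, 60-column wrapped."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WIDTH):
                fh.write(seq[i : i + FASTA_WIDTH] + "\n")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(path, genomes: dict) -> None:
    write_fasta(path, {name: g.sequence for name, g in genomes.items()})


# ---------------------------------------------------------------------------
# VCF


def write_vcf(path, variants, contig_lengths: dict) -> None:
    """Write strain SNVs as VCF v4.2 with MAT/PAT allele INFO fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=MAT,Number=1,Type=String,Description="Maternal strain '
            '(129/S1-like) allele">\n'
        )
        fh.write(
            '##INFO=<ID=PAT,Number=1,Type=String,Description="Paternal strain '
            '(JF1/Ms-like) allele">\n'
        )
        fh.write(
            "##convention=REF is the reference-genome base; the maternal allele "
            "equals REF at most sites but may differ; MAT and PAT always differ "
            "from each other\n"
        )
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            alts = sorted({a for a in (v.maternal_allele, v.paternal_allele) if a != v.ref_allele})
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{','.join(alts)}\t.\tPASS\t"
                f"MAT={v.maternal_allele};PAT={v.paternal_allele}\n"
            )


def read_vcf(path) -> list:
    """Read StrainVariants back from a VCF written by :func:`write_vcf`.

    Only biallelic SNVs with MAT/PAT INFO fields are accepted; indels or
    incomplete records are a hard error.
    """
    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if len(rec.ref) != 1 or any(len(a) != 1 for a in (rec.alts or ())):
                raise ValueError(f"{rec.chrom}:{rec.pos}: only SNVs are supported")
            try:
                mat = rec.info["MAT"]
                pat = rec.info["PAT"]
            except KeyError as exc:
                raise ValueError(f"{rec.chrom}:{rec.pos}: missing MAT/PAT INFO field") from exc
            variants.append(StrainVariant(rec.chrom, rec.pos, rec.ref, str(mat), str(pat)))
    return variants


# ---------------------------------------------------------------------------
# GTF


def write_gtf(path, genes) -> None:
    """Write gene models as GTF (gene + exon features)."""
    with open(path, "w") as fh:
        for g in genes:
            start, end = g.span
            attrs = (
                f'gene_id "{g.gene_id}"; silencing_class "{g.silencing_class}"; '
                f'is_xist_like "{str(g.is_xist_like).lower()}";'
            )
            fh.write(
                f"{g.chrom}\thybridxci\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for i, (es, ee) in enumerate(g.exon_intervals, start=1):
                fh.write(
                    f"{g.chrom}\thybridxci\texon\t{es}\t{ee}\t.\t{g.strand}\t.\t"
                    f'{attrs} exon_number "{i}";\n'
                )


def read_gtf(path) -> list:
    """Read gene models back from a GTF written by :func:`write_gtf`."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes["gene_id"][0]
        exons = []
        for ex in db.features_of_type("exon"):
            if ex.attributes["gene_id"][0] == gid:
                exons.append((ex.start, ex.end))
        exons.sort()
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=feat.seqid,
                strand=feat.strand,
                exon_intervals=tuple(exons),
                is_xist_like=feat.attributes.get("is_xist_like", ["false"])[0] == "true",
                silencing_class=feat.attributes.get("silencing_class", ["autosomal"])[0],
            )
        )
    return genes


# ---------------------------------------------------------------------------
# FASTQ


def write_fastq(path, reads) -> None:
    """Write (read_id, sequence) pairs as Phred+33 FASTQ, quality 'I' (Q40)."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path):
    """Yield (read_id, sequence) pairs; malformed records raise with the
    offending record number."""
    with open(path) as fh:
        n = 0
        while True:
            header = fh.readline()
            if not header:
                break
            n += 1
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record #{n} in {path}")
            yield header[1:].split()[0].rstrip("\n"), seq


# ---------------------------------------------------------------------------
# tables


def write_tsv(path, df: pd.DataFrame, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def genomes_from_fasta(path, x_chroms=("chrX",)) -> dict:
    seqs = read_fasta(path)
    return {
        name: ToyGenome(name, seq, "X" if name in x_chroms else "autosome")
        for name, seq in seqs.items()
    }
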