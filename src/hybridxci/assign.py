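"""Zero-mismatch allelic read assignment.

Each read is matched exactly (no mismatches allowed) against the
maternal and paternal strain transcriptomes, in both orientations.  A
read hitting a single locus in only one strain is allelic for that
strain; the same single locus in both strains is ``shared`` (a SNP-free
span, counted for totals but never for allelic counts); more than one
distinct locus anywhere is ``multimapped`` and excluded; no hit at all
is ``unmapped``.  The strict 0-mismatch rule means any sequencing error
knocks a read out rather than mis-assigning it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pseudogenome import reverse_complement

STATUSES = ("maternal", "paternal", "shared", "multimapped", "unmapped")


@dataclass(frozen=True)
class ReadAssignment:
    """Outcome of assigning one read.

    ``positions_hit`` counts exact-match loci per strain (maternal,
    paternal).  For uniquely placed reads, ``offset``/``strand`` give
    the transcript-space location (0-based, '+' = read matches the
    transcript sense strand) and ``read_len`` the matched length.
    """

    read_id: str
    status: str
    gene_id: str | None = None
    positions_hit: tuple = (0, 0)
    offset: int | None = None
    strand: str | None = None
    read_len: int = 0


class TranscriptomeIndex:
    """Exact-substring index over a per-gene transcript dict.

    Seeds on the first ``k`` bases of the query and verifies the full
    read, which finds *all* exact occurrences (any occurrence of the
    read places its first k-mer at the same offset).  Queries shorter
    than ``k`` fall back to a full scan.
    """

    def __init__(self, transcripts: dict, k: int = 25):
        if k < 1:
            raise ValueError("k must be positive")
        self.k = k
        self.transcripts = dict(transcripts)
        self._kmers: dict = {}
        for gene_id, seq in self.transcripts.items():
            for i in range(len(seq) - k + 1):
                self._kmers.setdefault(seq[i : i + k], []).append((gene_id, i))

    def _exact_hits(self, query: str):
        """All (gene_id, offset) where ``query`` occurs verbatim."""
        if len(query) >= self.k:
            for gene_id, off in self._kmers.get(query[: self.k], ()):
                seq = self.transcripts[gene_id]
                if seq.startswith(query, off):
                    yield gene_id, off
        else:
            for gene_id, seq in self.transcripts.items():
                start = seq.find(query)
                while start != -1:
                    yield gene_id, start
                    start = seq.find(query, start + 1)

    def lookup(self, read: str) -> set:
        """All loci ``(gene_id, offset, strand)`` exactly matching the read.

        Both orientations are searched; the reported offset is always in
        transcript coordinates of the matched span.
        """
        hits = {(g, o, "+") for g, o in self._exact_hits(read)}
        rc = reverse_complement(read)
        hits |= {(g, o, "-") for g, o in self._exact_hits(rc)}
        return hits


def assign_read(read_id: str, sequence: str, maternal_index: TranscriptomeIndex,
                paternal_index: TranscriptomeIndex) -> ReadAssignment:
    """Classify one read against both strain transcriptomes.

    Loci are compared across strains by ``(gene, offset, strand)``;
    because the two strain transcripts of a gene have equal length, a
    SNP-free read occupies the identical locus in both and is
    ``shared``.  Any read with more than one distinct locus in the
    union (two genes, or two placements within one gene) is
    ``multimapped``.  Reads containing N can never match and come back
    ``unmapped``.
    """
    if not sequence:
        raise ValueError(f"read {read_id!r}: empty sequence")
    loci_m = maternal_index.lookup(sequence)
    loci_p = paternal_index.lookup(sequence)
    all_loci = loci_m | loci_p
    hit_counts = (len(loci_m), len(loci_p))
    if not all_loci:
        return ReadAssignment(read_id, "unmapped", positions_hit=hit_counts)
    if len(all_loci) > 1:
        return ReadAssignment(read_id, "multimapped", positions_hit=hit_counts)
    (gene_id, offset, strand), = all_loci
    if loci_m and loci_p:
        status = "shared"
    elif loci_m:
        status = "maternal"
    else:
        status = "paternal"
    return ReadAssignment(
        read_id, status, gene_id=gene_id, positions_hit=hit_counts,
        offset=offset, strand=strand, read_len=len(sequence),
    )


def assign_all(reads, maternal_index: TranscriptomeIndex,
               paternal_index: TranscriptomeIndex):
    """Assign an iterable of ``(read_id, sequence)`` pairs.

    Returns ``(assignments, mapped_total)`` where the mapped total
    counts uniquely placed reads (maternal + paternal + shared);
    multimapped and unmapped reads are excluded from it, mirroring the
    exclusion of multi-mappers from all downstream analysis.
    """
    assignments = []
    mapped_total = 0
    for read_id, sequence in reads:
        a = assign_read(read_id, sequence, maternal_index, paternal_index)
        assignments.append(a)
        if a.status in ("maternal", "paternal", "shared"):
            mapped_total += 1
    return assignments, mapped_total
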