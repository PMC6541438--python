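"""Allele-specific Xist RNA FISH probe design.

Designs SNP-discriminating single-molecule FISH detection oligos with
the polymorphic base at the fifth position from the 5' end, plus
unlabeled mask oligos complementary to the 3' portion of each detection
oligo so that only a 9–10 nt window around the SNP is free to nucleate
hybridization — short enough that a single mismatch destabilizes
binding to the alternate allele.  Both strains' panels use the same SNP
set; maternal-strain oligos carry the Quasar 570 dye label and
paternal-strain oligos Quasar 670.  The hybridization mix uses 5 nM per
detection oligo and 10 nM mask, a 1:1 mask:detection ratio (each mask
serves the two strain oligos of its SNP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .pseudogenome import reverse_complement

SNP_POSITION_FROM_5P = 5  # discriminating base position in the detection oligo
DEFAULT_PROBE_LEN = 28
DEFAULT_FREE_WINDOW = 10
ALLOWED_FREE_WINDOWS = (9, 10)
DYES = {"maternal": "Quasar 570", "paternal": "Quasar 670"}


@dataclass(frozen=True)
class AlleleProbe:
    """One strain-specific detection oligo (written 5'->3')."""

    name: str
    strain: str
    sequence: str
    snp_tpos: int  # 0-based transcript coordinate of the SNP
    snp_index_from_5p: int
    dye_label: str
    target_window: tuple  # (start, end) 0-based half-open transcript span


@dataclass(frozen=True)
class MaskOligo:
    """Unlabeled mask complementary to the 3' portion of its detection pair."""

    name: str
    sequence: str
    snp_tpos: int
    free_window: int


@dataclass(frozen=True)
class HybMix:
    """Hybridization-mix metadata."""

    detection_conc_nM: float = 5.0
    mask_conc_nM: float = 10.0
    ratio: str = "1:1"  # mask : detection, at the oligo-pairing level


@dataclass
class ProbePanel:
    probes: list = field(default_factory=list)
    masks: list = field(default_factory=list)
    mix: HybMix = field(default_factory=HybMix)

    def by_strain(self, strain: str) -> list:
        return [p for p in self.probes if p.strain == strain]


def _usable_snps(snp_tpositions, tlen: int, probe_len: int) -> list:
    """SNPs with enough flanking transcript sequence for the probe window.

    The probe covers transcript positions [t-4-(probe_len-5), t+4]
    (0-based), so the SNP needs probe_len-5 bases 3'-ward in probe
    coordinates and 4 bases on the other side.
    """
    usable, skipped = [], []
    for t in snp_tpositions:
        w_end = t + SNP_POSITION_FROM_5P - 1  # inclusive
        w_start = w_end - probe_len + 1
        if w_start >= 0 and w_end < tlen:
            usable.append(t)
        else:
            skipped.append(t)
    if skipped:
        warnings.warn(
            f"{len(skipped)} SNP(s) too close to a transcript end for a "
            f"{probe_len} nt probe: {skipped}",
            stacklevel=3,
        )
    return usable


def _greedy_max_spacing(tpositions: list, n: int) -> list:
    """Pick ``n`` SNPs spread along the transcript: endpoints first, then
    repeatedly the candidate maximizing its minimum distance to the
    chosen set (ties to the smaller coordinate)."""
    pos = sorted(tpositions)
    if n >= len(pos):
        return pos
    if n == 1:
        return [pos[len(pos) // 2]]
    chosen = [pos[0], pos[-1]]
    remaining = pos[1:-1]
    while len(chosen) < n:
        best = max(remaining, key=lambda t: (min(abs(t - c) for c in chosen), -t))
        chosen.append(best)
        remaining.remove(best)
    return sorted(chosen)


def design_probe_panel(maternal_tx: str, paternal_tx: str, snp_tpositions,
                       n_probes: int = 5,
                       probe_len: int = DEFAULT_PROBE_LEN,
                       free_window: int = DEFAULT_FREE_WINDOW,
                       gene_id: str = "xist") -> ProbePanel:
    """Design the allele-specific detection + mask oligo panel.

    ``snp_tpositions`` are 0-based transcript coordinates where the two
    strain transcripts differ.  Exactly ``n_probes`` SNPs are chosen
    (greedy max-spacing along the transcript); each yields one detection
    oligo per strain — reverse complements of the strain transcript
    window placing the SNP at base 5 from the oligo 5' end — plus one
    shared mask complementary to the oligo 3' portion, leaving
    ``free_window`` (9 or 10) nt free around the SNP.  SNPs whose probe
    window would contain a second SNP are excluded so the two strain
    oligos differ at position 5 only.
    """
    if len(maternal_tx) != len(paternal_tx):
        raise ValueError("strain transcripts must have equal length")
    if free_window not in ALLOWED_FREE_WINDOWS:
        raise ValueError(f"free_window must be one of {ALLOWED_FREE_WINDOWS}")
    if probe_len <= free_window:
        raise ValueError("probe_len must exceed free_window")
    if n_probes < 1:
        raise ValueError("n_probes must be positive")
    tlen = len(maternal_tx)
    diff_positions = {i for i in range(tlen) if maternal_tx[i] != paternal_tx[i]}
    bad = [t for t in snp_tpositions if t not in diff_positions]
    if bad:
        raise ValueError(f"positions {bad} do not discriminate the strain transcripts")

    usable = _usable_snps(sorted(snp_tpositions), tlen, probe_len)
    # drop SNPs whose window holds another discriminating site
    isolated = []
    for t in usable:
        w_end = t + SNP_POSITION_FROM_5P - 1
        w_start = w_end - probe_len + 1
        others = diff_positions & set(range(w_start, w_end + 1))
        if others == {t}:
            isolated.append(t)
    if len(isolated) < n_probes:
        raise ValueError(
            f"need {n_probes} usable SNPs but only {len(isolated)} available "
            f"(deficit {n_probes - len(isolated)})"
        )
    chosen = _greedy_max_spacing(isolated, n_probes)

    panel = ProbePanel(mix=HybMix())
    for i, t in enumerate(chosen, start=1):
        w_end = t + SNP_POSITION_FROM_5P - 1
        w_start = w_end - probe_len + 1
        for strain, tx in (("maternal", maternal_tx), ("paternal", paternal_tx)):
            oligo = reverse_complement(tx[w_start : w_end + 1])
            panel.probes.append(
                AlleleProbe(
                    name=f"{gene_id}_snp{i}_{strain}",
                    strain=strain,
                    sequence=oligo,
                    snp_tpos=t,
                    snp_index_from_5p=SNP_POSITION_FROM_5P,
                    dye_label=DYES[strain],
                    target_window=(w_start, w_end + 1),
                )
            )
        # the masked 3' region lies outside the SNP window, hence is
        # identical between strains; one mask serves both oligos
        probe_m = panel.probes[-2].sequence
        probe_p = panel.probes[-1].sequence
        mask_seq_m = reverse_complement(probe_m[free_window:])
        mask_seq_p = reverse_complement(probe_p[free_window:])
        assert mask_seq_m == mask_seq_p
        panel.masks.append(
            MaskOligo(
                name=f"{gene_id}_snp{i}_mask",
                sequence=mask_seq_m,
                snp_tpos=t,
                free_window=free_window,
            )
        )
    return panel


def validate_discrimination(panel: ProbePanel, maternal_tx: str, paternal_tx: str) -> list:
    """Check every detection oligo's free window against both strains.

    The unmasked (5') region must match its own strain's transcript
    perfectly (as a reverse complement) and mismatch the alternate
    strain at exactly one position — the SNP.  Returns a list of
    failure dicts; an empty list means the panel discriminates.
    """
    failures = []
    txs = {"maternal": maternal_tx, "paternal": paternal_tx}
    for probe in panel.probes:
        mask = next(m for m in panel.masks if m.snp_tpos == probe.snp_tpos)
        free = probe.sequence[: mask.free_window]
        w_start, w_end = probe.target_window
        # free region pairs with the 3'-most part of the target window
        target_span = (w_end - mask.free_window, w_end)
        own = txs[probe.strain][target_span[0] : target_span[1]]
        alt_strain = "paternal" if probe.strain == "maternal" else "maternal"
        alt = txs[alt_strain][target_span[0] : target_span[1]]
        own_rc = reverse_complement(own)
        alt_rc = reverse_complement(alt)
        own_mm = sum(1 for x, y in zip(free, own_rc) if x != y)
        alt_mm = [i for i, (x, y) in enumerate(zip(free, alt_rc)) if x != y]
        ok = own_mm == 0 and len(alt_mm) == 1 and alt_mm[0] == probe.snp_index_from_5p - 1
        if not ok:
            failures.append(
                {
                    "probe": probe.name,
                    "own_strain_mismatches": own_mm,
                    "alt_strain_mismatches": len(alt_mm),
                    "alt_mismatch_positions": alt_mm,
                }
            )
    return failures


def order_sheet(panel: ProbePanel):
    """Rows for an oligo order sheet (name, sequence, dye, role)."""
    rows = [
        {"name": p.name, "sequence": p.sequence, "dye": p.dye_label, "role": "detection",
         "strain": p.strain}
        for p in panel.probes
    ]
    rows += [
        {"name": m.name, "sequence": m.sequence, "dye": "", "role": "mask", "strain": ""}
        for m in panel.masks
    ]
    return rows
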