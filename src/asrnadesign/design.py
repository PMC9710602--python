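"""Antisense-RNA design: window placement and reverse complementation.

An asRNA is the perfect reverse complement of a fixed-length window of the
target mRNA.  The window is anchored on the start codon: mRNA coordinate 0
is the first base of the start codon and the ``offset`` parameter is the
mRNA coordinate of the window's 5'-most base, negative values lying
upstream.  The default window (length 21, offset −8) therefore spans mRNA
positions −8..+12, overlapping the typical Shine–Dalgarno site, the start
codon and the first bases of the coding sequence — the region where
antisense occlusion blocks translation initiation most effectively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .genome_io import GeneFeature, Genome

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: span of the Shine–Dalgarno region assumed by the documentation helpers,
#: in mRNA coordinates (half-open); user-adjustable wherever it is consumed.
DEFAULT_SD_SPAN = (-15, -4)

MAX_ROUNDS = 2  # design → screen → redesign once → screen; never a third cycle


class UndesignableWindowError(ValueError):
    """The requested window cannot be placed for this gene.

    ``reason`` is machine-readable: one of ``past_contig_start``,
    ``past_contig_end``, ``past_cds_end``, ``window_exceeds_genome``.
    """

    def __init__(self, locus_tag: str, reason: str, detail: str):
        self.locus_tag = locus_tag
        self.reason = reason
        super().__init__(f"{locus_tag}: {reason}: {detail}")


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class DesignParams:
    """Design-side parameters.

    asrna_length
        Length of the designed asRNA in nt (default 21).
    offset
        mRNA coordinate of the window's 5'-most base (default −8, placing
        the window over the Shine–Dalgarno region and start codon).
    redesign_step
        How far downstream the round-2 window moves when round 1 is flagged
        for off-targets; defaults to ``asrna_length`` so the two windows are
        disjoint.
    """

    asrna_length: int = 21
    offset: int = -8
    redesign_step: Optional[int] = None

    def __post_init__(self) -> None:
        if self.asrna_length < 10:
            raise ValueError(
                f"asrna_length must be >= 10 nt (got {self.asrna_length}); "
                "shorter probes cannot be screened meaningfully"
            )
        if self.redesign_step is None:
            self.redesign_step = self.asrna_length
        if self.redesign_step < 1:
            raise ValueError("redesign_step must be positive")

    @property
    def max_rounds(self) -> int:
        return MAX_ROUNDS


@dataclass(frozen=True)
class TargetWindow:
    """The genomic footprint an asRNA binds, on the gene's coding strand."""

    contig_id: str
    genomic_start: int  # 0-based inclusive, in [0, contig length)
    genomic_end: int    # exclusive; may exceed contig length on circular wrap
    strand: int         # coding strand of the gene
    offset: int         # mRNA coordinate of the window's 5'-most base

    @property
    def length(self) -> int:
        return self.genomic_end - self.genomic_start


@dataclass(frozen=True)
class AsRNADesign:
    locus_tag: str
    round: int  # 1 or 2
    window: TargetWindow
    target_sense_seq: str  # mRNA-sense, 5'->3'
    asrna_seq: str         # 5'->3'


def compute_window(
    feature: GeneFeature, offset: int, length: int, genome: Genome
) -> TargetWindow:
    """Place a window of ``length`` nt at mRNA coordinate ``offset``.

    Plus strand: genomic ``[start+offset, start+offset+length)``.
    Minus strand: genomic ``[end-offset-length, end-offset)``.
    Circular contigs wrap modulo the genome length; on linear contigs a
    window crossing a boundary is an error, never clamped.  A positive
    offset whose window runs past the CDS 3' end is also an error: the
    probe would leave the transcript it is meant to silence.
    """
    glen = len(genome)
    if length > glen:
        raise UndesignableWindowError(
            feature.locus_tag,
            "window_exceeds_genome",
            f"window length {length} > contig length {glen}",
        )
    if offset > 0 and offset + length > feature.length:
        raise UndesignableWindowError(
            feature.locus_tag,
            "past_cds_end",
            f"offset {offset} + length {length} exceeds CDS length "
            f"{feature.length}",
        )
    if feature.strand == +1:
        gs = feature.start + offset
    else:
        gs = feature.end - offset - length
    ge = gs + length
    if genome.topology == "linear":
        if gs < 0:
            raise UndesignableWindowError(
                feature.locus_tag,
                "past_contig_start",
                f"window start {gs} < 0 on linear contig",
            )
        if ge > glen:
            raise UndesignableWindowError(
                feature.locus_tag,
                "past_contig_end",
                f"window end {ge} > contig length {glen} on linear contig",
            )
    else:
        gs %= glen
        ge = gs + length
    return TargetWindow(
        contig_id=feature.contig_id or genome.id,
        genomic_start=gs,
        genomic_end=ge,
        strand=feature.strand,
        offset=offset,
    )


def extract_target_sense(genome: Genome, window: TargetWindow) -> str:
    """mRNA-sense sequence of a window, 5'->3' on the gene's coding strand."""
    glen = len(genome)
    if window.genomic_end <= glen:
        sub = genome.sequence[window.genomic_start : window.genomic_end]
    else:
        if genome.topology != "circular":
            raise ValueError(
                f"window [{window.genomic_start}, {window.genomic_end}) "
                f"exceeds linear contig of length {glen}"
            )
        sub = (
            genome.sequence[window.genomic_start :]
            + genome.sequence[: window.genomic_end - glen]
        )
    return sub if window.strand == +1 else reverse_complement(sub)


def design_asrna(
    genome: Genome,
    feature: GeneFeature,
    params: DesignParams,
    offset: Optional[int] = None,
    round: int = 1,
) -> AsRNADesign:
    """Design one asRNA: window placement, extraction, reverse complement."""
    if round not in (1, 2):
        raise ValueError(f"round must be 1 or 2, got {round}")
    if offset is None:
        offset = params.offset
    window = compute_window(feature, offset, params.asrna_length, genome)
    sense = extract_target_sense(genome, window)
    return AsRNADesign(
        locus_tag=feature.locus_tag,
        round=round,
        window=window,
        target_sense_seq=sense,
        asrna_seq=reverse_complement(sense),
    )
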