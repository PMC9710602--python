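"""Deterministic synthetic annotated genomes for testing and demos.

The generator lays out ``n_genes`` random ATG-prefixed coding sequences
separated by random intergenic spacers, on either strand, optionally
followed by planted duplicate loci that copy part of an earlier gene
byte-identically — the construction that forces off-target hits and
exercises the redesign round.  Two duplicate spans are supported:

``sd_start_region``
    copies the mRNA region from 20 nt upstream of the start codon through
    the end of the default round-1 design window (mRNA [−20, +13)), so the
    round-1 probe is duplicated but a probe stepped one window downstream
    escapes;
``whole_gene_with_flanks``
    copies the entire gene plus 30 nt of flank on each side, so no window
    near the start codon can escape.

Clean genomes (no duplicate pairs) are rejection-sampled until no 15-mer
occurs twice anywhere (counting both strands), which makes "no off-target"
expectations deterministic rather than merely probable.  Genomes with
planted duplicates are resampled until the planted copies are the *only*
repeats.  A fixed seed yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .design import (
    DesignParams,
    UndesignableWindowError,
    compute_window,
    extract_target_sense,
    reverse_complement,
)
from .genome_io import GeneFeature, Genome, write_genbank
from .offtarget import ScreenParams, brute_force_scan, classify_hit

#: mRNA-coordinate half-open spans copied for each duplicate kind
SD_START_SPAN = (-20, 13)
WHOLE_GENE_FLANK = 30

#: repeats of this length or more are scrubbed from clean fixtures
REPEAT_GUARD_K = 15

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticGenomeSpec:
    n_genes: int = 6
    gene_length: int = 120
    intergenic_length: int = 60
    fraction_minus_strand: float = 0.33
    duplicate_pairs: list[tuple[int, str]] = field(default_factory=list)
    topology: str = "linear"
    gc_content: float = 0.5
    seed: int = 0
    contig_id: str = "SYNCONTIG1"
    locus_prefix: str = "SYN"
    #: rejection-sample until default-parameter screens are provably clean
    #: apart from planted duplicates.  Feasible for the small genomes the
    #: screening tests use; disable for large design-only fixtures, where
    #: chance near-matches are statistically unavoidable.
    screen_guard: bool = True

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.gene_length < 63:
            raise ValueError(
                "gene_length must be >= 63 nt so a stepped round-2 window fits"
            )
        if self.intergenic_length < 30:
            raise ValueError("intergenic_length must be >= 30 nt")
        if not (0.0 <= self.fraction_minus_strand <= 1.0):
            raise ValueError("fraction_minus_strand must lie in [0, 1]")
        if self.topology not in ("linear", "circular"):
            raise ValueError("topology must be linear|circular")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must lie in (0, 1)")
        for src, span in self.duplicate_pairs:
            if not (0 <= src < self.n_genes):
                raise ValueError(f"duplicate source index {src} out of range")
            if span not in ("sd_start_region", "whole_gene_with_flanks"):
                raise ValueError(f"unknown duplicate span {span!r}")
        if self.duplicate_pairs and self.intergenic_length < WHOLE_GENE_FLANK * 2:
            raise ValueError(
                "intergenic_length must be >= 60 nt when planting duplicates "
                "so copied flanks stay inside the spacers"
            )


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _mrna_to_genomic(feat: GeneFeature, c: int, glen: int, circular: bool) -> int:
    g = feat.start + c if feat.strand == +1 else feat.end - 1 - c
    return g % glen if circular else g


def _span_interval(feat: GeneFeature, a: int, b: int) -> tuple[int, int]:
    """Genomic half-open interval of mRNA span [a, b) for a feature."""
    if feat.strand == +1:
        return feat.start + a, feat.start + b
    return feat.end - b, feat.end - a


def _repeated_kmer_positions(seq: str, k: int) -> dict[str, list[tuple[int, int]]]:
    """Canonical k-mers occurring more than once, with (pos, strand)."""
    occ: dict[str, list[tuple[int, int]]] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        rc = reverse_complement(w)
        canon = min(w, rc)
        occ.setdefault(canon, []).append((i, +1 if w <= rc else -1))
    return {w: ps for w, ps in occ.items() if len(ps) > 1}


def _attempt(spec: SyntheticGenomeSpec, rng: np.random.Generator) -> Genome:
    total = spec.n_genes + len(spec.duplicate_pairs)
    strands = np.where(rng.random(total) < spec.fraction_minus_strand, -1, +1)
    glen = spec.intergenic_length * (total + 1) + spec.gene_length * total
    seq = _random_bases(rng, glen, spec.gc_content)

    features: list[GeneFeature] = []
    pos = spec.intergenic_length
    for i in range(total):
        mrna = np.concatenate(
            [
                np.frombuffer(b"ATG", dtype=np.uint8),
                _random_bases(rng, spec.gene_length - 3, spec.gc_content),
            ]
        )
        if strands[i] == +1:
            seq[pos : pos + spec.gene_length] = mrna
        else:
            rc = np.frombuffer(
                reverse_complement(mrna.tobytes().decode()).encode(), dtype=np.uint8
            )
            seq[pos : pos + spec.gene_length] = rc
        features.append(
            GeneFeature(
                locus_tag=f"{spec.locus_prefix}_{i + 1:04d}",
                start=pos,
                end=pos + spec.gene_length,
                strand=int(strands[i]),
                gene_name=f"{spec.locus_prefix.lower()}{i + 1}",
                product="synthetic protein",
                contig_id=spec.contig_id,
            )
        )
        pos += spec.gene_length + spec.intergenic_length

    circular = spec.topology == "circular"
    comp = dict(zip(b"ACGTN", b"TGCAN"))
    for j, (src_idx, span) in enumerate(spec.duplicate_pairs):
        src = features[src_idx]
        dup = features[spec.n_genes + j]
        if span == "sd_start_region":
            a, b = SD_START_SPAN
        else:
            a, b = -WHOLE_GENE_FLANK, spec.gene_length + WHOLE_GENE_FLANK
        for c in range(a, b):
            gs = _mrna_to_genomic(src, c, glen, circular)
            gd = _mrna_to_genomic(dup, c, glen, circular)
            base = seq[gs] if src.strand == +1 else comp[seq[gs]]
            seq[gd] = base if dup.strand == +1 else comp[base]

    return Genome(
        id=spec.contig_id,
        sequence=seq.tobytes().decode("ascii"),
        topology=spec.topology,
        features=features,
    )


def _planted_intervals(spec: SyntheticGenomeSpec, genome: Genome) -> list[tuple[int, int]]:
    out = []
    for j, (src_idx, span) in enumerate(spec.duplicate_pairs):
        if span == "sd_start_region":
            a, b = SD_START_SPAN
        else:
            a, b = -WHOLE_GENE_FLANK, spec.gene_length + WHOLE_GENE_FLANK
        for feat in (genome.features[src_idx], genome.features[spec.n_genes + j]):
            out.append(_span_interval(feat, a, b))
    return out


def _only_planted_repeats(spec: SyntheticGenomeSpec, genome: Genome) -> bool:
    text = genome.sequence
    if genome.topology == "circular":
        text = text + text[: REPEAT_GUARD_K - 1]
    repeats = _repeated_kmer_positions(text, REPEAT_GUARD_K)
    if not spec.duplicate_pairs:
        return not repeats
    allowed = _planted_intervals(spec, genome)
    for positions in repeats.values():
        for p, _strand in positions:
            if not any(lo <= p and p + REPEAT_GUARD_K <= hi for lo, hi in allowed):
                return False
    return True


def _screens_clean(spec: SyntheticGenomeSpec, genome: Genome) -> bool:
    """True iff, at the default design and screen parameters, every gene's
    round-1 and round-2 windows hit nothing beyond the intended site and
    the planted duplicate spans.

    The exact-repeat guard alone is not enough: a screen at 80% identity
    can be tripped by chance near-matches that share no long exact word,
    so those are rejection-sampled away too.
    """
    dparams = DesignParams()
    sparams = ScreenParams()
    allowed = _planted_intervals(spec, genome)
    glen = len(genome) if genome.topology == "circular" else None
    for feat in genome.cds_features:
        for off in (dparams.offset, dparams.offset + dparams.redesign_step):
            try:
                window = compute_window(feat, off, dparams.asrna_length, genome)
            except UndesignableWindowError:
                continue
            footprint = extract_target_sense(genome, window)
            for hit in brute_force_scan(footprint, genome, sparams):
                if classify_hit(hit, window, genome_length=glen):
                    continue
                if any(
                    min(hit.subject_end, hi) - max(hit.subject_start, lo) >= 1
                    for lo, hi in allowed
                ):
                    continue
                return False
    return True


def make_genome(
    spec: SyntheticGenomeSpec, path: Optional[Union[str, Path]] = None
) -> Genome:
    """Generate a synthetic annotated genome; optionally write GenBank.

    Deterministic in ``spec.seed``: the same spec always produces a
    byte-identical genome (and file).
    """
    for attempt in range(500):
        rng = np.random.default_rng((spec.seed, attempt))
        genome = _attempt(spec, rng)
        if _only_planted_repeats(spec, genome) and (
            not spec.screen_guard or _screens_clean(spec, genome)
        ):
            break
    else:
        raise RuntimeError(
            "could not sample a genome whose only long repeats are the "
            "planted duplicates; reduce genome size or change the seed"
        )
    if path is not None:
        write_genbank(genome, path)
    return genome
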