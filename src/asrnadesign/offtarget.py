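"""Genome-wide off-target screening of asRNA binding footprints.

The question asked here: at which genomic loci, on either strand, does the
sequence an asRNA was designed to bind recur well enough that the asRNA
could pair there too?  A locus counts when an ungapped alignment of the
binding footprint reaches the identity and length thresholds; the intended
design site itself is found and flagged separately, and everything else is
an off-target.

Three backends share one definition of a hit:

* ``find_matches`` — the default seed-and-extend matcher.  Exact seed words
  shared between the footprint and the genome nominate alignment diagonals;
  each diagonal is scored ungapped (match +1 / mismatch −2) and trimmed to
  its maximal-scoring segment.  The seed length is capped at the lossless
  filtration bound implied by the thresholds (see ``lossless_seed_length``),
  so no qualifying alignment can be missed: the heuristic is exact.
* ``brute_force_scan`` — evaluates every diagonal on both strands with the
  same scoring.  O(genome × footprint); the test oracle.
* ``run_external_blast`` — optional adapter around NCBI ``blastn`` for
  users who want e-value-based screening with a local BLAST install.

Hits are deduplicated by (subject interval, strand), keeping the
highest-identity alignment, and reported in genomic order.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .design import AsRNADesign, TargetWindow, reverse_complement
from .genome_io import Genome

_ACGT = frozenset(b"ACGT")

MATCH_SCORE = 1
MISMATCH_SCORE = -2


class BlastUnavailableError(RuntimeError):
    """The external BLAST toolchain is not on PATH."""


@dataclass
class ScreenParams:
    """Thresholds for the off-target screen.

    min_identity
        Percent identity an alignment must reach to be reported (default 80).
    min_match_length
        Minimum aligned length in nt (default 15).
    seed_word_size
        Requested exact-seed length for the builtin matcher (default 11).
        Internally capped at the lossless bound so the screen stays exact.
    evalue_threshold
        E-value cutoff for the external BLAST backend only (default 1000,
        the permissive value appropriate for short queries).
    backend
        ``builtin`` or ``external_blast``.
    """

    min_identity: float = 80.0
    min_match_length: int = 15
    seed_word_size: int = 11
    evalue_threshold: float = 1000.0
    backend: str = "builtin"

    def __post_init__(self) -> None:
        if not (50.0 <= self.min_identity <= 100.0):
            raise ValueError("min_identity must lie in [50, 100]")
        if self.seed_word_size < 1:
            raise ValueError("seed_word_size must be positive")
        if self.seed_word_size > self.min_match_length:
            raise ValueError("seed_word_size must be <= min_match_length")
        if self.backend not in ("builtin", "external_blast"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class OfftargetHit:
    locus_tag: str
    round: int
    subject_contig: str
    subject_start: int  # 0-based inclusive; < contig length
    subject_end: int    # exclusive; may exceed contig length on circular wrap
    subject_strand: int
    aligned_length: int
    identity: float     # percent
    score: int          # matches - 2*mismatches
    evalue: Optional[float] = None
    is_intended: bool = False


def lossless_seed_length(
    min_match_length: int, min_identity: float, query_length: int
) -> int:
    """Longest exact seed guaranteed to occur in every qualifying alignment.

    An ungapped alignment of length ``l`` with at most ``e`` mismatches
    contains an exact run of at least ``ceil((l-e)/(e+1))`` nt (pigeonhole).
    Minimizing over the admissible lengths ``min_match_length <= l <=
    query_length`` with ``e = floor(l * (1 - min_identity/100))`` gives the
    longest seed that can never miss a reportable hit.
    """
    best = query_length
    for l in range(min_match_length, query_length + 1):
        e = math.floor(l * (100.0 - min_identity) / 100.0 + 1e-9)
        run = math.ceil((l - e) / (e + 1))
        best = min(best, run)
    return max(1, best)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _best_segments(
    padded: np.ndarray,
    placements: np.ndarray,
    pad_offset: int,
    query: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximal-scoring ungapped segment for each placement (diagonal).

    For every placement ``p`` the query is laid against the padded genome
    starting at ``p + pad_offset`` and the best-scoring contiguous segment
    is found (Kadane over +1/−2 columns), preferring higher score, then
    longer, then leftmost.  Returns (score, length, start-within-query)
    arrays; non-genome padding bytes never match, so segments never leave
    the genome (a maximal segment cannot begin or end on a mismatch).
    """
    L = query.size
    n = placements.size
    idx = placements[:, None] + pad_offset + np.arange(L)[None, :]
    sub = padded[idx]
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    q_ok = np.isin(query, acgt)  # N in the query matches nothing
    s_ok = np.isin(sub, acgt)    # N or padding in the genome matches nothing
    match = (sub == query[None, :]) & q_ok[None, :] & s_ok

    cur = np.zeros(n, dtype=np.int64)
    cur_start = np.zeros(n, dtype=np.int64)
    best = np.full(n, np.iinfo(np.int64).min, dtype=np.int64)
    best_len = np.zeros(n, dtype=np.int64)
    best_start = np.zeros(n, dtype=np.int64)
    for j in range(L):
        delta = np.where(match[:, j], MATCH_SCORE, MISMATCH_SCORE)
        restart = cur < 0
        cur = np.where(restart, 0, cur) + delta
        cur_start = np.where(restart, j, cur_start)
        length = j - cur_start + 1
        better = (cur > best) | ((cur == best) & (length > best_len))
        best = np.where(better, cur, best)
        best_len = np.where(better, length, best_len)
        best_start = np.where(better, cur_start, best_start)
    return best, best_len, best_start


def _scan_placements(
    footprint: str,
    genome: Genome,
    params: ScreenParams,
    candidate_placements: Optional[dict[int, np.ndarray]] = None,
) -> list[OfftargetHit]:
    """Score placements of the footprint (both orientations) on one contig.

    ``candidate_placements`` maps strand (+1/−1) to diagonal offsets to
    evaluate; ``None`` means every diagonal (brute force).  A placement
    ``p`` is the genomic coordinate the query's first base aligns to; on
    linear contigs partial overlaps hanging off either end are included.
    """
    L = len(footprint)
    glen = len(genome)
    garr = _encode(genome.sequence)
    if genome.topology == "circular":
        padded = np.concatenate([garr, garr[: max(L - 1, 0)]])
        pad_offset = 0
        all_placements = np.arange(glen)
    else:
        pad = np.zeros(L - 1, dtype=np.uint8)
        padded = np.concatenate([pad, garr, pad])
        pad_offset = L - 1
        all_placements = np.arange(-(L - 1), glen)

    raw: list[OfftargetHit] = []
    for strand, qseq in ((+1, footprint), (-1, reverse_complement(footprint))):
        # strand −1 means the site reads as the footprint on the minus
        # strand, i.e. the plus-strand text at the locus equals the reverse
        # complement of the footprint — so that is the string searched.
        query = _encode(qseq)
        if candidate_placements is None:
            placements = all_placements
        else:
            placements = candidate_placements.get(strand, np.empty(0, dtype=np.int64))
            if placements.size == 0:
                continue
        score, seg_len, seg_start = _best_segments(
            padded, placements.astype(np.int64), pad_offset, query
        )
        matches = (score + 2 * seg_len) // 3
        keep = (
            (seg_len >= params.min_match_length)
            & (score > 0)
            & (matches * 100.0 >= params.min_identity * seg_len - 1e-9)
        )
        for p, sc, ln, st in zip(
            placements[keep], score[keep], seg_len[keep], seg_start[keep]
        ):
            subj_start = int(p + st)
            subj_end = subj_start + int(ln)
            if genome.topology == "circular":
                subj_start %= glen
                subj_end = subj_start + int(ln)
            m = int((sc + 2 * ln) // 3)
            raw.append(
                OfftargetHit(
                    locus_tag="",
                    round=0,
                    subject_contig=genome.id,
                    subject_start=subj_start,
                    subject_end=subj_end,
                    subject_strand=strand,
                    aligned_length=int(ln),
                    identity=100.0 * m / int(ln),
                    score=int(sc),
                )
            )
    return _dedup(raw)


def _dedup(hits: list[OfftargetHit]) -> list[OfftargetHit]:
    best: dict[tuple, OfftargetHit] = {}
    for h in hits:
        key = (h.subject_contig, h.subject_start, h.subject_end, h.subject_strand)
        prev = best.get(key)
        if prev is None or (h.identity, h.score) > (prev.identity, prev.score):
            best[key] = h
    return sorted(
        best.values(),
        key=lambda h: (
            h.subject_contig,
            h.subject_start,
            h.subject_end,
            h.subject_strand,
        ),
    )


def _seed_placements(
    footprint: str, genome: Genome, k: int
) -> dict[int, np.ndarray]:
    """Diagonals nominated by exact shared k-mers, per strand."""
    glen = len(genome)
    L = len(footprint)
    if genome.topology == "circular":
        text = genome.sequence + genome.sequence[: max(k - 1, 0)]
        limit = glen
    else:
        text = genome.sequence
        limit = glen - k + 1
    index: dict[str, list[int]] = {}
    for g in range(max(limit, 0)):
        w = text[g : g + k]
        if "N" in w:
            continue
        index.setdefault(w, []).append(g)

    out: dict[int, np.ndarray] = {}
    for strand, qseq in ((+1, footprint), (-1, reverse_complement(footprint))):
        diags: set[int] = set()
        for j in range(L - k + 1):
            w = qseq[j : j + k]
            if "N" in w:
                continue
            for g in index.get(w, ()):
                diags.add(g - j)
        if genome.topology == "circular":
            diags = {d % glen for d in diags}
        else:
            diags = {d for d in diags if -(L - 1) <= d < glen}
        out[strand] = np.array(sorted(diags), dtype=np.int64)
    return out


def classify_hit(
    hit: OfftargetHit, intended: TargetWindow, genome_length: Optional[int] = None
) -> bool:
    """True iff the hit overlaps the intended binding window (>= 1 bp) on
    the intended strand — i.e. it is the design site, not an off-target."""
    if hit.subject_contig != intended.contig_id:
        return False
    if hit.subject_strand != intended.strand:
        return False
    shifts = (0,) if genome_length is None else (-genome_length, 0, genome_length)
    for shift in shifts:
        lo = max(hit.subject_start + shift, intended.genomic_start)
        hi = min(hit.subject_end + shift, intended.genomic_end)
        if hi - lo >= 1:
            return True
    return False


def brute_force_scan(
    footprint: str, genome: Genome, params: ScreenParams
) -> list[OfftargetHit]:
    """Exhaustive oracle: every diagonal, both strands, same hit definition
    as the seeded matcher.  O(genome x footprint); intended for testing."""
    return _scan_placements(footprint, genome, params, candidate_placements=None)


def find_matches(
    design: AsRNADesign, genome: Genome, params: ScreenParams
) -> list[OfftargetHit]:
    """Screen one design against one contig with the builtin matcher."""
    k = min(
        params.seed_word_size,
        lossless_seed_length(
            params.min_match_length, params.min_identity, len(design.target_sense_seq)
        ),
    )
    candidates = _seed_placements(design.target_sense_seq, genome, k)
    hits = _scan_placements(
        design.target_sense_seq, genome, params, candidate_placements=candidates
    )
    glen = len(genome) if genome.topology == "circular" else None
    return [
        replace(
            h,
            locus_tag=design.locus_tag,
            round=design.round,
            is_intended=classify_hit(h, design.window, genome_length=glen),
        )
        for h in hits
    ]


# ---------------------------------------------------------------------------
# external BLAST backend


def write_fasta(entries: Iterable[tuple[str, str]], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def parse_blast_tabular(text: str) -> list[dict]:
    """Parse 12-column tabular (outfmt 6) BLAST output."""
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 12:
            raise ValueError(
                f"malformed BLAST tabular line {lineno}: expected 12 fields, "
                f"got {len(fields)}: {line!r}"
            )
        try:
            rows.append(
                {
                    "qseqid": fields[0],
                    "sseqid": fields[1],
                    "pident": float(fields[2]),
                    "length": int(fields[3]),
                    "mismatch": int(fields[4]),
                    "gapopen": int(fields[5]),
                    "qstart": int(fields[6]),
                    "qend": int(fields[7]),
                    "sstart": int(fields[8]),
                    "send": int(fields[9]),
                    "evalue": float(fields[10]),
                    "bitscore": float(fields[11]),
                }
            )
        except ValueError as exc:
            raise ValueError(
                f"malformed BLAST tabular line {lineno}: {line!r} ({exc})"
            ) from exc
    return rows


def run_external_blast(
    designs: Sequence[AsRNADesign],
    genomes: Union[Genome, Sequence[Genome]],
    params: ScreenParams,
) -> list[OfftargetHit]:
    """Screen designs with a local NCBI BLAST+ install (``blastn-short``).

    The target-sense footprint of each design is queried against a
    nucleotide database of the genome, so subject-strand semantics match
    the builtin matcher.  Contigs are treated as linear (BLAST databases
    cannot wrap a circular origin).
    """
    if isinstance(genomes, Genome):
        genomes = [genomes]
    for tool in ("makeblastdb", "blastn"):
        if shutil.which(tool) is None:
            raise BlastUnavailableError(
                f"{tool} not found on PATH; install NCBI BLAST+ or use the "
                "builtin matcher (--backend builtin)"
            )
    by_query = {f"{d.locus_tag}|r{d.round}": d for d in designs}
    genome_by_id = {g.id: g for g in genomes}
    with tempfile.TemporaryDirectory(prefix="asrna_blast_") as tmp:
        tmpdir = Path(tmp)
        db_fa = tmpdir / "genome.fa"
        q_fa = tmpdir / "queries.fa"
        write_fasta([(g.id, g.sequence) for g in genomes], db_fa)
        write_fasta(
            [(qid, d.target_sense_seq) for qid, d in by_query.items()], q_fa
        )
        db = tmpdir / "genome_db"
        _run([
            "makeblastdb", "-in", str(db_fa), "-dbtype", "nucl", "-out", str(db),
        ])
        out = _run([
            "blastn",
            "-task", "blastn-short",
            "-query", str(q_fa),
            "-db", str(db),
            "-outfmt", "6",
            "-evalue", str(params.evalue_threshold),
            "-perc_identity", str(params.min_identity),
            "-word_size", str(max(4, params.seed_word_size)),
            "-dust", "no",
            "-soft_masking", "false",
            "-strand", "both",
        ])
    hits: list[OfftargetHit] = []
    for row in parse_blast_tabular(out):
        design = by_query.get(row["qseqid"])
        if design is None:
            raise ValueError(f"BLAST output names unknown query {row['qseqid']!r}")
        if row["length"] < params.min_match_length:
            continue
        if row["sstart"] <= row["send"]:
            strand, s0, s1 = +1, row["sstart"] - 1, row["send"]
        else:
            strand, s0, s1 = -1, row["send"] - 1, row["sstart"]
        matches = round(row["length"] * row["pident"] / 100.0)
        mism = row["length"] - matches
        genome = genome_by_id.get(row["sseqid"])
        hit = OfftargetHit(
            locus_tag=design.locus_tag,
            round=design.round,
            subject_contig=row["sseqid"],
            subject_start=s0,
            subject_end=s1,
            subject_strand=strand,
            aligned_length=row["length"],
            identity=row["pident"],
            score=matches + MISMATCH_SCORE * mism,
            evalue=row["evalue"],
        )
        hit.is_intended = classify_hit(
            hit,
            design.window,
            genome_length=(
                len(genome)
                if genome is not None and genome.topology == "circular"
                else None
            ),
        )
        hits.append(hit)
    return _dedup_per_query(hits)


def _dedup_per_query(hits: list[OfftargetHit]) -> list[OfftargetHit]:
    best: dict[tuple, OfftargetHit] = {}
    for h in hits:
        key = (
            h.locus_tag,
            h.round,
            h.subject_contig,
            h.subject_start,
            h.subject_end,
            h.subject_strand,
        )
        prev = best.get(key)
        if prev is None or (h.identity, h.score) > (prev.identity, prev.score):
            best[key] = h
    return sorted(
        best.values(),
        key=lambda h: (
            h.locus_tag,
            h.round,
            h.subject_contig,
            h.subject_start,
            h.subject_end,
            h.subject_strand,
        ),
    )


def _run(cmd: list[str]) -> str:
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(
            f"{cmd[0]} failed (exit {proc.returncode}): {proc.stderr.strip()}"
        )
    return proc.stdout
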