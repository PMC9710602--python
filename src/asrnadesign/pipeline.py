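"""The two-round design workflow and its report serialization.

Round 1 designs an asRNA for every selected gene at the configured offset
and screens it genome-wide.  Any gene whose screen returns at least one
off-target is redesigned exactly once, ``redesign_step`` nt further
downstream, and screened again.  There is never a third round: for recent
high-identity gene duplicates the redesign loop would not terminate and
would walk the probe out of the gene, so a gene still dirty after round 2
ships flagged, carrying its round-2 design and all hit evidence for the
user to judge.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .design import (
    AsRNADesign,
    DesignParams,
    UndesignableWindowError,
    design_asrna,
    reverse_complement,
)
from .genome_io import GeneFeature, Genome, TargetList, select_targets
from .offtarget import OfftargetHit, ScreenParams, find_matches, run_external_blast

DESIGN_COLUMNS = [
    "locus_tag",
    "gene_name",
    "product",
    "strand",
    "round",
    "offset",
    "window_start_1based",
    "window_end_1based",
    "target_sense_seq",
    "asrna_seq",
    "status",
    "offtarget_count",
    "undesignable_reason",
]

HIT_COLUMNS = [
    "locus_tag",
    "round",
    "subject_contig",
    "subject_start_1based",
    "subject_end_1based",
    "subject_strand",
    "aligned_length",
    "identity",
    "score",
    "evalue",
    "is_intended",
]


@dataclass
class GeneOutcome:
    locus_tag: str
    status: str  # clean_round1 | clean_round2 | flagged | undesignable
    feature: Optional[GeneFeature] = None
    final_design: Optional[AsRNADesign] = None
    undesignable_reason: Optional[str] = None
    round1_offtarget_count: int = 0
    round2_offtarget_count: Optional[int] = None


@dataclass
class DesignReport:
    design_params: DesignParams
    screen_params: ScreenParams
    outcomes: list[GeneOutcome]
    hits: list[OfftargetHit] = field(default_factory=list)
    input_file: Optional[str] = None
    genome_ids: list[str] = field(default_factory=list)
    tool_version: str = __version__
    timestamp: Optional[str] = None


def next_offset(params: DesignParams, round1_offset: int) -> int:
    """Offset for the round-2 redesign: one step downstream of round 1.

    The default step equals the asRNA length, so the two windows are
    disjoint while the probe stays near the translation-initiation region.
    """
    return round1_offset + params.redesign_step


def _as_genome_list(genomes: Union[Genome, Sequence[Genome]]) -> list[Genome]:
    return [genomes] if isinstance(genomes, Genome) else list(genomes)


def _screen_batch(
    designs: Sequence[AsRNADesign],
    genomes: Sequence[Genome],
    sparams: ScreenParams,
) -> dict[str, list[OfftargetHit]]:
    """Screen a batch of designs against every contig; hits keyed by gene."""
    out: dict[str, list[OfftargetHit]] = {d.locus_tag: [] for d in designs}
    if not designs:
        return out
    if sparams.backend == "external_blast":
        for hit in run_external_blast(designs, genomes, sparams):
            out[hit.locus_tag].append(hit)
    else:
        for d in designs:
            for g in genomes:
                out[d.locus_tag].extend(find_matches(d, g, sparams))
    return out


def design_library(
    genomes: Union[Genome, Sequence[Genome]],
    targets: Optional[TargetList] = None,
    dparams: Optional[DesignParams] = None,
    sparams: Optional[ScreenParams] = None,
    input_file: Optional[str] = None,
) -> DesignReport:
    """Run the full workflow over the selected genes of a genome.

    Per-gene failures (undesignable windows) become outcomes rather than
    aborting the batch; an empty target selection is an error.
    """
    genomes = _as_genome_list(genomes)
    dparams = dparams or DesignParams()
    sparams = sparams or ScreenParams()
    if sparams.seed_word_size > dparams.asrna_length:
        raise ValueError("seed_word_size cannot exceed asrna_length")
    if sparams.min_match_length > dparams.asrna_length:
        raise ValueError("min_match_length cannot exceed asrna_length")
    all_tags = [f.locus_tag for g in genomes for f in g.cds_features]
    if len(all_tags) != len(set(all_tags)):
        raise ValueError("locus_tags must be unique across all contigs")
    features = select_targets(genomes, targets)
    if not features:
        raise ValueError("no design targets: the genome has no CDS features")
    genome_by_id = {g.id: g for g in genomes}

    outcomes: dict[str, GeneOutcome] = {}
    all_hits: list[OfftargetHit] = []

    round1: list[tuple[GeneFeature, AsRNADesign]] = []
    for feat in features:
        g = genome_by_id[feat.contig_id]
        try:
            d1 = design_asrna(g, feat, dparams, offset=dparams.offset, round=1)
        except UndesignableWindowError as exc:
            outcomes[feat.locus_tag] = GeneOutcome(
                locus_tag=feat.locus_tag,
                status="undesignable",
                feature=feat,
                undesignable_reason=exc.reason,
            )
            continue
        round1.append((feat, d1))

    hits1 = _screen_batch([d for _, d in round1], genomes, sparams)
    flagged: list[tuple[GeneFeature, AsRNADesign, int]] = []
    for feat, d1 in round1:
        gene_hits = hits1[feat.locus_tag]
        all_hits.extend(gene_hits)
        n_off = sum(1 for h in gene_hits if not h.is_intended)
        if n_off == 0:
            outcomes[feat.locus_tag] = GeneOutcome(
                locus_tag=feat.locus_tag,
                status="clean_round1",
                feature=feat,
                final_design=d1,
                round1_offtarget_count=0,
            )
        else:
            flagged.append((feat, d1, n_off))

    offset2 = next_offset(dparams, dparams.offset)
    round2: list[tuple[GeneFeature, AsRNADesign, int]] = []
    for feat, d1, n_off1 in flagged:
        g = genome_by_id[feat.contig_id]
        try:
            d2 = design_asrna(g, feat, dparams, offset=offset2, round=2)
        except UndesignableWindowError as exc:
            # round-2 window unplaceable: keep the round-1 design, flagged
            outcomes[feat.locus_tag] = GeneOutcome(
                locus_tag=feat.locus_tag,
                status="flagged",
                feature=feat,
                final_design=d1,
                undesignable_reason=f"round2:{exc.reason}",
                round1_offtarget_count=n_off1,
                round2_offtarget_count=None,
            )
            continue
        round2.append((feat, d2, n_off1))

    hits2 = _screen_batch([d for _, d, _ in round2], genomes, sparams)
    for feat, d2, n_off1 in round2:
        gene_hits = hits2[feat.locus_tag]
        all_hits.extend(gene_hits)
        n_off2 = sum(1 for h in gene_hits if not h.is_intended)
        outcomes[feat.locus_tag] = GeneOutcome(
            locus_tag=feat.locus_tag,
            status="clean_round2" if n_off2 == 0 else "flagged",
            feature=feat,
            final_design=d2,
            round1_offtarget_count=n_off1,
            round2_offtarget_count=n_off2,
        )

    ordered = [outcomes[f.locus_tag] for f in features]
    return DesignReport(
        design_params=dparams,
        screen_params=sparams,
        outcomes=ordered,
        hits=all_hits,
        input_file=input_file,
        genome_ids=[g.id for g in genomes],
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )


def designs_table(report: DesignReport) -> pd.DataFrame:
    rows = []
    for o in report.outcomes:
        d = o.final_design
        final_off = (
            o.round2_offtarget_count
            if o.round2_offtarget_count is not None
            else o.round1_offtarget_count
        )
        rows.append(
            {
                "locus_tag": o.locus_tag,
                "gene_name": (o.feature.gene_name if o.feature else None) or "",
                "product": (o.feature.product if o.feature else None) or "",
                "strand": (
                    ("+" if o.feature.strand == +1 else "-") if o.feature else ""
                ),
                "round": d.round if d else "",
                "offset": d.window.offset if d else "",
                "window_start_1based": d.window.genomic_start + 1 if d else "",
                "window_end_1based": d.window.genomic_end if d else "",
                "target_sense_seq": d.target_sense_seq if d else "",
                "asrna_seq": d.asrna_seq if d else "",
                "status": o.status,
                "offtarget_count": final_off if d else "",
                "undesignable_reason": o.undesignable_reason or "",
            }
        )
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def hits_table(report: DesignReport) -> pd.DataFrame:
    rows = []
    for h in report.hits:
        rows.append(
            {
                "locus_tag": h.locus_tag,
                "round": h.round,
                "subject_contig": h.subject_contig,
                "subject_start_1based": h.subject_start + 1,
                "subject_end_1based": h.subject_end,
                "subject_strand": "+" if h.subject_strand == +1 else "-",
                "aligned_length": h.aligned_length,
                "identity": round(h.identity, 2),
                "score": h.score,
                "evalue": "" if h.evalue is None else h.evalue,
                "is_intended": h.is_intended,
            }
        )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def _provenance(report: DesignReport, include_timestamp: bool) -> dict:
    info = {
        "tool_version": report.tool_version,
        "input_file": report.input_file,
        "genome_ids": report.genome_ids,
        "design_params": {
            "asrna_length": report.design_params.asrna_length,
            "offset": report.design_params.offset,
            "redesign_step": report.design_params.redesign_step,
            "max_rounds": report.design_params.max_rounds,
        },
        "screen_params": {
            "min_identity": report.screen_params.min_identity,
            "min_match_length": report.screen_params.min_match_length,
            "seed_word_size": report.screen_params.seed_word_size,
            "evalue_threshold": report.screen_params.evalue_threshold,
            "backend": report.screen_params.backend,
        },
    }
    if include_timestamp:
        info["timestamp"] = report.timestamp
    return info


def write_report(
    report: DesignReport,
    prefix: Union[str, Path],
    format: str = "csv",
    include_timestamp: bool = True,
) -> list[Path]:
    """Serialize the report.

    ``csv`` writes ``<prefix>_designs.csv`` and ``<prefix>_hits.csv``
    (RFC-4180, UTF-8) plus a ``<prefix>_run_info.json`` sidecar holding the
    parameters and provenance; ``xlsx`` writes one workbook with ``designs``
    and ``hits`` sheets.  With ``include_timestamp=False`` output for a
    fixed input is byte-identical across runs.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    designs = designs_table(report)
    hits = hits_table(report)
    written: list[Path] = []
    if format == "csv":
        dpath = prefix.with_name(prefix.name + "_designs.csv")
        hpath = prefix.with_name(prefix.name + "_hits.csv")
        designs.to_csv(dpath, index=False, lineterminator="\n", encoding="utf-8")
        hits.to_csv(hpath, index=False, lineterminator="\n", encoding="utf-8")
        written += [dpath, hpath]
    elif format == "xlsx":
        xpath = prefix.with_name(prefix.name + ".xlsx")
        with pd.ExcelWriter(xpath, engine="openpyxl") as xw:
            designs.to_excel(xw, sheet_name="designs", index=False)
            hits.to_excel(xw, sheet_name="hits", index=False)
        written.append(xpath)
    else:
        raise ValueError(f"unknown output format {format!r}")
    jpath = prefix.with_name(prefix.name + "_run_info.json")
    with open(jpath, "w") as fh:
        json.dump(_provenance(report, include_timestamp), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(jpath)
    return written


def verify_designs_csv(path: Union[str, Path]) -> bool:
    """Cross-check a designs CSV: every asRNA must be the reverse
    complement of its recorded sense window.  Returns True when all rows
    with a design pass."""
    df = pd.read_csv(path, keep_default_na=False)
    for _, row in df.iterrows():
        sense = str(row["target_sense_seq"])
        asrna = str(row["asrna_seq"])
        if not sense:
            continue
        if reverse_complement(sense) != asrna:
            return False
    return True
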