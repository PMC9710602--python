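"""Reading and writing annotated genomes and target-gene lists.

Internally every coordinate is 0-based, half-open ``[start, end)``; the
1-based inclusive convention of GenBank/EMBL flat files exists only at the
I/O boundary.  Only CDS features become design targets; everything else is
parsed and ignored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class GenomeFormatError(ValueError):
    """The input file is not a usable annotated genome."""


class TargetResolutionError(KeyError):
    """One or more requested gene identifiers could not be resolved."""

    def __init__(self, unresolved: Sequence[str]):
        self.unresolved = list(unresolved)
        super().__init__(
            "unresolved target identifier(s): " + ", ".join(self.unresolved)
        )


@dataclass
class GeneFeature:
    """A single annotated feature on a contig.

    ``start``/``end`` are 0-based half-open genomic coordinates.  For a
    plus-strand gene the first base of the start codon sits at ``start``;
    for a minus-strand gene it sits at ``end - 1``.
    """

    locus_tag: str
    start: int
    end: int
    strand: int  # +1 or -1
    gene_name: Optional[str] = None
    product: Optional[str] = None
    kind: str = "CDS"
    contig_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in (+1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid feature span [{self.start}, {self.end}) for "
                f"{self.locus_tag}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """One contig: sequence, topology and its annotated features."""

    id: str
    sequence: str
    topology: str = "linear"  # or "circular"
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear|circular, got {self.topology!r}")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"genome {self.id}: non-DNA characters {sorted(bad)}")
        if len(self.sequence) < 1:
            raise ValueError(f"genome {self.id}: empty sequence")
        seen: set[str] = set()
        for f in self.features:
            if f.locus_tag in seen:
                raise GenomeFormatError(
                    f"duplicate locus_tag {f.locus_tag!r} in genome {self.id}"
                )
            seen.add(f.locus_tag)
            if f.contig_id is None:
                f.contig_id = self.id
            if f.end > len(self.sequence):
                raise ValueError(
                    f"feature {f.locus_tag} [{f.start}, {f.end}) exceeds "
                    f"contig length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cds_features(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "CDS"]


@dataclass
class TargetList:
    """Ordered gene identifiers (locus_tag or gene name) to design for."""

    identifiers: list[str]

    def __post_init__(self) -> None:
        if not self.identifiers:
            raise ValueError("target list must not be empty when supplied")
        deduped: list[str] = []
        seen: set[str] = set()
        for ident in self.identifiers:
            if ident in seen:
                warnings.warn(f"duplicate target identifier {ident!r} dropped")
                continue
            seen.add(ident)
            deduped.append(ident)
        self.identifiers = deduped


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".gb", ".gbk", ".gbff", ".genbank"):
        return "genbank"
    if suffix in (".embl", ".ebl"):
        return "embl"
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line
                break
        else:
            raise GenomeFormatError(f"{path}: empty file")
    if first.startswith("LOCUS"):
        return "genbank"
    if first.startswith("ID "):
        return "embl"
    raise GenomeFormatError(
        f"{path}: cannot auto-detect format (expected a LOCUS or ID line)"
    )


def _first_qualifier(feat: SeqFeature, key: str) -> Optional[str]:
    vals = feat.qualifiers.get(key)
    return vals[0] if vals else None


def _record_to_genome(record: SeqRecord, seen_tags: set[str]) -> Genome:
    topology = record.annotations.get("topology", "linear")
    if topology not in ("linear", "circular"):
        topology = "linear"
    features: list[GeneFeature] = []
    anon = 0
    for feat in record.features:
        if feat.type != "CDS":
            continue
        loc = feat.location
        if loc is None:
            continue
        if len(loc.parts) > 1:
            tag = _first_qualifier(feat, "locus_tag") or "?"
            logger.warning(
                "skipping CDS %s on %s: compound/joined location has no "
                "well-defined start-codon anchor",
                tag,
                record.id,
            )
            continue
        strand = loc.strand
        if strand not in (+1, -1):
            logger.warning("skipping strandless CDS on %s", record.id)
            continue
        tag = _first_qualifier(feat, "locus_tag") or _first_qualifier(feat, "gene")
        if tag is None:
            anon += 1
            tag = f"{record.id}_cds{anon:04d}"
        if tag in seen_tags:
            raise GenomeFormatError(f"duplicate locus_tag {tag!r} in input file")
        seen_tags.add(tag)
        features.append(
            GeneFeature(
                locus_tag=tag,
                start=int(loc.start),
                end=int(loc.end),
                strand=int(strand),
                gene_name=_first_qualifier(feat, "gene"),
                product=_first_qualifier(feat, "product"),
                kind="CDS",
                contig_id=record.id,
            )
        )
    if not features:
        logger.warning("record %s contains no CDS features", record.id)
    return Genome(
        id=record.id,
        sequence=str(record.seq),
        topology=topology,
        features=features,
    )


def read_genomes(path: PathLike, format: str = "auto") -> list[Genome]:
    """Read every record of a GenBank/EMBL file as an independent contig.

    locus_tag uniqueness is enforced across the whole file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _sniff_format(path) if format == "auto" else format
    if fmt not in ("genbank", "embl"):
        raise ValueError(f"unsupported format {fmt!r}")
    try:
        records = list(SeqIO.parse(str(path), fmt))
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise GenomeFormatError(f"{path}: cannot parse as {fmt}: {exc}") from exc
    if not records:
        raise GenomeFormatError(f"{path}: no sequence records found")
    seen: set[str] = set()
    return [_record_to_genome(rec, seen) for rec in records]


def parse_genome(path: PathLike, format: str = "auto") -> Genome:
    """Read a single-contig annotated genome.

    Raises :class:`GenomeFormatError` if the file holds more than one record;
    use :func:`read_genomes` for multi-contig files.
    """
    genomes = read_genomes(path, format=format)
    if len(genomes) != 1:
        raise GenomeFormatError(
            f"{path}: expected one record, found {len(genomes)}; "
            "use read_genomes() for multi-contig files"
        )
    return genomes[0]


def write_genbank(genome: Genome, path: PathLike) -> None:
    """Serialize a Genome back to a GenBank flat file (round-trip safe)."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16],
        description="synthetic contig",
        annotations={"molecule_type": "DNA", "topology": genome.topology},
    )
    for f in genome.features:
        quals = {"locus_tag": [f.locus_tag]}
        if f.gene_name:
            quals["gene"] = [f.gene_name]
        if f.product:
            quals["product"] = [f.product]
        record.features.append(
            SeqFeature(
                SimpleLocation(f.start, f.end, strand=f.strand),
                type=f.kind,
                qualifiers=quals,
            )
        )
    SeqIO.write([record], str(path), "genbank")


def read_target_list(path: PathLike) -> TargetList:
    """Plain-text target list: one identifier per line, ``#`` comments."""
    identifiers: list[str] = []
    with open(path) as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token:
                identifiers.append(token)
    if not identifiers:
        raise ValueError(f"{path}: target list contains no identifiers")
    return TargetList(identifiers)


def select_targets(
    genomes: Union[Genome, Iterable[Genome]],
    targets: Optional[TargetList] = None,
) -> list[GeneFeature]:
    """Resolve the design-target set.

    Without a target list: every CDS feature, in genomic order (contigs in
    file order).  With a list: the matching features in list order; a
    locus_tag match wins over a gene-name match, and a gene name matching
    more than one feature is an error.  Every unresolved identifier is
    reported at once.
    """
    if isinstance(genomes, Genome):
        genomes = [genomes]
    all_cds = [f for g in genomes for f in g.cds_features]
    if targets is None:
        return list(all_cds)
    by_tag = {f.locus_tag: f for f in all_cds}
    by_name: dict[str, list[GeneFeature]] = {}
    for f in all_cds:
        if f.gene_name:
            by_name.setdefault(f.gene_name, []).append(f)
    selected: list[GeneFeature] = []
    unresolved: list[str] = []
    for ident in targets.identifiers:
        if ident in by_tag:
            selected.append(by_tag[ident])
        elif ident in by_name:
            matches = by_name[ident]
            if len(matches) > 1:
                raise TargetResolutionError(
                    [f"{ident} (ambiguous: {len(matches)} features)"]
                )
            selected.append(matches[0])
        else:
            unresolved.append(ident)
    if unresolved:
        raise TargetResolutionError(unresolved)
    return selected
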