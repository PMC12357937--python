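"""Gene structures, CDS-relative intron positions, phases, and splice checks.

A :class:`GeneStructure` is the ordered list of coding-exon spans of one gene
in one species, in transcript 5'->3' order.  Intron positions are expressed
as *p*, the number of coding nucleotides strictly 5' of the intron; the
intron phase is ``p mod 3`` (0 = between codons, 1 = after the first codon
base, 2 = after the second), and the anchor residue is codon ``p // 3``.

All coordinates are 0-based half-open internally.  GFF3 input (1-based,
inclusive) is converted at the boundary.  The CDS is taken to include the
stop codon, so the encoded protein has ``cds_length/3 - 1`` residues.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

from .errors import CoordinateError, StructureParseError

COMPLEMENT = str.maketrans("acgtACGTnN", "tgcaTGCAnN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ExonSpan:
    """One coding-exon span, 0-based half-open."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise StructureParseError(
                f"invalid exon span [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IntronSite:
    """An intron position on the CDS-local coding axis.

    ``cds_offset`` is p, the count of coding nucleotides strictly 5' of the
    intron; ``phase == p % 3`` and ``anchor_codon == p // 3``.
    """

    gene_id: str
    ordinal: int  # 1-based, increasing 5'->3'
    cds_offset: int
    phase: int
    anchor_codon: int


@dataclass
class GeneStructure:
    """Ordered coding-exon spans of one gene, transcript orientation.

    ``exons`` are in transcript 5'->3' order: for a minus-strand gene the
    genomic start coordinates therefore *decrease* along the list.
    """

    gene_id: str
    species: str = ""
    family: str = ""
    strand: str = "+"
    contig_id: str | None = None
    exons: Sequence[ExonSpan] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise StructureParseError(
                f"{self.gene_id}: unknown strand {self.strand!r}"
            )
        if not self.exons:
            raise StructureParseError(f"{self.gene_id}: no exons")
        self._check_exons()
        if self.cds_length < 3 or self.cds_length % 3 != 0:
            raise StructureParseError(
                f"{self.gene_id}: CDS length {self.cds_length} "
                "is not a positive multiple of 3"
            )

    def _check_exons(self) -> None:
        spans = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(spans, spans[1:]):
            if a.end > b.start:
                raise StructureParseError(
                    f"{self.gene_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        # transcript orientation: + ascending genomic starts, - descending
        keys = [e.start for e in self.exons]
        expect = sorted(keys, reverse=(self.strand == "-"))
        if keys != expect:
            raise StructureParseError(
                f"{self.gene_id}: exons not in transcript orientation "
                f"for strand {self.strand}"
            )

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def protein_length(self) -> int:
        """Encoded protein length (CDS includes the stop codon)."""
        return self.cds_length // 3 - 1


def classify_phase(p: int) -> int:
    """Phase of an intron inserted after p coding nucleotides.

    0: between codons; 1: after the first base of a codon; 2: after the
    second.  Raises for p < 1 (an intron cannot precede the CDS).
    """
    if p < 1:
        raise CoordinateError(f"intron position p={p} must be >= 1")
    return p % 3


def derive_intron_sites(g: GeneStructure) -> list[IntronSite]:
    """Intron sites of a structure: one per exon-exon junction.

    Site k (1-based) has p = cumulative coding length of exons 1..k.
    Returns an empty list for a single-exon CDS.
    """
    sites: list[IntronSite] = []
    p = 0
    for k, exon in enumerate(g.exons[:-1], start=1):
        p += exon.length
        sites.append(
            IntronSite(
                gene_id=g.gene_id,
                ordinal=k,
                cds_offset=p,
                phase=classify_phase(p),
                anchor_codon=p // 3,
            )
        )
    return sites


def validate_splice_sites(
    g: GeneStructure, contig: str
) -> list[dict[str, bool]]:
    """Check the gt-ag rule for every intron of a genome-coordinate structure.

    Returns one ``{"starts_gt": bool, "ends_ag": bool}`` per intron in
    transcript order; case-insensitive and strand-aware (minus-strand introns
    are checked on the reverse complement).  Introns shorter than 4 nt are
    flagged ``False``/``False`` rather than raising.
    """
    for e in g.exons:
        if e.end > len(contig):
            raise CoordinateError(
                f"{g.gene_id}: exon [{e.start},{e.end}) beyond contig "
                f"length {len(contig)}"
            )
    reports: list[dict[str, bool]] = []
    for a, b in zip(g.exons, g.exons[1:]):
        if g.strand == "+":
            lo, hi = a.end, b.start
        else:
            lo, hi = b.end, a.start
        gap = contig[lo:hi]
        if len(gap) < 4:
            reports.append({"starts_gt": False, "ends_ag": False})
            continue
        if g.strand == "-":
            gap = revcomp(gap)
        gap = gap.lower()
        reports.append(
            {"starts_gt": gap[:2] == "gt", "ends_ag": gap[-2:] == "ag"}
        )
    return reports


# ---------------------------------------------------------------------------
# readers

EXON_TSV_COLUMNS = [
    "gene_id",
    "species",
    "family",
    "strand",
    "contig_id",
    "exon_index",
    "start",
    "end",
]


def _structures_from_exon_tsv(path: Path) -> list[GeneStructure]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(EXON_TSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise StructureParseError(
                f"{path}: missing exon_tsv columns {sorted(missing)}"
            )
        rows = list(reader)
    by_gene: dict[str, list[dict]] = {}
    order: list[str] = []
    for row in rows:
        gid = row["gene_id"]
        if gid not in by_gene:
            by_gene[gid] = []
            order.append(gid)
        by_gene[gid].append(row)
    structures = []
    for gid in order:
        recs = sorted(by_gene[gid], key=lambda r: int(r["exon_index"]))
        first = recs[0]
        try:
            exons = [ExonSpan(int(r["start"]), int(r["end"])) for r in recs]
        except (ValueError, StructureParseError) as exc:
            raise StructureParseError(f"{path}: gene {gid}: {exc}") from exc
        structures.append(
            GeneStructure(
                gene_id=gid,
                species=first["species"],
                family=first["family"],
                strand=first["strand"],
                contig_id=first["contig_id"] or None,
                exons=exons,
            )
        )
    return structures


def _structures_from_gff3(path: Path) -> list[GeneStructure]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    groups: dict[str, list] = {}
    order: list[str] = []
    for feat in db.features_of_type("CDS", order_by="start"):
        parents = feat.attributes.get("Parent") or feat.attributes.get("ID")
        if not parents:
            raise StructureParseError(
                f"{path}: CDS at {feat.seqid}:{feat.start} has no "
                "Parent/ID attribute"
            )
        key = parents[0]
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(feat)
    structures = []
    for key in order:
        feats = groups[key]
        strands = {f.strand for f in feats}
        if len(strands) != 1 or strands & {".", "?"}:
            raise StructureParseError(
                f"{path}: record {key}: unknown or mixed strand {strands}"
            )
        strand = strands.pop()
        # GFF3 is 1-based inclusive -> 0-based half-open
        feats.sort(key=lambda f: f.start, reverse=(strand == "-"))
        first = feats[0]
        attrs = first.attributes
        structures.append(
            GeneStructure(
                gene_id=key,
                species=(attrs.get("species") or [""])[0],
                family=(attrs.get("family") or [""])[0],
                strand=strand,
                contig_id=first.seqid,
                exons=[ExonSpan(f.start - 1, f.end) for f in feats],
            )
        )
    return structures


def read_structures(
    path: str | Path, format: str = "exon_tsv"
) -> list[GeneStructure]:
    """Read gene structures from ``exon_tsv`` or ``gff3``.

    exon_tsv: tab-separated with header ``gene_id species family strand
    contig_id exon_index start end`` in 0-based half-open coordinates.
    gff3: CDS features grouped by their Parent attribute; minus-strand
    features are reordered into transcript orientation.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    if format == "exon_tsv":
        return _structures_from_exon_tsv(path)
    if format == "gff3":
        return _structures_from_gff3(path)
    raise StructureParseError(f"unknown structure format {format!r}")


def write_exon_tsv(structures: Iterable[GeneStructure], path: str | Path) -> None:
    """Write structures in the exon_tsv dialect understood by read_structures."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(EXON_TSV_COLUMNS)
        for g in structures:
            for i, e in enumerate(g.exons):
                writer.writerow(
                    [g.gene_id, g.species, g.family, g.strand,
                     g.contig_id or "", i, e.start, e.end]
                )
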