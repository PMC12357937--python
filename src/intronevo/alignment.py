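"""Projection of intron sites onto protein multiple-sequence-alignment columns.

An intron with anchor residue r (codon ``p // 3``) in gene g is projected to
the alignment column that holds the (r+1)-th non-gap character of g's row;
the phase travels with it unchanged.  Two introns in different genes are
candidate homologues when they share (column, phase) exactly.

Nucleotide offsets between projected introns — the quantity behind
statements like "inserted 7 bp away" — are measured on ONE declared
reference row's coding axis: position = 3*r + phase, where r counts the
non-gap reference residues strictly before the column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import AlignIO, SeqIO

from .errors import CoordinateError, ProjectionError
from .gene_models import IntronSite


@dataclass
class Msa:
    """A protein alignment as an id -> aligned-row mapping, gap = '-'."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise CoordinateError(f"ragged alignment: row lengths {lengths}")
        # '.' is an alternative gap in some aligner outputs
        self.rows = {k: v.replace(".", "-") for k, v in self.rows.items()}

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def ungapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace("-", "")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Msa":
        aln = AlignIO.read(str(path), "fasta")
        return cls({rec.id: str(rec.seq) for rec in aln})

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name, row in self.rows.items():
                fh.write(f">{name}\n{row}\n")


@dataclass(frozen=True)
class ProjectedIntron:
    """An intron site in alignment coordinates: anchor column + phase."""

    gene_id: str
    ordinal: int
    column: int
    phase: int
    family: str = ""
    taxon: str = ""

    @property
    def key(self) -> tuple[int, int]:
        return (self.column, self.phase)


def column_of_residue(msa: Msa, seq_id: str, residue_index: int) -> int:
    """Alignment column of the (residue_index+1)-th non-gap character."""
    if seq_id not in msa.rows:
        raise CoordinateError(f"sequence {seq_id!r} not in alignment")
    if residue_index < 0:
        raise CoordinateError(f"{seq_id}: negative residue index {residue_index}")
    seen = -1
    for col, char in enumerate(msa.rows[seq_id]):
        if char != "-":
            seen += 1
            if seen == residue_index:
                return col
    raise CoordinateError(
        f"{seq_id}: residue index {residue_index} beyond ungapped "
        f"length {seen + 1}"
    )


def residue_of_column(msa: Msa, seq_id: str, column: int) -> int:
    """Inverse of column_of_residue for non-gap columns (0-based residue)."""
    row = msa.rows[seq_id]
    if row[column] == "-":
        raise CoordinateError(f"{seq_id}: column {column} is a gap")
    return sum(1 for c in row[:column] if c != "-")


def project_introns(
    msa: Msa,
    sites: Iterable[IntronSite],
    protein_lengths: Mapping[str, int] | None = None,
    family_of_gene: Mapping[str, str] | None = None,
    taxon_of_gene: Mapping[str, str] | None = None,
) -> list[ProjectedIntron]:
    """Project intron sites into alignment coordinates.

    When ``protein_lengths`` is given, each gene's ungapped row must match it
    and anchor codons at or past the stop codon raise :class:`ProjectionError`.
    """
    projected: list[ProjectedIntron] = []
    for site in sites:
        gid = site.gene_id
        if gid not in msa.rows:
            raise CoordinateError(f"gene {gid!r} not in alignment")
        if protein_lengths is not None:
            plen = protein_lengths[gid]
            ungapped = len(msa.ungapped(gid))
            if ungapped != plen:
                raise ProjectionError(
                    f"{gid}: alignment row has {ungapped} residues but "
                    f"protein length is {plen}"
                )
            if site.anchor_codon >= plen:
                raise ProjectionError(
                    f"{gid}: intron {site.ordinal} anchors at codon "
                    f"{site.anchor_codon}, within/after the stop codon "
                    f"(protein length {plen})"
                )
        col = column_of_residue(msa, gid, site.anchor_codon)
        projected.append(
            ProjectedIntron(
                gene_id=gid,
                ordinal=site.ordinal,
                column=col,
                phase=site.phase,
                family=(family_of_gene or {}).get(gid, ""),
                taxon=(taxon_of_gene or {}).get(gid, ""),
            )
        )
    return projected


def ref_nt_position(msa: Msa, ref_id: str, proj: ProjectedIntron) -> int:
    """Coding-nucleotide coordinate of a projection on a reference row.

    3*r + phase, with r = number of non-gap reference characters in columns
    strictly before the projection's column.  Well defined (the position
    collapses onto the preceding residue count) even when the reference has
    a gap at that column.
    """
    if ref_id not in msa.rows:
        raise CoordinateError(f"reference {ref_id!r} not in alignment")
    row = msa.rows[ref_id]
    r = sum(1 for c in row[: proj.column] if c != "-")
    return 3 * r + proj.phase


def offset_between(
    msa: Msa, ref_id: str, a: ProjectedIntron, b: ProjectedIntron
) -> int:
    """Absolute nucleotide distance between two projections on a reference."""
    return abs(ref_nt_position(msa, ref_id, a) - ref_nt_position(msa, ref_id, b))


def write_projection_tsv(
    projected: Sequence[ProjectedIntron], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tordinal\tcolumn\tphase\ttaxon\tfamily\n")
        for p in projected:
            fh.write(
                f"{p.gene_id}\t{p.ordinal}\t{p.column}\t{p.phase}\t"
                f"{p.taxon}\t{p.family}\n"
            )


def read_protein_lengths(path: str | Path) -> dict[str, int]:
    """Protein lengths from an (unaligned) FASTA file."""
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
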