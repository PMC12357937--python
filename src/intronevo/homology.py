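"""Intron-position homology: exact clustering, near-miss reporting,
cross-family convergence, and presence/absence matrix construction.

Homology of intron positions is strict: two projected introns are assigned
to the same character only when they share the alignment column AND the
phase.  Positions a few nucleotides apart (the "7 bp"/"23 bp" cases) remain
distinct characters and are surfaced as near matches, never merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .alignment import Msa, ProjectedIntron, offset_between
from .errors import CoordinateError, TaxonMappingError


@dataclass
class PositionCluster:
    """All projected introns sharing one exact (column, phase) position."""

    column: int
    phase: int
    character_id: str
    members: list[ProjectedIntron] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, int]:
        return (self.column, self.phase)

    @property
    def families(self) -> set[str]:
        return {m.family for m in self.members}

    def representative(self) -> ProjectedIntron:
        return self.members[0]


@dataclass(frozen=True)
class NearMatch:
    cluster_a: str
    cluster_b: str
    offset_nt: int
    reference_id: str


@dataclass(frozen=True)
class ConvergencePair:
    cluster_a: str
    cluster_b: str
    family_a: str
    family_b: str
    offset_nt: int
    flag: str  # "identical" | "near"


def cluster_exact(
    projected: Sequence[ProjectedIntron], prefix: str = "C"
) -> list[PositionCluster]:
    """Partition projections by exact (column, phase).

    Character ids are deterministic: clusters ordered by column then phase
    and labelled ``{prefix}1``, ``{prefix}2``, ...
    """
    by_key: dict[tuple[int, int], list[ProjectedIntron]] = {}
    for p in projected:
        by_key.setdefault(p.key, []).append(p)
    clusters = []
    for i, key in enumerate(sorted(by_key), start=1):
        col, phase = key
        clusters.append(
            PositionCluster(
                column=col,
                phase=phase,
                character_id=f"{prefix}{i}",
                members=by_key[key],
            )
        )
    return clusters


def near_matches(
    clusters: Sequence[PositionCluster],
    msa: Msa,
    ref_id: str,
    max_offset_nt: int = 30,
) -> list[NearMatch]:
    """Unordered cluster pairs separated by 1..max_offset_nt on a reference.

    Phase enters the reference coordinate (3r + phase), so two distinct
    clusters always sit a positive number of nucleotides apart; clusters in
    the same codon differ by 1-2 nt and are reported.  Clusters are never
    merged — a near match is a report, not a homology statement.
    """
    if ref_id not in msa.rows:
        raise CoordinateError(f"reference {ref_id!r} not in alignment")
    out: list[NearMatch] = []
    for i, a in enumerate(clusters):
        for b in clusters[i + 1 :]:
            off = offset_between(
                msa, ref_id, a.representative(), b.representative()
            )
            if 0 < off <= max_offset_nt:
                first, second = sorted([a.character_id, b.character_id])
                out.append(NearMatch(first, second, off, ref_id))
    out.sort(key=lambda m: (m.offset_nt, m.cluster_a, m.cluster_b))
    return out


def detect_convergence(
    projected: Sequence[ProjectedIntron],
    msa: Msa,
    ref_id: str,
    max_offset_nt: int = 30,
) -> list[ConvergencePair]:
    """Cross-family identical or near intron positions on a joint alignment.

    Projections must carry family labels.  Pairs of clusters whose member
    family sets differ are reported with offset 0 ("identical" — possible
    when one cluster already spans two families sharing the exact position)
    or 1..max_offset_nt ("near").  A single family yields an empty report.
    """
    families = {p.family for p in projected}
    if len(families) < 2:
        return []
    clusters = cluster_exact(projected)
    out: list[ConvergencePair] = []
    # identical positions across families within one cluster
    for c in clusters:
        fams = sorted(c.families)
        if len(fams) > 1:
            for i, fa in enumerate(fams):
                for fb in fams[i + 1 :]:
                    out.append(
                        ConvergencePair(
                            c.character_id, c.character_id, fa, fb, 0,
                            "identical",
                        )
                    )
    for i, a in enumerate(clusters):
        for b in clusters[i + 1 :]:
            cross = [
                (fa, fb)
                for fa in sorted(a.families)
                for fb in sorted(b.families)
                if fa != fb
            ]
            if not cross:
                continue
            off = offset_between(
                msa, ref_id, a.representative(), b.representative()
            )
            if 0 < off <= max_offset_nt:
                for fa, fb in cross:
                    out.append(
                        ConvergencePair(
                            a.character_id, b.character_id, fa, fb, off,
                            "near",
                        )
                    )
    out.sort(key=lambda p: (p.offset_nt, p.cluster_a, p.cluster_b))
    return out


class PresenceMatrix:
    """Binary taxa x intron-position-character matrix.

    Backed by a pandas DataFrame with taxa as rows and character ids as
    columns; every character must have at least one possessor taxon.
    """

    def __init__(self, df: pd.DataFrame):
        if not df.empty:
            vals = set(df.to_numpy().ravel().tolist())
            if not vals <= {0, 1}:
                raise ValueError(f"non-binary matrix cells: {vals - {0, 1}}")
            if (df.sum(axis=0) == 0).any():
                empty = df.columns[df.sum(axis=0) == 0].tolist()
                raise ValueError(f"characters with no possessor: {empty}")
        self.df = df.astype(int) if not df.empty else df

    @property
    def taxa(self) -> list[str]:
        return list(self.df.index)

    @property
    def characters(self) -> list[str]:
        return list(self.df.columns)

    def possessors(self, character: str) -> list[str]:
        col = self.df[character]
        return list(col.index[col == 1])

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index_label="taxon")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)

    def to_relaxed_phylip(self, path: str | Path) -> None:
        """Relaxed-phylip binary matrix (name, space, 0/1 string per row)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.taxa)} {len(self.characters)}\n")
            for taxon in self.taxa:
                states = "".join(str(v) for v in self.df.loc[taxon])
                fh.write(f"{taxon}  {states}\n")


def build_matrix(
    clusters: Sequence[PositionCluster],
    taxon_of_gene: Mapping[str, str],
    all_taxa: Sequence[str] | None = None,
) -> PresenceMatrix:
    """Presence/absence matrix from position clusters.

    cell(t, c) = 1 iff taxon t owns a member of cluster c.  ``all_taxa``
    adds taxa with genes but no introns as all-zero rows (default: the
    range of ``taxon_of_gene``).  A taxon contributing two distinct genes
    to one family is rejected: deduplicate paralogs first.
    """
    for c in clusters:
        for m in c.members:
            if m.gene_id not in taxon_of_gene:
                raise TaxonMappingError(
                    f"gene {m.gene_id!r} has no taxon mapping"
                )
    seen: dict[tuple[str, str], set[str]] = {}
    for c in clusters:
        for m in c.members:
            key = (taxon_of_gene[m.gene_id], m.family)
            seen.setdefault(key, set()).add(m.gene_id)
    dupes = {k: v for k, v in seen.items() if len(v) > 1}
    if dupes:
        raise TaxonMappingError(
            "multiple genes per taxon per family; deduplicate before "
            f"matrix building: {dupes}"
        )
    taxa = list(all_taxa) if all_taxa is not None else sorted(
        set(taxon_of_gene.values())
    )
    data = {
        c.character_id: [
            1 if t in {taxon_of_gene[m.gene_id] for m in c.members} else 0
            for t in taxa
        ]
        for c in clusters
    }
    df = pd.DataFrame(data, index=pd.Index(taxa, name="taxon"))
    return PresenceMatrix(df)


def write_clusters_tsv(
    clusters: Sequence[PositionCluster], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("character_id\tcolumn\tphase\tgene_id\tordinal\ttaxon\tfamily\n")
        for c in clusters:
            for m in c.members:
                fh.write(
                    f"{c.character_id}\t{c.column}\t{c.phase}\t{m.gene_id}\t"
                    f"{m.ordinal}\t{m.taxon}\t{m.family}\n"
                )
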