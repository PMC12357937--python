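"""Synthetic datasets with planted truth, and the packaged lineage fixture.

Two generators live here:

* :func:`simulate` evolves a coding gene along a rooted tree with
  single-origin intron gains (a Poisson process per branch at distinct
  (codon, phase) sites — the Dollo assumption is enforced by construction),
  optional losses, per-site amino-acid substitutions, and optional
  codon-aligned indels with the true alignment tracked throughout.  Every
  event is recorded in a truth log so that pipeline output can be compared
  against planted reality.

* :func:`make_te_intron` builds a transposon-derived intron the way a cut-
  and-paste DNA-transposon insertion into an exon would: a target-site
  duplication straddling the splice junctions (the splice gt/ag fall inside
  the duplicated and inverted repeats), terminal inverted-repeat arms
  beginning ``tgt`` / ending ``aca``, and a central tandem array.

:func:`paper_fixture` loads the packaged lineage-level presence/absence
matrices for the two anion-transporter paralogs and the two published
alternatives for the Euteleostei backbone topology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .dollo import SpeciesTree
from .errors import GenerationError
from .gene_models import ExonSpan, GeneStructure, revcomp, write_exon_tsv
from .homology import PresenceMatrix

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "acgt"

# one fixed sense codon per amino acid keeps CDS emission deterministic
CODON_OF_AA = {
    "A": "gct", "C": "tgt", "D": "gat", "E": "gaa", "F": "ttt",
    "G": "ggt", "H": "cat", "I": "att", "K": "aaa", "L": "ctg",
    "M": "atg", "N": "aat", "P": "cct", "Q": "caa", "R": "cgt",
    "S": "tct", "T": "act", "V": "gtt", "W": "tgg", "Y": "tat",
}
STOP_CODON = "taa"


def _rand_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(NT_ALPHABET), size=n)) if n > 0 else ""


def _rand_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=n))


# ---------------------------------------------------------------------------
# gene evolution on a tree


@dataclass
class SimConfig:
    """Stated world of the gene-evolution simulator.

    Rates are per unit branch length; the substitution rate is per protein
    site.  Intron gains are drawn at distinct (codon, phase) sites so no
    position is ever gained twice (Dollo by construction) unless
    ``allow_homoplasy`` is set for stress testing.
    """

    tree: str  # Newick with branch lengths
    cds_codons: int = 300  # protein length at the root, in residues
    root_introns: tuple[tuple[int, int], ...] = ()
    gain_rate: float = 0.4
    loss_rate: float = 0.0
    subst_rate: float = 0.05
    indels: bool = False
    indel_rate: float = 0.02
    seed: int = 0
    allow_homoplasy: bool = False

    def __post_init__(self) -> None:
        if self.cds_codons < 50:
            raise GenerationError("CDS length must be at least 50 codons")
        if min(self.gain_rate, self.loss_rate, self.subst_rate,
               self.indel_rate) < 0:
            raise GenerationError("rates must be non-negative")


def default_tree(n_leaves: int = 8, branch_length: float = 1.0) -> str:
    """A balanced rooted tree over taxa t1..tN with equal branch lengths."""
    nodes = [f"t{i + 1}:{branch_length}" for i in range(n_leaves)]
    while len(nodes) > 1:
        paired = []
        for i in range(0, len(nodes) - 1, 2):
            paired.append(f"({nodes[i]},{nodes[i + 1]}):{branch_length}")
        if len(nodes) % 2:
            paired.append(nodes[-1])
        nodes = paired
    return nodes[0].rsplit(":", 1)[0] + ";"


@dataclass
class TruthLog:
    """Planted events, character map, and true alignment of one simulation."""

    seed: int
    gains: dict[str, list[dict]] = field(default_factory=dict)
    losses: dict[str, list[dict]] = field(default_factory=dict)
    characters: list[dict] = field(default_factory=list)
    alignment: dict[str, str] = field(default_factory=dict)

    @property
    def n_gains(self) -> int:
        return sum(len(v) for v in self.gains.values())

    @property
    def n_losses(self) -> int:
        return sum(len(v) for v in self.losses.values())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "gains": self.gains,
                    "losses": self.losses,
                    "characters": self.characters,
                    "alignment": self.alignment,
                },
                indent=2,
            ),
            encoding="utf-8",
        )


@dataclass
class SimDataset:
    """In-memory result of :func:`simulate` (also written to disk)."""

    config: SimConfig
    tree: SpeciesTree
    structures: list[GeneStructure]
    contigs: dict[str, str]
    cds: dict[str, str]
    proteins: dict[str, str]
    alignment: dict[str, str]
    truth: TruthLog


class _Lineage:
    """Mutable per-lineage state: column ids, residues, present introns."""

    __slots__ = ("cols", "aas", "introns")

    def __init__(self, cols: list[int], aas: list[str],
                 introns: set[tuple[int, int]]):
        self.cols = cols
        self.aas = aas
        self.introns = introns

    def copy(self) -> "_Lineage":
        return _Lineage(list(self.cols), list(self.aas), set(self.introns))


def simulate(config: SimConfig, out_dir: str | Path | None = None) -> SimDataset:
    """Evolve a coding gene with introns along ``config.tree``.

    Returns the dataset in memory; when ``out_dir`` is given, also writes
    structures.tsv, contigs.fasta, cds.fasta, proteins.fasta,
    alignment.fasta, tree.nwk and truth.json.  Deterministic for a fixed
    config and seed.
    """
    rng = np.random.default_rng(config.seed)
    tree = SpeciesTree.from_newick(config.tree)
    L = config.cds_codons
    master: list[int] = list(range(L))  # global column order
    next_col = L
    used_sites: set[tuple[int, int]] = set()
    truth = TruthLog(seed=config.seed)

    root_introns = set()
    for codon, phase in config.root_introns:
        if not (1 <= codon < L and phase in (0, 1, 2)):
            raise GenerationError(
                f"root intron ({codon},{phase}) outside CDS of {L} codons"
            )
        root_introns.add((codon, phase))
        used_sites.add((codon, phase))
    root_state = _Lineage(list(range(L)), list(_rand_aa(rng, L)), root_introns)

    states: dict[str, _Lineage] = {}

    def evolve_branch(parent: _Lineage, child_label: str, bl: float) -> _Lineage:
        nonlocal next_col
        st = parent.copy()
        # substitutions
        n_sub = rng.binomial(len(st.aas), min(1.0, config.subst_rate * bl))
        for i in rng.choice(len(st.aas), size=n_sub, replace=False):
            old = st.aas[i]
            choices = [a for a in AA_ALPHABET if a != old]
            st.aas[i] = choices[rng.integers(len(choices))]
        # codon-aligned indels with alignment tracking
        if config.indels:
            for _ in range(rng.poisson(config.indel_rate * bl)):
                size = int(rng.integers(1, 4))
                if rng.random() < 0.5:  # insertion
                    pos = int(rng.integers(0, len(st.cols) + 1))
                    new_cols = list(range(next_col, next_col + size))
                    next_col += size
                    if pos == 0:
                        anchor = master.index(st.cols[0])
                        master[anchor:anchor] = new_cols
                    else:
                        anchor = master.index(st.cols[pos - 1])
                        master[anchor + 1 : anchor + 1] = new_cols
                    st.cols[pos:pos] = new_cols
                    st.aas[pos:pos] = list(_rand_aa(rng, size))
                else:  # deletion avoiding intron anchors and over-shrinking
                    if len(st.cols) - size < 50:
                        continue
                    anchors = {c for c, _ in st.introns}
                    for _attempt in range(20):
                        # never delete the first codon: keeps every intron
                        # strictly inside the CDS (p >= 1)
                        pos = int(rng.integers(1, len(st.cols) - size + 1))
                        seg = st.cols[pos : pos + size]
                        if not anchors & set(seg):
                            del st.cols[pos : pos + size]
                            del st.aas[pos : pos + size]
                            break
        # intron gains: distinct (column, phase) sites, Dollo by construction
        for _ in range(rng.poisson(config.gain_rate * bl)):
            for _attempt in range(1000):
                idx = int(rng.integers(1, len(st.cols)))
                phase = int(rng.integers(0, 3))
                site = (st.cols[idx], phase)
                if config.allow_homoplasy or site not in used_sites:
                    break
            else:
                raise GenerationError(
                    "could not place a new intron: CDS too short for the "
                    "requested number of distinct gains"
                )
            used_sites.add(site)
            st.introns.add(site)
            truth.gains.setdefault(child_label, []).append(
                {"column_id": site[0], "phase": site[1]}
            )
        # intron losses
        for _ in range(rng.poisson(config.loss_rate * bl)):
            if not st.introns:
                break
            present = sorted(st.introns)
            site = present[rng.integers(len(present))]
            st.introns.discard(site)
            truth.losses.setdefault(child_label, []).append(
                {"column_id": site[0], "phase": site[1]}
            )
        return st

    root = tree.tree.seed_node
    states[tree.label_of(root)] = root_state
    for node in tree.tree.preorder_node_iter():
        if node is root:
            continue
        parent_label = tree.label_of(node.parent_node)
        label = tree.label_of(node)
        bl = node.edge.length if node.edge.length is not None else 1.0
        states[label] = evolve_branch(states[parent_label], label, bl)

    # assemble leaf-level outputs
    leaf_labels = sorted(tree.leaf_labels)
    order_index = {c: i for i, c in enumerate(master)}
    proteins: dict[str, str] = {}
    alignment: dict[str, str] = {}
    cds: dict[str, str] = {}
    contigs: dict[str, str] = {}
    structures: list[GeneStructure] = []
    for leaf in leaf_labels:
        st = states[leaf]
        proteins[leaf] = "".join(st.aas)
        present = set(st.cols)
        row = []
        pos_of_col = {c: i for i, c in enumerate(st.cols)}
        for c in master:
            row.append(st.aas[pos_of_col[c]] if c in present else "-")
        alignment[leaf] = "".join(row)
        cds_seq = "".join(CODON_OF_AA[a] for a in st.aas) + STOP_CODON
        cds[leaf] = cds_seq
        # CDS-relative intron positions p = 3*codon_index + phase
        ps = sorted(
            3 * pos_of_col[c] + phase
            for c, phase in st.introns
            if c in present
        )
        # genomic contig: exons joined by gt..ag introns, plus pads
        cuts = [0] + ps + [len(cds_seq)]
        exon_seqs = [cds_seq[a:b] for a, b in zip(cuts, cuts[1:])]
        pad5 = _rand_nt(rng, 20)
        pieces = [pad5]
        exon_spans: list[ExonSpan] = []
        cursor = len(pad5)
        for i, ex in enumerate(exon_seqs):
            pieces.append(ex)
            exon_spans.append(ExonSpan(cursor, cursor + len(ex)))
            cursor += len(ex)
            if i < len(exon_seqs) - 1:
                ilen = int(rng.integers(60, 121))
                intron_seq = "gt" + _rand_nt(rng, ilen - 4) + "ag"
                pieces.append(intron_seq)
                cursor += ilen
        pieces.append(_rand_nt(rng, 20))
        contig_id = f"contig_{leaf}"
        contigs[contig_id] = "".join(pieces)
        structures.append(
            GeneStructure(
                gene_id=leaf,
                species=leaf,
                family="sim",
                strand="+",
                contig_id=contig_id,
                exons=exon_spans,
            )
        )

    # character map: every planted site that survives in at least one leaf
    for site in sorted(used_sites):
        col_id, phase = site
        possessors = [
            leaf
            for leaf in leaf_labels
            if site in states[leaf].introns and col_id in set(states[leaf].cols)
        ]
        if not possessors:
            continue
        truth.characters.append(
            {
                "column_id": col_id,
                "phase": phase,
                "column": order_index[col_id],
                "possessors": possessors,
            }
        )
    truth.alignment = alignment

    dataset = SimDataset(
        config=config,
        tree=tree,
        structures=structures,
        contigs=contigs,
        cds=cds,
        proteins=proteins,
        alignment=alignment,
        truth=truth,
    )
    if out_dir is not None:
        _write_dataset(dataset, Path(out_dir))
    return dataset


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def _write_dataset(ds: SimDataset, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_exon_tsv(ds.structures, out_dir / "structures.tsv")
    _write_fasta(ds.contigs, out_dir / "contigs.fasta")
    _write_fasta(ds.cds, out_dir / "cds.fasta")
    _write_fasta(ds.proteins, out_dir / "proteins.fasta")
    _write_fasta(ds.alignment, out_dir / "alignment.fasta")
    (out_dir / "tree.nwk").write_text(ds.config.tree, encoding="utf-8")
    ds.truth.to_json(out_dir / "truth.json")
    (out_dir / "config.json").write_text(
        json.dumps(asdict(ds.config), indent=2), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# transposon-derived introns


@dataclass
class TeIntronParams:
    """Knobs of the planted transposon-intron construct.

    Defaults mirror the notothenioid observations the generator emulates:
    a 4-nt target-site duplication and a 37-nt central tandem unit (four
    copies with two point mutations in the array), with 12-nt inverted
    arms and 30-nt exonic flanks.
    """

    tsd_len: int = 4
    tir_arm: int = 12
    tandem_unit: int = 37
    tandem_copies: int = 4
    tandem_mutations: int = 2
    spacer_len: int = 20
    flank_len: int = 30


def _mutate_nt(seq: str, n: int, rng: np.random.Generator) -> str:
    chars = list(seq)
    if n <= 0 or not chars:
        return seq
    for i in rng.choice(len(chars), size=min(n, len(chars)), replace=False):
        alt = [b for b in NT_ALPHABET if b != chars[i]]
        chars[i] = alt[rng.integers(len(alt))]
    return "".join(chars)


def _has_boundary_pair_longer_than(
    flank5: str, intron: str, flank3: str, length: int, window: int = 10
) -> bool:
    """True if some exact boundary-bracketing direct repeat exceeds `length`.

    Used to certify the planted construct: the planted duplication must be
    the longest one, otherwise the instance does not represent its own
    truth annotation and is redrawn.
    """
    from .te import detect_tsd

    hits = detect_tsd(
        flank5, intron, flank3,
        min_len=length + 1, max_len=length + 4, window=window,
    )
    return bool(hits)


def make_te_intron(
    params: TeIntronParams | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[str, str, str, dict]:
    """Build (flank5, intron, flank3, truth) for a planted TE-derived intron.

    Layout (exon | intron | exon), with the TSD copies straddling the
    junctions so the splice gt/ag lie inside the repeats:

        ...exon [TSD5'part]| gt [TIR-left ... tandem array ... TIR-right] ag |[TSD3'part] exon...

    The first TSD copy ends with the intron's ``gt``; the second begins
    with its ``ag``.  TIR arms begin ``tgt`` and end ``aca``.  Random
    portions are redrawn until no accidental direct repeat longer than the
    planted TSD brackets the boundaries, so the truth annotation is exact.
    """
    p = params or TeIntronParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if p.tsd_len and p.tsd_len < 4:
        raise GenerationError(
            "tsd_len must be 0 (disabled) or >= 4: the duplication must "
            "contain both the splice gt and ag"
        )
    for _attempt in range(100):
        tsd = "ag" + _rand_nt(rng, p.tsd_len - 4) + "gt" if p.tsd_len else ""
        arm = "tgt" + _rand_nt(rng, p.tir_arm - 3)
        unit = _rand_nt(rng, p.tandem_unit)
        array = _mutate_nt(unit * p.tandem_copies, p.tandem_mutations, rng) \
            if p.tandem_copies >= 2 else unit
        spacer1 = _rand_nt(rng, p.spacer_len)
        spacer2 = _rand_nt(rng, p.spacer_len)
        element = arm + spacer1 + array + spacer2 + revcomp(arm)
        intron = "gt" + element + "ag"
        if p.tsd_len:
            exon5_tail = tsd[:-2]  # ends where the intron's gt begins
            exon3_head = tsd[2:]
            # block the trivial 1-nt extensions of the planted pair
            left = _rand_nt(rng, p.flank_len - len(exon5_tail))
            while left and left[-1] == "a":
                left = left[:-1] + _rand_nt(rng, 1)
            right = _rand_nt(rng, p.flank_len - len(exon3_head))
            while right and right[0] == "t":
                right = _rand_nt(rng, 1) + right[1:]
            flank5 = left + exon5_tail
            flank3 = exon3_head + right
            if _has_boundary_pair_longer_than(flank5, intron, flank3, p.tsd_len):
                continue
        else:
            flank5 = _rand_nt(rng, p.flank_len)
            flank3 = _rand_nt(rng, p.flank_len)
            # truth is "no duplication": redraw chance boundary pairs too
            if _has_boundary_pair_longer_than(flank5, intron, flank3, 3):
                continue
        truth = {
            "tsd_len": p.tsd_len,
            "tsd_seq": tsd,
            "tir_arm": p.tir_arm,
            "tir_left_span": (2, 2 + len(arm)),
            "tir_right_span": (len(intron) - 2 - len(arm), len(intron) - 2),
            "tandem_unit": p.tandem_unit,
            "tandem_copies": p.tandem_copies,
            "tandem_span": (
                2 + len(arm) + len(spacer1),
                2 + len(arm) + len(spacer1) + len(array),
            ),
            "element_span": (2, 2 + len(element)),
        }
        return flank5, intron, flank3, truth
    raise GenerationError(
        "could not draw a clean TE-intron construct in 100 attempts"
    )


def plant_copies(
    query: str,
    n_contigs: int,
    contig_len: int = 600,
    mut_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    prefix: str = "decoy",
) -> list[tuple[str, str]]:
    """Random contigs each carrying one (optionally mutated) copy of query."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for i in range(n_contigs):
        pad = max(contig_len - len(query), 20)
        at = int(rng.integers(5, pad - 5))
        copy = _mutate_nt(query, rng.binomial(len(query), mut_rate), rng)
        seq = _rand_nt(rng, at) + copy + _rand_nt(rng, pad - at)
        out.append((f"{prefix}_{i + 1}", seq))
    return out


# ---------------------------------------------------------------------------
# packaged lineage fixture


# tree node labels used by downstream analyses of the fixture
RAYFINNED_ROOT = "Actinopterygii"
TELEOST_ROOT = "Teleostei"
EURYPTERYGII_CROWN = "Eurypterygii"
SYNGNATHID_CLADE = "Syngnathid_clade"
NOTOTHENIOID_CROWN = "Notothenioid_crown"

SLC26A1_CHARACTERS = ("A1", "E1", "E2", "E3", "E4", "E5", "O1")
SLC26A2_CHARACTERS = ("A1p", "R1", "Q1", "O2", "N1", "N2")


def _data_text(name: str) -> str:
    return (resources.files("intronevo") / "data" / name).read_text(
        encoding="utf-8"
    )


def paper_fixture() -> dict:
    """Lineage-level presence/absence matrices and candidate topologies.

    Matrices (11 lineage taxa): one per paralog.  slc26a1 characters:
    A1 (ancient intron shared by all jawed vertebrates), E1-E5 (the five
    introns gained on the stem of Eurypterygii/Galaxiiformes), O1 (the
    independent Osmeriformes/Stomiiformes intron ~23 nt from E2).
    slc26a2 characters: A1p (ancient), R1 (the ray-finned-ancestor intron),
    Q1 (Eurypterygii/Galaxiiformes gain), O2 (Osmeriformes/Stomiiformes
    intron ~7 nt from Q1), N1/N2 (the two notothenioid-crown gains).

    Trees: the backbone placing Galaxiiformes sister to Neoteleostei
    ('lavoue_near') and the alternative placing Galaxiiformes with
    Esociformes/Salmoniformes/Argentiniformes ('betancur').
    """
    import io
    import pandas as pd

    def _matrix(name: str) -> PresenceMatrix:
        df = pd.read_csv(io.StringIO(_data_text(name)), sep="\t", index_col=0)
        return PresenceMatrix(df)

    return {
        "matrices": {
            "slc26a1": _matrix("slc26a1_matrix.tsv"),
            "slc26a2": _matrix("slc26a2_matrix.tsv"),
        },
        "trees": {
            "lavoue_near": SpeciesTree.from_newick(
                _data_text("tree_lavoue_near.nwk")
            ),
            "betancur": SpeciesTree.from_newick(
                _data_text("tree_betancur.nwk")
            ),
        },
    }


def combined_fixture_matrix(fixture: dict | None = None) -> PresenceMatrix:
    """Both paralogs' characters side by side over the shared lineage taxa."""
    import pandas as pd

    fx = fixture or paper_fixture()
    a1 = fx["matrices"]["slc26a1"].df.add_prefix("slc26a1:")
    a2 = fx["matrices"]["slc26a2"].df.add_prefix("slc26a2:")
    return PresenceMatrix(pd.concat([a1, a2], axis=1))
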