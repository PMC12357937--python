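"""Planted-truth generators: determinism, truth replay, recovery, fixture."""

import json

import numpy as np
import pytest

from intronevo.alignment import Msa, project_introns
from intronevo.dollo import dollo_reconstruct
from intronevo.errors import GenerationError
from intronevo.gene_models import derive_intron_sites, validate_splice_sites
from intronevo.homology import build_matrix, cluster_exact
from intronevo.simulate import (
    SimConfig,
    TeIntronParams,
    default_tree,
    make_te_intron,
    simulate,
)
from intronevo.te import detect_tsd, tandem_period


def run_pipeline(ds):
    """structures -> sites -> projection -> clusters -> matrix -> events."""
    sites = [s for g in ds.structures for s in derive_intron_sites(g)]
    msa = Msa(dict(ds.alignment))
    plens = {g.gene_id: g.protein_length for g in ds.structures}
    taxa = {g.gene_id: g.species for g in ds.structures}
    projected = project_introns(msa, sites, plens, taxon_of_gene=taxa)
    clusters = cluster_exact(projected)
    matrix = build_matrix(
        clusters, {g.gene_id: g.species for g in ds.structures},
        all_taxa=sorted(ds.tree.leaf_labels),
    )
    states, events = dollo_reconstruct(ds.tree, matrix)
    return clusters, matrix, states, events


def truth_event_set(ds, kind):
    """{(branch_child, alignment_column, phase)} for planted gains/losses."""
    col_of = {
        (c["column_id"], c["phase"]): c["column"]
        for c in ds.truth.characters
    }
    rec = ds.truth.gains if kind == "gain" else ds.truth.losses
    return {
        (child, col_of[(e["column_id"], e["phase"])], e["phase"])
        for child, evs in rec.items()
        for e in evs
        if (e["column_id"], e["phase"]) in col_of
    }


def inferred_gain_set(clusters, events):
    key_of = {c.character_id: c.key for c in clusters}
    return {
        (child, key_of[ch][0], key_of[ch][1])
        for child, chars in events.gains.items()
        for ch in chars
    }


class TestSimulate:
    def test_deterministic_under_fixed_seed(self, tmp_path):
        cfg = SimConfig(tree=default_tree(8), seed=42, loss_rate=0.1)
        a = simulate(cfg, out_dir=tmp_path / "a")
        b = simulate(cfg, out_dir=tmp_path / "b")
        assert a.contigs == b.contigs
        assert a.alignment == b.alignment
        assert (tmp_path / "a" / "truth.json").read_text() == (
            tmp_path / "b" / "truth.json"
        ).read_text()

    def test_no_events_means_shared_root_structure(self):
        cfg = SimConfig(
            tree=default_tree(4), gain_rate=0.0, loss_rate=0.0,
            root_introns=((50, 1),), seed=1,
        )
        ds = simulate(cfg)
        counts = {g.gene_id: g.exon_count for g in ds.structures}
        assert set(counts.values()) == {2}
        _, _, _, events = run_pipeline(ds)
        # the shared ancestral intron is one root-branch gain, no losses
        assert events.n_gains == 1 and events.n_losses == 0
        assert events.gain_branch(events.as_records()[0][1]) == ds.tree.root_label

    def test_truth_replay_reproduces_leaf_introns(self):
        cfg = SimConfig(tree=default_tree(8), seed=7, loss_rate=0.15)
        ds = simulate(cfg)
        # replay planted events root->leaf and compare with leaf structures
        for g in ds.structures:
            leaf = g.gene_id
            node = ds.tree.node(leaf)
            path = []
            while node is not None:
                path.append(ds.tree.label_of(node))
                node = node.parent_node
            present: set[tuple[int, int]] = set(
                (c, p) for c, p in ds.config.root_introns
            )
            for label in reversed(path):
                for e in ds.truth.gains.get(label, []):
                    present.add((e["column_id"], e["phase"]))
                for e in ds.truth.losses.get(label, []):
                    present.discard((e["column_id"], e["phase"]))
            assert g.exon_count == len(present) + 1

    def test_gtag_written_at_every_intron(self):
        cfg = SimConfig(tree=default_tree(4), seed=3, gain_rate=1.0)
        ds = simulate(cfg)
        for g in ds.structures:
            for report in validate_splice_sites(g, ds.contigs[g.contig_id]):
                assert report == {"starts_gt": True, "ends_ag": True}

    def test_end_to_end_recovery_without_losses(self):
        cfg = SimConfig(tree=default_tree(8), seed=11)
        ds = simulate(cfg)
        clusters, matrix, _, events = run_pipeline(ds)
        assert len(clusters) == len(ds.truth.characters)
        assert inferred_gain_set(clusters, events) == truth_event_set(ds, "gain")
        assert events.n_losses == 0

    def test_recovery_with_losses(self):
        # a seeded draw in which no loss erases a just-gained singleton
        cfg = SimConfig(tree=default_tree(8), seed=19, loss_rate=0.12)
        ds = simulate(cfg)
        clusters, matrix, _, events = run_pipeline(ds)
        surviving = {
            (c["column_id"], c["phase"]) for c in ds.truth.characters
        }
        planted = sum(
            1 for evs in ds.truth.gains.values() for e in evs
            if (e["column_id"], e["phase"]) in surviving
        ) + sum(
            1 for evs in ds.truth.losses.values() for e in evs
            if (e["column_id"], e["phase"]) in surviving
        )
        assert events.total_events == planted

    def test_indel_mode_tracks_true_alignment(self):
        cfg = SimConfig(
            tree=default_tree(8), seed=23, indels=True, indel_rate=0.3,
        )
        ds = simulate(cfg)
        lengths = {len(r) for r in ds.alignment.values()}
        assert len(lengths) == 1
        ungapped = {k: v.replace("-", "") for k, v in ds.alignment.items()}
        assert ungapped == ds.proteins
        # projection still collapses shared introns to single columns
        clusters, matrix, _, events = run_pipeline(ds)
        assert len(clusters) == len(ds.truth.characters)
        assert inferred_gain_set(clusters, events) == truth_event_set(ds, "gain")

    def test_invalid_config_rejected(self):
        with pytest.raises(GenerationError, match="50 codons"):
            SimConfig(tree=default_tree(4), cds_codons=10)
        with pytest.raises(GenerationError, match="non-negative"):
            SimConfig(tree=default_tree(4), gain_rate=-1)


class TestMakeTeIntron:
    def test_default_construct_recovered_by_detectors(self):
        from intronevo.te import detect_tir

        f5, intron, f3, truth = make_te_intron(seed=2)
        assert intron.startswith("gt") and intron.endswith("ag")
        tsd = detect_tsd(f5, intron, f3)
        assert tsd[0].length == truth["tsd_len"] == 4
        tir = detect_tir(intron)
        assert tir is not None and tir.arm_length >= 12
        assert tandem_period(intron).unit_length == 37

    def test_disabled_tsd_leaves_no_planted_pair(self):
        params = TeIntronParams(tsd_len=0)
        f5, intron, f3, truth = make_te_intron(params, seed=5)
        assert truth["tsd_seq"] == ""
        cands = detect_tsd(f5, intron, f3)
        assert all(c.length < 4 for c in cands)

    def test_single_copy_array_has_no_period(self):
        params = TeIntronParams(tandem_copies=1)
        _, intron, _, _ = make_te_intron(params, seed=6)
        rep = tandem_period(intron)
        assert rep is None

    def test_truth_annotation_matches_sequence(self):
        _, intron, _, truth = make_te_intron(seed=8)
        lo, hi = truth["tir_left_span"]
        assert intron[lo:lo + 3] == "tgt"
        rlo, rhi = truth["tir_right_span"]
        assert intron[rhi - 3:rhi] == "aca"
        alo, ahi = truth["tandem_span"]
        assert ahi - alo == 37 * 4


class TestPaperFixture:
    def test_lineage_intron_counts(self, fixture):
        a1 = fixture["matrices"]["slc26a1"].df
        a2 = fixture["matrices"]["slc26a2"].df
        # Eurypterygii-wide structures: 6 slc26a1 introns -> 7 exons
        assert a1.loc["Eurypterygii_core"].sum() == 6
        # seahorse/seadragon/pipefish clade: 2 slc26a2 introns -> 3 exons
        assert a2.loc["Syngnathid_clade"].sum() == 2
        # outgroups carry exactly the one ancient intron in each paralog
        for taxon in ("Cartilaginous", "Lobe_finned", "Tetrapod"):
            assert a1.loc[taxon].sum() == 1
            assert a2.loc[taxon].sum() == 1
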