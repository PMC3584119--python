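"""Generator tests: determinism, truth round-trips and internal consistency
of the simulated bundles with their own ground-truth tables."""

import numpy as np
import pandas as pd
import pytest

from mitosig import geneorder as go, synthgen
from mitosig.mitoannot import revcomp
from mitosig.models import hky_at_rich
from mitosig.trees import Tree

START_SET = {"ATA", "ATT", "ATC", "ATG", "GTG", "TTG", "GTT"}
ANTICODON_OFFSET = (go.TRNA_GEOMETRY["acceptor"] + go.TRNA_GEOMETRY["linker1"]
                    + 2 * go.TRNA_GEOMETRY["d_stem"]
                    + go.TRNA_GEOMETRY["dhu_loop"]
                    + go.TRNA_GEOMETRY["linker2"]
                    + go.TRNA_GEOMETRY["ac_stem"] + 2)


def coding(truth, row):
    seq = truth.segments[row["taxon"]][row["segment"]]
    sub = seq[row["start"]:row["end"]]
    return sub if row["strand"] == "+" else revcomp(sub)


def test_simulation_is_deterministic():
    a = synthgen.simulate(seed=7)
    b = synthgen.simulate(seed=7)
    assert a.segments == b.segments
    pd.testing.assert_frame_equal(a.features, b.features)
    pd.testing.assert_frame_equal(a.spacers, b.spacers)
    assert a.tree.newick() == b.tree.newick()


def test_different_seeds_differ():
    a = synthgen.simulate(seed=1)
    b = synthgen.simulate(seed=2)
    assert a.segments != b.segments


def test_truth_round_trip(tmp_path):
    truth = synthgen.simulate(seed=3)
    truth.write(tmp_path / "truth")
    again = synthgen.TruthBundle.read(tmp_path / "truth", truth.config)
    assert again.segments == truth.segments
    pd.testing.assert_frame_equal(
        again.features.reset_index(drop=True),
        truth.features.reset_index(drop=True))
    assert again.tree.newick() == truth.tree.newick()
    assert again.clade_map == truth.clade_map


def test_tree_matches_config(default_run):
    truth = default_run.truth
    cfg = truth.config
    leaves = truth.tree.leaf_names()
    assert len(leaves) == cfg.n_outgroups + cfg.n_ingroup_taxa
    for label, size in zip("ABC", cfg.clade_sizes):
        members = [t for t, c in truth.clade_map.items() if c == label]
        assert len(members) == size
        under = set(truth.tree.leaves_under(f"clade{label}"))
        assert under == set(members)
    outs = [t for t, c in truth.clade_map.items() if c == "outgroup"]
    assert len(outs) == cfg.n_outgroups


def test_pcg_truth_has_legitimate_starts_and_stops(default_run):
    truth = default_run.truth
    stop_of = {(seg, ft.gene): ft.stop for seg in go.SEGMENT_IDS
               for ft in go.SEGMENTS[seg] if ft.type == "PCG"}
    pcgs = truth.features.query("type == 'PCG'")
    assert len(pcgs) == len(stop_of) * len(truth.taxa)
    for _, row in pcgs.iterrows():
        cds = coding(truth, row)
        assert cds[:3] in START_SET
        stop = stop_of[(row["segment"], row["gene"])]
        assert cds.endswith(stop)
        if stop in ("TAA", "TAG"):
            assert len(cds) % 3 == 0
        body = cds[:len(cds) - len(stop)] if stop in ("T", "TA") else cds[:-3]
        # purifying selection in the generator keeps CDSs free of
        # internal stops
        for q in range(3, 3 * (len(body) // 3), 3):
            assert body[q:q + 3] not in ("TAA", "TAG")


def test_trna_truth_carries_frozen_anticodons(default_run):
    truth = default_run.truth
    trnas = truth.features.query("type == 'tRNA'")
    assert set(trnas["gene"]) == set(go.TRNA_ANTICODONS)
    # loop replacement events may change a tRNA's length downstream of the
    # anticodon; compute the expected per-(taxon, gene) adjustment
    loop_len = {"DHU": go.TRNA_GEOMETRY["dhu_loop"],
                "TPC": go.TRNA_GEOMETRY["t_loop"]}
    delta = {}
    for ev in truth.config.loop_events:
        for taxon in truth.tree.leaves_under(ev.branch):
            key = (taxon, ev.trna)
            delta[key] = delta.get(key, 0) + len(ev.motif) - loop_len[ev.loop]
    for _, row in trnas.iterrows():
        seq = coding(truth, row)
        assert len(seq) == go.TRNA_LENGTH + delta.get(
            (row["taxon"], row["gene"]), 0)
        # every replacement loop here is DHU (same length) or TPC (downstream
        # of the anticodon), so the anticodon offset is invariant
        anticodon = seq[ANTICODON_OFFSET:ANTICODON_OFFSET + 3]
        assert anticodon == go.TRNA_ANTICODONS[row["gene"]]


def test_spacer_events_place_carriers_on_the_right_clades(default_run):
    truth = default_run.truth
    tree = truth.tree

    def carriers(locus):
        sub = truth.spacers.query("locus == @locus")
        return set(sub.loc[sub["present"].astype(bool), "taxon"])

    assert carriers("isp^cox1-trnL2") == (
        set(tree.leaves_under("A_1")) | set(tree.leaves_under("B1"))
        | set(tree.leaves_under("C2")))
    # ancestral spacer deleted on the cladeA stem
    assert carriers("isp^atp6-cox3") == \
        set(tree.leaf_names()) - set(tree.leaves_under("cladeA"))
    # ubiquitous root spacer
    assert carriers("isp^trnS2-nad1") == set(tree.leaf_names())
    assert carriers("isp^trnL1-rrnL") == {"OUT3"}


def test_trait_painting_matches_events(default_run):
    truth = default_run.truth
    tree = truth.tree
    col = truth.traits.column("crested_front")
    present = {t for t, s in col.items() if s == "present"}
    assert present == set(tree.leaves_under("cladeBC")) | {"A1"}
    host = truth.traits.column("host_plant_class")
    gym = {t for t, s in host.items() if s == "gymnosperm"}
    assert gym == set(tree.leaves_under("cladeBC"))


def test_config_dict_round_trip():
    cfg = synthgen.default_config(seed=9)
    d = synthgen.config_to_dict(cfg)
    again = synthgen.config_from_dict(d)
    assert again == cfg
    assert synthgen.config_to_dict(again) == d


def test_segments_cover_features_exactly(default_run):
    truth = default_run.truth
    for taxon in truth.taxa:
        for seg_id, seq in truth.segments[taxon].items():
            feats = truth.features.query(
                "taxon == @taxon and segment == @seg_id")
            spacers = truth.spacers.query(
                "taxon == @taxon and segment == @seg_id")
            total = int((feats["end"] - feats["start"]).sum()
                        + spacers["sequence"].str.len().sum())
            assert total == len(seq)
            # features appear in template order without overlap
            ordered = feats.sort_values("start")
            assert list(ordered["gene"]) == \
                [ft.gene for ft in go.SEGMENTS[seg_id]]
            assert (ordered["start"].values[1:]
                    >= ordered["end"].values[:-1]).all()


def test_simulate_alignment_deterministic_and_shaped():
    tree = Tree.from_newick("((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05);")
    model = hky_at_rich()
    aln1 = synthgen.simulate_alignment(tree, model, 300, seed=4)
    aln2 = synthgen.simulate_alignment(tree, model, 300, seed=4)
    assert aln1 == aln2
    assert set(aln1) == {"a", "b", "c", "d"}
    assert all(len(s) == 300 for s in aln1.values())
    assert set("".join(aln1.values())) <= set("ACGT")


def test_base_composition_tracks_model_frequencies():
    tree = Tree.from_newick("(a:0.2,b:0.2);")
    model = hky_at_rich()
    aln = synthgen.simulate_alignment(tree, model, 20000, seed=0)
    seq = "".join(aln.values())
    freq_at = (seq.count("A") + seq.count("T")) / len(seq)
    assert freq_at == pytest.approx(0.8, abs=0.02)


def test_config_validation():
    with pytest.raises(ValueError):
        synthgen.SimulationConfig(n_outgroups=0)
    with pytest.raises(ValueError):
        synthgen.SimulationConfig(clade_sizes=(3, 0))
    with pytest.raises(ValueError):
        synthgen.SpacerEvent("isp^a-b", "x", "duplicate")
    with pytest.raises(ValueError):
        synthgen.LoopEvent("trnD", "ACC", "x", "AAA")
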