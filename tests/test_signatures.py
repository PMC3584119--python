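"""Signature tests: IUPAC consensus, spacer grouping, presence-pattern
classification and diagnostic loop motifs."""

import pandas as pd
import pytest

from mitosig.signatures import (classify_pattern, diagnostic_motifs,
                                group_spacers, iupac_consensus, matches_iupac)
from mitosig.trees import Tree

TREE = Tree.from_newick(
    "(out:0.2,((a1:0.1,a2:0.1)cladeA:0.1,"
    "(b1:0.1,b2:0.1)cladeB:0.1)ingroup:0.1)root;")


def test_iupac_consensus_minimal_degeneracy():
    assert iupac_consensus(["ACGT"]) == ("ACGT", 0)
    motif, deg = iupac_consensus(["ACGT", "ACGA"])
    assert motif == "ACGW" and deg == 1
    motif, deg = iupac_consensus(["AG", "AA", "AC", "AT"])
    assert motif == "AN" and deg == 1
    motif, deg = iupac_consensus(["AG", "AA"])
    assert motif == "AR" and deg == 1
    assert iupac_consensus(["ACG", "AC"]) is None


def test_matches_iupac():
    assert matches_iupac("ACGA", "ACGW")
    assert not matches_iupac("ACGC", "ACGW")
    assert not matches_iupac("ACG", "ACGW")
    assert matches_iupac("acgt", "NNNN")


def _spacer_frame(rows):
    return pd.DataFrame(rows, columns=["locus", "taxon", "present",
                                       "sequence"])


def test_group_spacers_consensus_and_identity_gate():
    df = _spacer_frame([
        ("isp^x-y", "a1", True, "ACGTA"),
        ("isp^x-y", "a2", True, "ACGTT"),
        ("isp^x-y", "b1", False, ""),
        ("isp^x-y", "b2", False, ""),
        ("isp^u-v", "a1", True, "AAAA"),
        ("isp^u-v", "a2", True, "TTTT"),
        ("isp^u-v", "b1", False, ""),
        ("isp^u-v", "b2", False, ""),
        ("isp^m-n", "a1", False, ""),
        ("isp^m-n", "a2", False, ""),
        ("isp^m-n", "b1", False, ""),
        ("isp^m-n", "b2", False, ""),
    ])
    groups = {g.locus: g for g in group_spacers(df)}
    # loci with no carrier are dropped
    assert set(groups) == {"isp^x-y", "isp^u-v"}
    assert groups["isp^x-y"].present == ["a1", "a2"]
    assert groups["isp^x-y"].shared_motif == "ACGTN"
    assert groups["isp^x-y"].mean_identity == pytest.approx(0.8)
    # identity 0.0 is below the 0.6 threshold: no motif reported
    assert groups["isp^u-v"].shared_motif is None


def _group(carriers):
    df = _spacer_frame([("isp^x-y", t, t in carriers,
                         "ACGT" if t in carriers else "")
                        for t in TREE.leaf_names()])
    return group_spacers(df)[0]


def test_classify_pattern_ubiquitous():
    p = classify_pattern(TREE, _group(set(TREE.leaf_names())))
    assert p.pattern_class == "ubiquitous"
    assert p.parsimony_length == 0
    assert p.root_state == "present"
    assert p.gains == [] and p.losses == []


def test_classify_pattern_lineage_specific():
    p = classify_pattern(TREE, _group({"b1"}))
    assert p.pattern_class == "lineage_specific"
    assert p.supporting_clade == "b1"
    assert p.gains == ["b1"]
    assert p.parsimony_length == 1


def test_classify_pattern_clade_restricted():
    p = classify_pattern(TREE, _group({"a1", "a2"}))
    assert p.pattern_class == "clade_restricted"
    assert p.supporting_clade == "cladeA"
    assert p.gains == ["cladeA"]
    assert p.root_state == "absent"


def test_classify_pattern_prefers_fewer_origins_dollo():
    # carriers = ingroup minus one leaf: one gain + one loss beats two gains
    p = classify_pattern(TREE, _group({"a1", "a2", "b1"}))
    assert p.pattern_class == "clade_restricted"
    assert p.supporting_clade is None
    origins = len(p.gains) + (1 if p.root_state == "present" else 0)
    assert origins == 1
    assert p.losses == ["b2"]


def test_classify_pattern_rejects_unknown_carriers():
    df = _spacer_frame([("isp^x-y", "nope", True, "ACGT")])
    with pytest.raises(ValueError):
        classify_pattern(TREE, group_spacers(df)[0])


def _loops_frame(seq_of):
    rows = [{"taxon": t, "trna": "trnD", "loop": "DHU", "sequence": s}
            for t, s in seq_of.items()]
    return pd.DataFrame(rows)


CLADES = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "out": "outgroup"}


def test_diagnostic_motifs_found_for_exclusive_clade_loop():
    loops = _loops_frame({"a1": "ATTATAT", "a2": "ATTATAT",
                          "b1": "CCTCCAC", "b2": "CCTCCAC",
                          "out": "GGGGGGG"})
    df = diagnostic_motifs(loops, CLADES)
    assert set(df["clade"]) == {"A", "B"}
    row = df[df["clade"] == "A"].iloc[0]
    assert row["motif"] == "ATTATAT"
    assert row["degenerate_positions"] == 0
    # every reported motif is exclusive by re-matching
    seq_of = dict(zip(loops["taxon"], loops["sequence"]))
    for _, m in df.iterrows():
        members = {t for t, c in CLADES.items() if c == m["clade"]}
        matching = {t for t, s in seq_of.items()
                    if matches_iupac(s, m["motif"])}
        assert matching == members


def test_diagnostic_motifs_suppressed_when_not_exclusive():
    loops = _loops_frame({"a1": "ATTATAT", "a2": "ATTATAT",
                          "b1": "ATTATAT", "b2": "CCTCCAC",
                          "out": "GGGGGGG"})
    df = diagnostic_motifs(loops, CLADES)
    # clade A's consensus also matches b1: must not be reported
    assert "A" not in set(df["clade"])


def test_diagnostic_motifs_respect_degeneracy_cap():
    loops = _loops_frame({"a1": "AAAAAAA", "a2": "TTTCCCA",
                          "b1": "GGGGGGG", "b2": "GGGGGGG",
                          "out": "CCCCCCC"})
    df = diagnostic_motifs(loops, CLADES, max_degeneracy=2)
    assert "A" not in set(df["clade"])  # six degenerate positions
    assert "B" in set(df["clade"])
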