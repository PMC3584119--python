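"""Annotator tests: PCG start/stop rules, truncated stops, cloverleaf
detection and full-bundle recovery against the simulated truth."""

import numpy as np
import pandas as pd
import pytest

from mitosig import geneorder as go, mitoannot, synthgen

MITO_FREQS = (0.4, 0.1, 0.1, 0.4)


def test_revcomp():
    assert mitoannot.revcomp("ATGC") == "GCAT"
    assert mitoannot.revcomp(mitoannot.revcomp("ATTAAAGGC")) == "ATTAAAGGC"


# -- PCG rules ----------------------------------------------------------------

BODY = "ATG" + "AAA" * 9  # 30 nt ORF without internal stops


def test_pcg_start_is_first_legitimate_start_with_long_orf():
    # the earlier GTG opens only a 3-nt ORF and must be skipped
    seq = "GTGTAA" + BODY + "TAG" + "CCCCC"
    start, end, start_codon, stop, trunc, _ = mitoannot.annotate_pcg(
        seq, scan_from=0, expected_len=len(BODY) + 3)
    assert (start, end) == (6, 6 + len(BODY) + 3)
    assert start_codon == "ATG"
    assert stop == "TAG"
    assert trunc is False


def test_pcg_stop_is_first_in_frame_stop():
    seq = BODY + "TAA" + "AAATAG"
    start, end, _, stop, trunc, _ = mitoannot.annotate_pcg(
        seq, scan_from=0, expected_len=len(BODY) + 3)
    assert (start, end) == (0, len(BODY) + 3)
    assert stop == "TAA" and trunc is False


def test_pcg_out_of_frame_stop_is_ignored():
    # TAA spanning codons 1|2 is out of frame and must not terminate the ORF
    seq = "ATG" + "ATA" + "AAA" * 8 + "TAG"
    start, end, _, stop, _, _ = mitoannot.annotate_pcg(
        seq, scan_from=0, expected_len=33)
    assert (start, end) == (0, 33)
    assert stop == "TAG"


@pytest.mark.parametrize("tail,offset", [("T", 1), ("TA", 2)])
def test_pcg_truncated_stop_flush_against_downstream(tail, offset):
    seq = BODY + tail + "GGGGGGGG"
    downstream = len(BODY) + offset
    start, end, _, stop, trunc, notes = mitoannot.annotate_pcg(
        seq, scan_from=0, expected_len=len(BODY) + offset,
        downstream_start=downstream)
    assert trunc is True
    assert stop == tail
    assert end == downstream
    assert "polyA" in notes


def test_pcg_bad_boundary_remainder_raises():
    seq = BODY + "G" + "GGGGGGGG"
    with pytest.raises(ValueError):
        mitoannot.annotate_pcg(seq, scan_from=0, expected_len=len(BODY),
                               downstream_start=len(BODY) + 1)


def test_pcg_requires_min_orf_fraction():
    # the only start opens a 12-nt ORF, far below half of expected_len
    seq = "ATG" + "AAA" * 3 + "TAA" + "C" * 100
    with pytest.raises(ValueError):
        mitoannot.annotate_pcg(seq, scan_from=0, expected_len=300)


# -- cloverleaf folding -------------------------------------------------------

def perfect_trna(gene: str, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    piece = synthgen._new_trna(rng, gene, MITO_FREQS)
    return synthgen._to_str(piece.seq)


def test_find_trnas_recovers_a_perfect_cloverleaf():
    trna = perfect_trna("trnD")
    flank5, flank3 = "CCAACCAACC", "CCAACCAACCAA"
    seq = flank5 + trna + flank3
    hit = mitoannot.find_trnas(seq, go.TRNA_ANTICODONS["trnD"])
    assert hit is not None
    start, end, score, max_pairs, geometry = hit
    assert (start, end) == (len(flank5), len(flank5) + len(trna))
    assert score == pytest.approx(max_pairs)  # all stems perfectly paired
    assert geometry["d_stem"] == go.TRNA_GEOMETRY["d_stem"]
    assert geometry["dhu_loop"] == go.TRNA_GEOMETRY["dhu_loop"]
    assert geometry["t_stem"] == go.TRNA_GEOMETRY["t_stem"]
    assert geometry["t_loop"] == go.TRNA_GEOMETRY["t_loop"]


def test_stem_mutation_lowers_the_fold_score():
    trna = perfect_trna("trnK", seed=3)
    flank = "CCAACCAACC"
    seq = flank + trna + flank
    clean = mitoannot.find_trnas(seq, go.TRNA_ANTICODONS["trnK"])
    # break one acceptor-stem pair (first base of the tRNA)
    broken_base = {"A": "C", "C": "A", "G": "T", "T": "G"}[trna[0]]
    mutated = flank + broken_base + trna[1:] + flank
    hit = mitoannot.find_trnas(mutated, go.TRNA_ANTICODONS["trnK"],
                               threshold=0.5)
    assert hit is not None
    assert hit[2] < clean[2]


def test_expected_anchor_breaks_score_ties():
    trna = perfect_trna("trnH", seed=5)
    # two identical folds; the one nearer the expected anchor must win
    seq = "CCAACC" + trna + "CCAACCAACC" + trna + "CCAACC"
    second_start = 6 + len(trna) + 10
    anchor_offset = 32  # anticodon offset inside the canonical cloverleaf
    hit = mitoannot.find_trnas(
        seq, go.TRNA_ANTICODONS["trnH"],
        expected_anchor=second_start + anchor_offset)
    assert hit[0] == second_start
    hit = mitoannot.find_trnas(seq, go.TRNA_ANTICODONS["trnH"],
                               expected_anchor=6 + anchor_offset)
    assert hit[0] == 6


def test_find_trnas_returns_none_below_threshold():
    assert mitoannot.find_trnas("A" * 200, "GTC") is None


# -- whole-segment / whole-genome annotation ---------------------------------

def test_annotation_covers_every_template_feature(default_run):
    ann = default_run.annotations
    truth = default_run.truth
    for taxon in truth.taxa:
        for seg_id in go.SEGMENT_IDS:
            seg_ann = ann[taxon][seg_id]
            genes = [f.gene for f in seg_ann.features]
            assert genes == [ft.gene for ft in go.SEGMENTS[seg_id]]
            loci = {sp.locus for sp in seg_ann.spacers}
            assert loci == set(go.segment_spacer_loci(seg_id))


def test_zero_length_spacers_are_reported_absent(default_run):
    truth = default_run.truth
    ann = default_run.annotations
    clade_a = set(truth.tree.leaves_under("cladeA"))
    for taxon in truth.taxa:
        sp = {s.locus: s for s in ann[taxon]["cox1_cox3"].spacers}
        spacer = sp["isp^atp6-cox3"]
        assert spacer.present == (taxon not in clade_a)
        if taxon in clade_a:
            assert spacer.length == 0 and spacer.sequence == ""


def test_rrna_and_control_region_boundaries_match_truth(default_run):
    truth = default_run.truth
    feats, _, _ = default_run._need_annotation_tables()
    key = ["taxon", "segment", "gene"]
    t = truth.features[truth.features["type"].isin(
        ["rRNA", "control_region"])]
    a = feats[feats["type"].isin(["rRNA", "control_region"])]
    merged = t.merge(a, on=key, suffixes=("_t", "_a"))
    assert len(merged) == len(t)
    assert (merged["start_t"] == merged["start_a"]).all()
    assert (merged["end_t"] == merged["end_a"]).all()


def test_minus_strand_features_are_reported_on_forward_coordinates(
        default_run):
    truth = default_run.truth
    ann = default_run.annotations
    taxon = truth.taxa[0]
    seg = ann[taxon]["nad5_nad4"]
    nad5 = next(f for f in seg.features if f.gene == "nad5")
    assert nad5.strand == "-"
    assert 0 <= nad5.start < nad5.end <= seg.length
    cds = mitoannot.revcomp(
        truth.segments[taxon]["nad5_nad4"][nad5.start:nad5.end])
    assert cds[:3] == nad5.start_codon


def test_module_invariant_pcg_and_anticodon_recovery(bundle_runs):
    """On default synthetic bundles the annotator recovers >=95% of PCG
    boundaries exactly and matches 100% of tRNA anticodons."""
    runs, metrics = bundle_runs
    n_exact = sum(m["pcg_boundary_recovery_pct"] * m["n_pcg_records"] / 100.0
                  for m in metrics.values())
    n_total = sum(m["n_pcg_records"] for m in metrics.values())
    assert 100.0 * n_exact / n_total >= 95.0
    for seed, run in runs.items():
        assert metrics[seed]["trna_detection_pct"] == 100.0
        for taxon, per_seg in run.annotations.items():
            for seg_ann in per_seg.values():
                for leaf in seg_ann.trnas.values():
                    assert leaf.anticodon == go.TRNA_ANTICODONS[leaf.gene], \
                        f"seed {seed}: {taxon} {leaf.gene}"


def test_gff_output_is_well_formed(default_run):
    truth = default_run.truth
    taxon = truth.taxa[0]
    text = mitoannot.to_gff3(taxon, default_run.annotations[taxon])
    lines = text.strip().splitlines()
    assert lines[0].startswith("##gff-version 3")
    body = [l for l in lines if not l.startswith("#")]
    assert body
    for line in body:
        cols = line.split("\t")
        assert len(cols) == 9
        assert int(cols[3]) >= 1 and int(cols[4]) >= int(cols[3])
        assert cols[6] in "+-"
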