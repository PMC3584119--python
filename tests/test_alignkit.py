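"""Alignment tests: translation, codon-aware alignment, structure-guided
gap placement, concatenation and partition bookkeeping."""

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from mitosig import alignkit
from mitosig.alignkit import (Alignment, PartitionScheme, StructureTrack,
                              codon_align, complete_truncated_stop,
                              concatenate, progressive_align, protein_scorer,
                              read_fasta, structure_align, translate_cds,
                              write_fasta, write_phylip)
from mitosig.pipeline import canonical_trna_track


# -- containers ---------------------------------------------------------------

def test_alignment_validation_and_accessors():
    aln = Alignment(["a", "b"], ["AC-T", "ACGT"])
    assert aln.length == 4 and len(aln) == 2
    assert aln.row("a") == "AC-T"
    assert aln.degapped("a") == "ACT"
    assert aln.subset(["b"]).rows == ["ACGT"]
    assert aln.columns([0, 3]).rows == ["AT", "AT"]
    with pytest.raises(ValueError):
        Alignment(["a", "b"], ["AC", "ACG"])
    with pytest.raises(ValueError):
        Alignment(["a", "a"], ["AC", "AC"])


def test_partition_scheme_validate_and_raxml():
    scheme = PartitionScheme("s", [("g1_p1", [(0, 6, 3)]),
                                   ("g1_p2", [(1, 6, 3)]),
                                   ("g1_p3", [(2, 6, 3)]),
                                   ("g2", [(6, 10, 1)])], 10)
    scheme.validate()
    assert sorted(scheme.block_columns("g1_p2")) == [1, 4]
    text = scheme.to_raxml()
    assert "DNA, g1_p1 = 1-6\\3" in text
    assert "DNA, g2 = 7-10" in text
    bad = PartitionScheme("s", [("g", [(0, 4, 1)])], 10)
    with pytest.raises(ValueError):
        bad.validate()


def test_structure_track_requires_symmetric_pairing():
    StructureTrack(["stem", "stem"], [1, 0])
    with pytest.raises(ValueError):
        StructureTrack(["stem", "stem", "loop"], [1, 2, -1])


# -- translation and codon alignment -----------------------------------------

def test_complete_truncated_stop_pads_to_taa():
    assert complete_truncated_stop("ATGAAAT") == "ATGAAATAA"
    assert complete_truncated_stop("ATGAAATA") == "ATGAAATAA"
    assert complete_truncated_stop("ATGAAATAA") == "ATGAAATAA"


def test_translate_cds_mito_code():
    # invertebrate mito code: TGA=Trp, AGA=Ser; first residue forced to Met
    nt, aa = translate_cds("ATTTGAAGAAAATAA")
    assert aa == "MWSK"
    assert nt == "ATTTGAAGAAAA"
    with pytest.raises(ValueError):
        translate_cds("ATGTAAAAATAA")


def test_codon_align_backtranslates_protein_gaps():
    a = "ATGAAATGTCGATAA"          # M K C R *
    b = "ATGTGCCGTTAA"             # M C R *
    aln = codon_align({"a": a, "b": b})
    assert aln.length % 3 == 0
    assert aln.degapped("a") == a[:-3]
    assert aln.degapped("b") == b[:-3]
    for row in aln.rows:
        for run_start, run_stop in _gap_runs(row):
            assert (run_stop - run_start) % 3 == 0
            assert run_start % 3 == 0
    prot = aln.protein
    assert prot.row("a").replace("-", "") == "MKCR"
    assert prot.row("b").replace("-", "") == "MCR"
    # each protein column maps to one intact codon column triple
    for name in ("a", "b"):
        for k, ch in enumerate(prot.row(name)):
            codon = aln.row(name)[3 * k:3 * k + 3]
            assert (codon == "---") == (ch == "-")


def _gap_runs(row):
    runs, i = [], 0
    while i < len(row):
        if row[i] == "-":
            j = i
            while j < len(row) and row[j] == "-":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _pair_score(row_a, row_b, matrix, go_, ge_):
    score = 0.0
    for run in _gap_runs(row_a) + _gap_runs(row_b):
        score -= go_ + ge_ * (run[1] - run[0] - 1)
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            score += matrix[x, y]
    return score


def test_pairwise_protein_alignment_matches_biopython_optimum():
    blosum = substitution_matrices.load("BLOSUM62")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = blosum
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    rng = np.random.default_rng(2)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    scorer = protein_scorer()
    for _ in range(15):
        a = "".join(rng.choice(list(alphabet), size=rng.integers(10, 40)))
        b = "".join(rng.choice(list(alphabet), size=rng.integers(10, 40)))
        aln = progressive_align(["a", "b"], [a, b], scorer, role="protein")
        ours = _pair_score(aln.row("a"), aln.row("b"), blosum, 10.0, 0.5)
        assert ours == pytest.approx(aligner.score(a, b))


# -- structure-guided alignment -----------------------------------------------

def test_structure_align_slides_gaps_out_of_stems():
    track = canonical_trna_track()
    assert len(track) == 70
    # template plus a copy with one loop nucleotide deleted: the single gap
    # must end up in a loop column, not a stem column
    from mitosig import synthgen
    rng = np.random.default_rng(6)
    template = synthgen._to_str(
        synthgen._new_trna(rng, "trnD", (0.4, 0.1, 0.1, 0.4)).seq)
    dhu_start = 7 + 2 + 4
    shorter = template[:dhu_start + 3] + template[dhu_start + 4:]
    aln = structure_align({"tmpl": template, "short": shorter}, track,
                          template_taxon="tmpl")
    assert aln.degapped("tmpl") == template
    assert aln.degapped("short") == shorter
    assert aln.row("tmpl") == template  # template stays ungapped
    gap_cols = [i for i, ch in enumerate(aln.row("short")) if ch == "-"]
    assert len(gap_cols) == 1
    assert track.annotation[gap_cols[0]] != "stem"


def test_structure_align_rejects_bad_template_length():
    track = canonical_trna_track()
    with pytest.raises(ValueError):
        structure_align({"x": "ACGT"}, track, template_taxon="x")


# -- concatenation ------------------------------------------------------------

def _toy_alignments():
    g1 = Alignment(["a", "b", "c"], ["ATGAAA", "ATGAAG", "ATGAAC"],
                   role="PCG_nt")
    g2 = Alignment(["a", "b", "c"], ["CCTT", "CCTA", "CCAA"], role="rRNA")
    return {"g1": g1, "g2": g2}


def test_concatenate_blocks_and_codon_split():
    aln, scheme = concatenate(_toy_alignments(), "toy", genes=["g1", "g2"],
                              codon_split=True)
    assert aln.length == 10
    assert aln.row("a") == "ATGAAACCTT"
    scheme.validate()
    labels = [lab for lab, _ in scheme.blocks]
    assert labels == ["g1_p1", "g1_p2", "g1_p3", "g2"]
    assert sorted(scheme.block_columns("g1_p2")) == [1, 4]
    assert sorted(scheme.block_columns("g2")) == [6, 7, 8, 9]


def test_concatenate_drops_or_pads_missing_taxa():
    alns = _toy_alignments()
    alns["g2"] = Alignment(["a", "b"], ["CCTT", "CCTA"], role="rRNA")
    dropped, _ = concatenate(alns, "toy", genes=["g1", "g2"],
                             codon_split=False)
    assert dropped.taxa == ["a", "b"]
    padded, _ = concatenate(alns, "toy", genes=["g1", "g2"],
                            codon_split=False, pad_missing=True)
    assert padded.taxa == ["a", "b", "c"]
    assert padded.row("c") == "ATGAAC" + "----"


def test_named_set_exclusions_apply():
    genes = alignkit.NAMED_SETS["nuc3"]["genes"]
    alns = {g: Alignment(["H_cunea", "L_dispar", "T_pityocampa", "O_lunifer"],
                         ["ATGAAA"] * 4, role="PCG_nt") for g in genes}
    aln, scheme = concatenate(alns, "nuc3")
    assert set(aln.taxa) == {"T_pityocampa", "O_lunifer"}
    assert scheme.name == "nuc3"


def test_fasta_and_phylip_round_trip(tmp_path):
    seqs = {"a": "ACGT-", "b": "AC--T"}
    path = tmp_path / "x.fasta"
    write_fasta(seqs, path)
    assert read_fasta(str(path)) == seqs
    aln = Alignment(list(seqs), list(seqs.values()), role="rRNA")
    ppath = tmp_path / "x.phy"
    write_phylip(aln, ppath)
    lines = ppath.read_text().strip().splitlines()
    assert lines[0].split() == ["2", "5"]
    assert len(lines) == 3
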