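"""Multiple alignments for mitogenomic data sets.

Three alignment styles are provided, mirroring common practice for
mitochondrial phylogenomics:

* ``codon_align`` – protein-coding genes are translated (invertebrate
  mitochondrial code), the proteins are aligned progressively, and the
  alignment is back-translated so that every amino-acid column maps onto one
  intact codon triple.  Truncated stop codons are completed to TAA (the
  polyadenylation convention) before translation.
* ``structure_align`` – RNA genes are aligned progressively at the
  nucleotide level and then corrected against a secondary-structure track:
  gaps are moved out of paired (stem) columns whenever an equal-score
  placement in a loop exists.
* ``concatenate`` – named single-gene alignments are joined column-wise into
  the classical concatenated sets (mtpcg, nuc2, nuc3, 7trnas, ...) together
  with a partition scheme (per gene, optionally per codon position).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

__all__ = [
    "Alignment", "PartitionScheme", "StructureTrack",
    "codon_align", "structure_align", "concatenate",
    "read_fasta", "write_fasta", "write_phylip",
    "MT_CODE", "NAMED_SETS",
]

MT_CODE = CodonTable.unambiguous_dna_by_id[5]  # invertebrate mitochondrial
_MT_STOPS = set(MT_CODE.stop_codons)

GAP = "-"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """A taxa x columns character matrix with gaps."""

    taxa: list[str]
    rows: list[str]
    role: str = "PCG_nt"  # PCG_nt | protein | tRNA | rRNA | concatenated

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("rows have unequal lengths")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.taxa, self.rows))

    def degapped(self, taxon: str) -> str:
        return self.row(taxon).replace(GAP, "")

    def subset(self, taxa: list[str]) -> "Alignment":
        return Alignment(list(taxa), [self.row(t) for t in taxa], self.role)

    def columns(self, idx) -> "Alignment":
        idx = np.asarray(idx)
        rows = ["".join(np.array(list(r))[idx]) for r in self.rows]
        return Alignment(list(self.taxa), rows, self.role)


@dataclass
class PartitionScheme:
    """Named disjoint column blocks covering an alignment.

    Each block is ``(label, spans)`` where spans is a list of
    ``(start, stop, step)`` in 0-based half-open coordinates, allowing the
    compact codon-position form (step 3) used by RAxML partition files.
    """

    name: str
    blocks: list[tuple[str, list[tuple[int, int, int]]]]
    n_columns: int

    @property
    def count(self) -> int:
        return len(self.blocks)

    def block_columns(self, label: str) -> np.ndarray:
        for lab, spans in self.blocks:
            if lab == label:
                return np.concatenate(
                    [np.arange(a, b, s) for a, b, s in spans])
        raise KeyError(label)

    def validate(self) -> None:
        cover = np.zeros(self.n_columns, dtype=int)
        for _, spans in self.blocks:
            for a, b, s in spans:
                cover[a:b:s] += 1
        if np.any(cover != 1):
            raise ValueError("blocks do not partition the column set")

    def to_raxml(self) -> str:
        lines = []
        for label, spans in self.blocks:
            parts = []
            for a, b, s in spans:
                if s == 1:
                    parts.append(f"{a + 1}-{b}")
                else:
                    parts.append(f"{a + 1}-{b}\\{s}")
            lines.append(f"DNA, {label} = " + ", ".join(parts))
        return "\n".join(lines) + "\n"


@dataclass
class StructureTrack:
    """Per-position secondary structure annotation of a template sequence.

    ``annotation[i]`` is ``stem``, ``loop`` or ``unpaired``; ``partner[i]``
    is the paired position (or -1).  Pairing must be symmetric.
    """

    annotation: list[str]
    partner: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.partner:
            self.partner = [-1] * len(self.annotation)
        if len(self.partner) != len(self.annotation):
            raise ValueError("annotation/partner length mismatch")
        for i, j in enumerate(self.partner):
            if j >= 0 and self.partner[j] != i:
                raise ValueError("pairing is not symmetric")

    def __len__(self) -> int:
        return len(self.annotation)


# ---------------------------------------------------------------------------
# FASTA / PHYLIP plumbing
# ---------------------------------------------------------------------------

def read_fasta(path_or_handle) -> dict[str, str]:
    from Bio import SeqIO
    handle = path_or_handle
    if isinstance(path_or_handle, (str,)):
        handle = open(path_or_handle)
    try:
        return {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(handle, "fasta")}
    finally:
        if handle is not path_or_handle:
            handle.close()


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_phylip(aln: Alignment, path) -> None:
    """Relaxed PHYLIP (names padded, single block)."""
    width = max(len(t) for t in aln.taxa) + 2
    with open(path, "w") as fh:
        fh.write(f" {len(aln)} {aln.length}\n")
        for taxon, row in zip(aln.taxa, aln.rows):
            fh.write(taxon.ljust(width) + row + "\n")


def alignment_from_fasta(path, role="PCG_nt") -> Alignment:
    d = read_fasta(path)
    return Alignment(list(d), list(d.values()), role)


# ---------------------------------------------------------------------------
# profile-profile global alignment (affine gaps, wavefront DP)
# ---------------------------------------------------------------------------

class _Scorer:
    """Alphabet encoding plus substitution scores for profile columns."""

    def __init__(self, alphabet: str, matrix: np.ndarray,
                 gap_open: float, gap_extend: float):
        self.alphabet = alphabet
        self.index = {ch: i for i, ch in enumerate(alphabet)}
        self.matrix = matrix
        self.gap_open = gap_open
        self.gap_extend = gap_extend

    def profile(self, rows: list[str]) -> np.ndarray:
        """Column frequency matrix (columns x alphabet); gaps weigh nothing."""
        n = len(self.alphabet)
        L = len(rows[0])
        prof = np.zeros((L, n))
        for row in rows:
            for i, ch in enumerate(row):
                k = self.index.get(ch)
                if k is not None:
                    prof[i, k] += 1.0
        return prof / len(rows)


def _pairwise_profile_align(pa: np.ndarray, pb: np.ndarray,
                            scorer: _Scorer) -> list[tuple[int, int]]:
    """Global affine-gap alignment of two column profiles.

    Returns traceback as (i, j) pairs where -1 marks a gap.  The DP is run
    over anti-diagonals so each step is a vectorized numpy operation.
    """
    go, ge = scorer.gap_open, scorer.gap_extend
    La, Lb = len(pa), len(pb)
    sub = pa @ scorer.matrix @ pb.T  # (La, Lb) expected column score

    NEG = -1e30
    M = np.full((La + 1, Lb + 1), NEG)
    X = np.full((La + 1, Lb + 1), NEG)  # gap in B (consumes A)
    Y = np.full((La + 1, Lb + 1), NEG)  # gap in A (consumes B)
    ptrM = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    ptrX = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    ptrY = np.zeros((La + 1, Lb + 1), dtype=np.int8)

    M[0, 0] = 0.0
    if La:
        X[1:, 0] = -go - ge * np.arange(La)
        ptrX[2:, 0] = 1
    if Lb:
        Y[0, 1:] = -go - ge * np.arange(Lb)
        ptrY[0, 2:] = 1

    for d in range(2, La + Lb + 1):
        # interior cells of this anti-diagonal (boundary rows/cols preset)
        i0 = max(1, d - Lb)
        i1 = min(La, d - 1)
        if i0 > i1:
            continue
        iv = np.arange(i0, i1 + 1)
        jv = d - iv

        # X: gap in B, from (i-1, j)
        fromM = M[iv - 1, jv] - go
        fromX = X[iv - 1, jv] - ge
        takeX = fromX > fromM
        X[iv, jv] = np.where(takeX, fromX, fromM)
        ptrX[iv, jv] = takeX.astype(np.int8)

        # Y: gap in A, from (i, j-1)
        fromM = M[iv, jv - 1] - go
        fromY = Y[iv, jv - 1] - ge
        takeY = fromY > fromM
        Y[iv, jv] = np.where(takeY, fromY, fromM)
        ptrY[iv, jv] = takeY.astype(np.int8)

        # M: match, from (i-1, j-1); ties prefer M (keeps alignments compact)
        mm = M[iv - 1, jv - 1]
        xx = X[iv - 1, jv - 1]
        yy = Y[iv - 1, jv - 1]
        stacked = np.stack([mm, xx, yy])
        best = stacked.argmax(axis=0)
        M[iv, jv] = stacked[best, np.arange(len(iv))] + sub[iv - 1, jv - 1]
        ptrM[iv, jv] = best.astype(np.int8)

    # traceback
    i, j = La, Lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    pairs: list[tuple[int, int]] = []
    while i > 0 or j > 0:
        if state == 0:
            pairs.append((i - 1, j - 1))
            state = int(ptrM[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            pairs.append((i - 1, -1))
            state = 1 if ptrX[i, j] else 0
            i -= 1
        else:
            pairs.append((-1, j - 1))
            state = 2 if ptrY[i, j] else 0
            j = j - 1
        if state == 1 and i == 0 and j > 0:
            state = 2
        if state == 2 and j == 0 and i > 0:
            state = 1
    pairs.reverse()
    return pairs


def _merge(rows_a: list[str], rows_b: list[str],
           pairs: list[tuple[int, int]]) -> tuple[list[str], list[str]]:
    out_a = ["".join(r[i] if i >= 0 else GAP for i, _ in pairs)
             for r in rows_a]
    out_b = ["".join(r[j] if j >= 0 else GAP for _, j in pairs)
             for r in rows_b]
    return out_a, out_b


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    sa = {a[i:i + k] for i in range(max(1, len(a) - k + 1))}
    sb = {b[i:i + k] for i in range(max(1, len(b) - k + 1))}
    if not sa or not sb:
        return 1.0
    return 1.0 - len(sa & sb) / min(len(sa), len(sb))


def _guide_order(seqs: list[str]) -> list[tuple[int, int]]:
    """Merge schedule (pairs of cluster ids) from average-linkage k-mer tree."""
    n = len(seqs)
    if n == 1:
        return []
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _kmer_distance(seqs[i], seqs[j])
    link = average(squareform(dm, checks=False))
    return [(int(a), int(b)) for a, b, _, _ in link]


def progressive_align(names: list[str], seqs: list[str],
                      scorer: _Scorer, role: str) -> Alignment:
    """Progressive MSA: k-mer guide tree, profile-profile merges."""
    if not seqs:
        raise ValueError("no sequences to align")
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [s]) for i, s in enumerate(seqs)}
    nxt = len(seqs)
    for a, b in _guide_order(seqs):
        ia, rows_a = clusters.pop(a)
        ib, rows_b = clusters.pop(b)
        pa = scorer.profile(rows_a)
        pb = scorer.profile(rows_b)
        pairs = _pairwise_profile_align(pa, pb, scorer)
        rows_a, rows_b = _merge(rows_a, rows_b, pairs)
        clusters[nxt] = (ia + ib, rows_a + rows_b)
        nxt += 1
    order, rows = next(iter(clusters.values()))
    # restore input order
    aligned = [None] * len(seqs)
    for idx, row in zip(order, rows):
        aligned[idx] = row
    return Alignment(list(names), aligned, role)


def protein_scorer(gap_open: float = 10.0, gap_extend: float = 0.5,
                   matrix_name: str = "BLOSUM62") -> _Scorer:
    blosum = substitution_matrices.load(matrix_name)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    mat = np.zeros((20, 20))
    for i, x in enumerate(alphabet):
        for j, y in enumerate(alphabet):
            mat[i, j] = blosum[x, y]
    return _Scorer(alphabet, mat, gap_open, gap_extend)


def nucleotide_scorer(match: float = 5.0, mismatch: float = -4.0,
                      gap_open: float = 10.0, gap_extend: float = 0.5) -> _Scorer:
    mat = np.full((4, 4), mismatch)
    np.fill_diagonal(mat, match)
    return _Scorer("ACGT", mat, gap_open, gap_extend)


# ---------------------------------------------------------------------------
# codon-aware alignment
# ---------------------------------------------------------------------------

def complete_truncated_stop(cds: str) -> str:
    """Pad a 3'-truncated CDS with A's (polyadenylation completes TAA)."""
    cds = cds.upper()
    remainder = len(cds) % 3
    if remainder:
        cds += "A" * (3 - remainder)
    return cds


def translate_cds(cds: str, name: str = "") -> tuple[str, str]:
    """Return (codon string, protein) with the terminal stop removed.

    Raises ``ValueError`` on internal stop codons.  Any legitimate start is
    read as formyl-Met, so the first residue is forced to M.
    """
    cds = complete_truncated_stop(cds)
    if cds[-3:] in _MT_STOPS:
        cds = cds[:-3]
    protein = str(Seq(cds).translate(table=5))
    if "*" in protein:
        raise ValueError(f"internal stop codon in {name or 'CDS'}")
    if protein:
        protein = "M" + protein[1:]
    return cds, protein


def codon_align(orthologs: dict[str, str],
                gap_open: float = 10.0, gap_extend: float = 0.5,
                matrix_name: str = "BLOSUM62") -> Alignment:
    """Codon-aware alignment through a translated protein backbone.

    Each CDS is translated (invertebrate mitochondrial code), the proteins
    are aligned progressively, and the protein alignment is back-translated
    so that every amino-acid column corresponds to one intact codon column
    triple.  The returned nucleotide alignment carries the protein alignment
    as the ``protein`` attribute.
    """
    names = list(orthologs)
    codons, proteins = [], []
    for name in names:
        nt, aa = translate_cds(orthologs[name], name)
        codons.append(nt)
        proteins.append(aa)
    scorer = protein_scorer(gap_open, gap_extend, matrix_name)
    paln = progressive_align(names, proteins, scorer, role="protein")
    nt_rows = []
    for name, nt in zip(names, codons):
        row = paln.row(name)
        triplets, k = [], 0
        for ch in row:
            if ch == GAP:
                triplets.append("---")
            else:
                triplets.append(nt[3 * k:3 * k + 3])
                k += 1
        nt_rows.append("".join(triplets))
    aln = Alignment(names, nt_rows, role="PCG_nt")
    aln.protein = paln
    return aln


# ---------------------------------------------------------------------------
# structure-guided RNA alignment
# ---------------------------------------------------------------------------

def _sp_column_score(aln_rows: list[str], cols: range,
                     scorer: _Scorer) -> float:
    total = 0.0
    for c in cols:
        column = [r[c] for r in aln_rows]
        for i in range(len(column)):
            ki = scorer.index.get(column[i])
            if ki is None:
                continue
            for j in range(i + 1, len(column)):
                kj = scorer.index.get(column[j])
                if kj is not None:
                    total += scorer.matrix[ki, kj]
    return total


def _column_annotation(template_row: str, track: StructureTrack) -> list[str]:
    """Project the per-position track of the template onto alignment columns."""
    ann = []
    k = 0
    for ch in template_row:
        if ch == GAP:
            ann.append("unpaired")
        else:
            ann.append(track.annotation[k])
            k += 1
    if k != len(track):
        raise ValueError("structure track does not match template length")
    return ann


def structure_align(rna_orthologs: dict[str, str], template: StructureTrack,
                    template_taxon: str | None = None,
                    scorer: _Scorer | None = None) -> Alignment:
    """Progressive nucleotide alignment with stem-aware gap correction.

    The template track describes the secondary structure of one input
    sequence (by default the first).  After the progressive alignment, each
    gap run is slid to an equal-score placement that minimizes the number of
    gaps sitting in stem (paired) columns; loop columns absorb length
    variation.  The correction is deterministic: rows in input order, runs
    left to right, smallest shift first.
    """
    scorer = scorer or nucleotide_scorer()
    names = list(rna_orthologs)
    template_taxon = template_taxon or names[0]
    if len(rna_orthologs[template_taxon]) != len(template):
        raise ValueError("template/track length mismatch")
    aln = progressive_align(names, [rna_orthologs[n] for n in names],
                            scorer, role="tRNA")
    rows = list(aln.rows)
    ann = _column_annotation(aln.row(template_taxon), template)

    def stem_gaps(row: str) -> int:
        return sum(1 for c, ch in enumerate(row)
                   if ch == GAP and ann[c] == "stem")

    for ridx in range(len(rows)):
        if names[ridx] == template_taxon:
            continue
        changed = True
        while changed:
            changed = False
            row = rows[ridx]
            runs = _gap_runs(row)
            for start, stop in runs:
                base_gaps = sum(1 for c in range(start, stop)
                                if ann[c] == "stem")
                if base_gaps == 0:
                    continue
                window = range(max(0, start - len(row)), 0)
                best = None
                ref_score = _sp_column_score(
                    rows, range(len(row)), scorer)
                for k in sorted(range(-(stop - start + 4), stop - start + 5),
                                key=lambda s: (abs(s), s)):
                    if k == 0:
                        continue
                    cand = _slide_run(row, start, stop, k)
                    if cand is None:
                        continue
                    cand_rows = rows[:ridx] + [cand] + rows[ridx + 1:]
                    if abs(_sp_column_score(cand_rows, range(len(row)),
                                            scorer) - ref_score) > 1e-9:
                        continue
                    s, e = start + k, stop + k
                    cand_gaps = sum(1 for c in range(s, e)
                                    if ann[c] == "stem")
                    if cand_gaps < base_gaps:
                        best = cand
                        break
                if best is not None:
                    rows[ridx] = best
                    changed = True
                    break
    return Alignment(names, rows, role=aln.role)


def _gap_runs(row: str) -> list[tuple[int, int]]:
    runs, i = [], 0
    while i < len(row):
        if row[i] == GAP:
            j = i
            while j < len(row) and row[j] == GAP:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _slide_run(row: str, start: int, stop: int, k: int) -> str | None:
    """Move the gap run [start, stop) by k columns; None if out of range."""
    s, e = start + k, stop + k
    if s < 0 or e > len(row):
        return None
    chars = list(row)
    run = chars[start:stop]
    del chars[start:stop]
    chars[s:s] = run
    moved = "".join(chars)
    if moved.replace(GAP, "") != row.replace(GAP, ""):
        return None
    return moved


# ---------------------------------------------------------------------------
# concatenation + partitions
# ---------------------------------------------------------------------------

# gene composition of the study's named concatenations
_PCGS = ["cox1", "cox2", "cox3", "atp8", "atp6", "nad5", "nad4", "cob", "nad1"]
_TRNAS = ["trnL2", "trnK", "trnD", "trnH", "trnS2", "trnL1", "trnV"]
NAMED_SETS: dict[str, dict] = {
    "mtpcg": {"genes": _PCGS, "codon_split": True},
    "nuc2": {"genes": ["EF-1a", "wng"], "codon_split": True},
    "nuc3": {"genes": ["EF-1a", "wng", "pho"], "codon_split": True,
             "exclude_taxa": ["H_cunea", "L_dispar"]},
    "7trnas": {"genes": _TRNAS, "codon_split": False},
    "rrnL+rrnS": {"genes": ["rrnL", "rrnS"], "codon_split": False},
    "rrnL+rrnS+7trnas": {"genes": ["rrnL", "rrnS"] + _TRNAS,
                         "codon_split": False},
    "aag13sp-set": {"genes": _PCGS + ["EF-1a", "wng", "rrnL", "rrnS"] + _TRNAS,
                    "codon_split": False},
    "aag11th-set": {"genes": _PCGS + ["EF-1a", "wng", "pho", "rrnL", "rrnS"]
                    + _TRNAS,
                    "codon_split": False,
                    "exclude_taxa": ["H_cunea", "L_dispar"]},
}


def concatenate(inputs: dict[str, Alignment], set_name: str = "custom",
                genes: list[str] | None = None,
                codon_split: bool | None = None,
                pad_missing: bool = False) -> tuple[Alignment, PartitionScheme]:
    """Column-wise concatenation of named gene alignments.

    ``set_name`` may be one of the preset concatenations (which fixes the
    gene list, the codon-position sub-partitioning and any taxon
    exclusions) or a user-defined label with an explicit ``genes`` list.
    Taxa missing from some block are dropped unless ``pad_missing`` is set,
    in which case their block is filled with gaps.
    """
    preset = NAMED_SETS.get(set_name)
    exclude: list[str] = []
    if preset is not None:
        if genes is None:
            genes = [g for g in preset["genes"] if g in inputs]
        if codon_split is None:
            codon_split = preset["codon_split"]
        exclude = preset.get("exclude_taxa", [])
    if genes is None:
        genes = list(inputs)
    if codon_split is None:
        codon_split = False
    chosen = {g: inputs[g] for g in genes}
    if not chosen:
        raise ValueError("no alignments to concatenate")

    all_taxa: list[str] = []
    for aln in chosen.values():
        for t in aln.taxa:
            if t not in all_taxa:
                all_taxa.append(t)
    all_taxa = [t for t in all_taxa if t not in exclude]
    if pad_missing:
        taxa = all_taxa
    else:
        taxa = [t for t in all_taxa
                if all(t in aln.taxa for aln in chosen.values())]
    if not taxa:
        raise ValueError("no taxon is present in every block")

    rows = {t: [] for t in taxa}
    blocks: list[tuple[str, list[tuple[int, int, int]]]] = []
    offset = 0
    for gene, aln in chosen.items():
        L = aln.length
        for t in taxa:
            rows[t].append(aln.row(t) if t in aln.taxa else GAP * L)
        is_pcg = codon_split and aln.role == "PCG_nt" and L % 3 == 0
        if is_pcg:
            for p in range(3):
                blocks.append((f"{gene}_p{p + 1}",
                               [(offset + p, offset + L, 3)]))
        else:
            blocks.append((gene, [(offset, offset + L, 1)]))
        offset += L

    aln_out = Alignment(taxa, ["".join(rows[t]) for t in taxa],
                        role="concatenated")
    scheme = PartitionScheme(set_name, blocks, offset)
    scheme.validate()
    return aln_out, scheme
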