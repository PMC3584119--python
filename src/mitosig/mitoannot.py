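"""Rule-based annotation of mitochondrial genome segments.

The annotator recovers feature boundaries from sequence alone, guided only
by the expected gene order template (:mod:`mitosig.geneorder`):

* **tRNAs** are found by an anticodon-anchored cloverleaf fold search over a
  small geometry grid (acceptor stem 7 bp, D stem 3-4 bp, anticodon stem
  5 bp, T stem 4-5 bp, loops 3-11 nt).  G.T counts as a pair; a fold is
  accepted when at least 80% of the pairable stem positions pair, and the
  best-scoring fold wins (ties prefer canonical 7-nt loops, then the
  leftmost start).
* **PCG 5' ends** are the legitimate start codon (ATN, GTG, TTG or GTT)
  downstream of the upstream same-strand gene that opens a sufficiently
  long ORF whose reach best matches the expected gene length (ties to the
  earliest candidate).  A per-gene overlap allowance lets a start sit
  inside the upstream gene (the atp8/atp6 arrangement).
* **PCG 3' ends** are the first in-frame stop codon; if no complete stop
  fits before the downstream same-strand feature and the in-frame remainder
  at the boundary is ``T`` or ``TA``, a truncated stop completed by
  polyadenylation is annotated flush against the downstream feature.
* **rRNAs** are delimited by their flanking tRNAs and the expected length:
  rrnL ends against trnV and extends its expected length back toward trnL1
  (any leftover toward trnL1 stays intergenic); rrnS starts against trnV.
* **Spacers** are the leftover gaps between consecutive annotated features,
  recorded even when empty.

Coordinates are 0-based half-open on the stored forward strand; minus-strand
features are analysed on the reverse complement and mapped back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import geneorder as go

__all__ = ["GeneAnnotation", "Cloverleaf", "IntergenicSpacer",
           "SegmentAnnotation", "revcomp", "find_trnas", "annotate_pcg",
           "annotate_segment", "annotate_genome", "features_table",
           "spacers_table", "loops_table", "to_gff3"]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
# Watson-Crick pairs count 1; the weaker G.T wobble pair counts 0.5
_PAIRS = {("A", "T"): 1.0, ("T", "A"): 1.0, ("G", "C"): 1.0,
          ("C", "G"): 1.0, ("G", "T"): 0.5, ("T", "G"): 0.5}
_STOPS = ("TAA", "TAG")
_START_SET = {"ATA", "ATT", "ATC", "ATG", "GTG", "TTG", "GTT"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _paired(a: str, b: str) -> float:
    return _PAIRS.get((a, b), 0.0)


def _stem_pairs(seq: str, start5: int, start3: int, n: int) -> float:
    """Pairing score between arm [start5, start5+n) and its reversed
    partner [start3, start3+n)."""
    return sum(_paired(seq[start5 + i], seq[start3 + n - 1 - i])
               for i in range(n))


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    gene: str
    type: str
    strand: str
    start: int                 # forward strand, 0-based half-open
    end: int
    start_codon: str = ""
    stop_codon: str = ""
    truncated_stop: bool = False
    notes: str = ""


@dataclass
class Cloverleaf:
    gene: str
    strand: str
    start: int                 # forward coordinates of the whole tRNA
    end: int
    anticodon: str
    score: int                 # paired stem positions
    max_pairs: int
    geometry: dict             # d_stem, dhu_loop, t_stem, t_loop lengths
    loops: dict                # loop -> sequence (coding orientation)
    loop_spans: dict           # loop -> (start, end) relative, coding orient.

    def as_annotation(self) -> GeneAnnotation:
        return GeneAnnotation(self.gene, "tRNA", self.strand,
                              self.start, self.end,
                              notes=f"anticodon={self.anticodon};"
                                    f"fold={self.score}/{self.max_pairs}")


@dataclass
class IntergenicSpacer:
    locus: str
    start: int
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def present(self) -> bool:
        return self.length > 0


@dataclass
class SegmentAnnotation:
    segment: str
    length: int
    features: list = field(default_factory=list)      # GeneAnnotation
    trnas: dict = field(default_factory=dict)         # gene -> Cloverleaf
    spacers: list = field(default_factory=list)       # IntergenicSpacer
    notes: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# tRNA cloverleaf search
# ---------------------------------------------------------------------------

# fixed parts of the geometry grid
_ACCEPTOR, _AC_STEM = 7, 5
_LINK1, _LINK2, _VAR = 2, 1, 4
_AC_FLANK = 2                  # loop nucleotides on each side of the anticodon


def _fold_at(seq: str, a: int, d_stem: int, dhu: int,
             t_stem: int, t_loop: int):
    """Score one cloverleaf geometry anchored at anticodon position *a*.

    Returns ``(score, max_pairs, start, end)`` or ``None`` if it does not
    fit in the sequence.
    """
    ac5 = a - _AC_FLANK - _AC_STEM
    d5 = ac5 - _LINK2 - 2 * d_stem - dhu
    start = d5 - _LINK1 - _ACCEPTOR
    ac3 = a + 3 + _AC_FLANK
    t5 = ac3 + _AC_STEM + _VAR
    end = t5 + 2 * t_stem + t_loop + _ACCEPTOR
    if start < 0 or end > len(seq):
        return None
    score = (_stem_pairs(seq, start, end - _ACCEPTOR, _ACCEPTOR)
             + _stem_pairs(seq, d5, d5 + d_stem + dhu, d_stem)
             + _stem_pairs(seq, ac5, ac3, _AC_STEM)
             + _stem_pairs(seq, t5, t5 + t_stem + t_loop, t_stem))
    max_pairs = _ACCEPTOR + d_stem + _AC_STEM + t_stem
    return score, max_pairs, start, end


def find_trnas(seq: str, anticodon: str, lo: int = 0, hi: int | None = None,
               threshold: float = 0.8, expected_anchor: int | None = None):
    """Best cloverleaf fold anchored on *anticodon* within ``[lo, hi)``.

    *seq* must already be in coding orientation.  When *expected_anchor* is
    given (the anticodon position implied by the gene-order template), the
    anchor closest to it wins and score only chooses the geometry at that
    anchor; otherwise the highest-scoring fold wins.  Returns
    ``(start, end, score, max_pairs, geometry)`` or ``None`` when no fold
    reaches the pairing threshold.
    """
    hi = len(seq) if hi is None else min(hi, len(seq))
    lo = max(lo, 0)
    per_anchor: dict[int, tuple] = {}
    a = seq.find(anticodon, lo)
    while 0 <= a < hi:
        for d_stem in (4, 3):
            for dhu in range(3, 12):
                for t_stem in (5, 4):
                    for t_loop in range(3, 12):
                        fold = _fold_at(seq, a, d_stem, dhu, t_stem, t_loop)
                        if fold is None:
                            continue
                        score, max_pairs, start, end = fold
                        if score < threshold * max_pairs:
                            continue
                        # geometry rank at a fixed anchor: score, then
                        # canonical 7-nt loops, then leftmost
                        rank = (-score, abs(dhu - 7) + abs(t_loop - 7),
                                start)
                        geometry = {"d_stem": d_stem, "dhu_loop": dhu,
                                    "t_stem": t_stem, "t_loop": t_loop,
                                    "anchor": a}
                        cand = (rank, start, end, score, max_pairs, geometry)
                        if a not in per_anchor or rank < per_anchor[a][0]:
                            per_anchor[a] = cand
        a = seq.find(anticodon, a + 1)
    if not per_anchor:
        return None
    # anchor choice: the best pairing score wins, but anchors within one
    # pairing unit of the top score are treated as ties and resolved by
    # proximity to the expected anticodon position (gene-order evidence)
    top = max(c[3] for c in per_anchor.values())
    pool = [c for c in per_anchor.values() if c[3] >= top - 1.0]
    if expected_anchor is not None:
        best = min(pool, key=lambda c: (abs(c[5]["anchor"] - expected_anchor),
                                        c[0]))
    else:
        best = min(pool, key=lambda c: c[0])
    _, start, end, score, max_pairs, geometry = best
    return start, end, score, max_pairs, geometry


def _loop_spans(geometry: dict, start: int) -> dict:
    """DHU and TPC loop spans relative to the tRNA start (coding orient.)."""
    d5 = _ACCEPTOR + _LINK1
    dhu_start = d5 + geometry["d_stem"]
    dhu_end = dhu_start + geometry["dhu_loop"]
    t5 = (dhu_end + geometry["d_stem"] + _LINK2 + 2 * _AC_STEM
          + 2 * _AC_FLANK + 3 + _VAR)
    tpc_start = t5 + geometry["t_stem"]
    tpc_end = tpc_start + geometry["t_loop"]
    return {"DHU": (dhu_start, dhu_end), "TPC": (tpc_start, tpc_end)}


# ---------------------------------------------------------------------------
# protein-coding genes
# ---------------------------------------------------------------------------

def annotate_pcg(seq: str, scan_from: int, expected_len: int,
                 downstream_start: int | None = None,
                 scan_span: int = 120, min_orf_frac: float = 0.5
                 ) -> tuple[int, int, str, str, bool, str]:
    """Locate one PCG in coding orientation.

    *seq* is the full (coding-orientation) segment; ``expected_len`` counts
    the stop codon (or the truncated ``T``/``TA`` remainder).  The 5' end is
    the legitimate start codon at or after ``scan_from`` that opens an ORF of
    at least ``min_orf_frac * expected_len`` nucleotides, resolves to a 3'
    end (first in-frame stop, or a truncated stop flush against
    ``downstream_start``) and whose resulting gene span best matches
    ``expected_len`` (ties go to the earliest candidate, so spurious starts
    inside upstream intergenic sequence do not pre-empt the genuine one).

    Returns ``(start, end, start_codon, stop_codon, truncated, notes)``.
    """
    min_len = max(30, int(min_orf_frac * expected_len))
    cap = min(len(seq),
              (downstream_start if downstream_start is not None
               else scan_from + expected_len + scan_span + 3))

    def resolve(p: int):
        """3' resolution for a start at p: (end, stop, truncated) or None."""
        q = p + 3
        while q + 3 <= cap:
            if seq[q:q + 3] in _STOPS:
                return q + 3, seq[q:q + 3], False
            q += 3
        if downstream_start is None:
            return None
        r = (downstream_start - p) % 3
        tail = seq[downstream_start - r:downstream_start]
        if (r, tail) in ((1, "T"), (2, "TA")):
            return downstream_start, tail, True
        return None

    candidates = []
    n_starts = n_short = 0
    bad_tail = None
    for p in range(scan_from, min(scan_from + scan_span, len(seq) - 3)):
        if seq[p:p + 3] not in _START_SET:
            continue
        n_starts += 1
        res = resolve(p)
        if res is None:
            if downstream_start is not None and bad_tail is None:
                r = (downstream_start - p) % 3
                bad_tail = seq[downstream_start - r:downstream_start]
            continue
        end, stop_codon, trunc = res
        if end - p < min_len:
            n_short += 1
            continue
        candidates.append((abs((end - p) - expected_len), p,
                           end, stop_codon, trunc))
    if not candidates:
        if n_starts == 0 or n_short:
            raise ValueError(
                "no legitimate start codon opens a long enough ORF")
        if downstream_start is None:
            raise ValueError("no in-frame stop codon before the scan limit")
        raise ValueError(
            f"no stop codon and boundary remainder {bad_tail!r} is not T/TA")
    _, start, end, stop_codon, trunc = min(candidates)
    notes = [f"stop={stop_codon}(+polyA)"] if trunc else []
    return (start, end, seq[start:start + 3], stop_codon, trunc,
            ";".join(notes))


# ---------------------------------------------------------------------------
# segment driver
# ---------------------------------------------------------------------------

def _coding_view(segment: str, strand: str) -> str:
    return segment if strand == "+" else revcomp(segment)


def _to_forward(length: int, strand: str, start: int, end: int):
    if strand == "+":
        return start, end
    return length - end, length - start


def _expected_positions(feats) -> dict[str, int]:
    pos, out = 0, {}
    for ft in feats:
        out[ft.gene] = pos
        pos += ft.length + (0 if ft.type != "PCG"
                            else len(ft.stop))
    return out


def annotate_segment(segment: str, segment_id: str, slack: int = 60,
                     overlap_allowance: dict[str, int] | None = None
                     ) -> SegmentAnnotation:
    """Annotate one segment against its gene-order template."""
    feats = go.SEGMENTS[segment_id]
    L = len(segment)
    ann = SegmentAnnotation(segment=segment_id, length=L)
    overlap_allowance = overlap_allowance or {}
    expected = _expected_positions(feats)
    located: dict[str, GeneAnnotation] = {}

    # pass 1: tRNA anchors, left to right, tracking positional drift
    drift = 0
    rc = revcomp(segment)
    for ft in feats:
        if ft.type != "tRNA":
            continue
        est_start = expected[ft.gene] + drift
        est_end = est_start + ft.length
        if ft.strand == "+":
            view, lo, hi = segment, est_start - slack, est_end + slack
        else:
            view, lo, hi = rc, L - est_end - slack, L - est_start + slack
        # anticodon position implied by the canonical cloverleaf geometry
        g = go.TRNA_GEOMETRY
        anchor = ((lo + slack) + g["acceptor"] + g["linker1"]
                  + 2 * g["d_stem"] + g["dhu_loop"] + g["linker2"]
                  + g["ac_stem"] + 2)
        hit = find_trnas(view, go.TRNA_ANTICODONS[ft.gene], lo, hi,
                         expected_anchor=anchor)
        if hit is None:
            # keep the best anchored fold even when divergence pushes it
            # below the confident pairing threshold, flagged as weak
            hit = find_trnas(view, go.TRNA_ANTICODONS[ft.gene], lo, hi,
                             threshold=0.0, expected_anchor=anchor)
            if hit is None:
                ann.notes.append(f"{ft.gene}: no anticodon-anchored fold "
                                 f"in window")
                continue
            ann.notes.append(
                f"{ft.gene}: weak cloverleaf fold ({hit[2]}/{hit[3]})")
        c_start, c_end, score, max_pairs, geometry = hit
        f_start, f_end = _to_forward(L, ft.strand, c_start, c_end)
        spans = _loop_spans(geometry, c_start)
        leaf = Cloverleaf(
            gene=ft.gene, strand=ft.strand, start=f_start, end=f_end,
            anticodon=go.TRNA_ANTICODONS[ft.gene], score=score,
            max_pairs=max_pairs, geometry=geometry,
            loops={k: view[c_start + a:c_start + b]
                   for k, (a, b) in spans.items()},
            loop_spans=spans)
        ann.trnas[ft.gene] = leaf
        located[ft.gene] = leaf.as_annotation()
        drift = f_start - expected[ft.gene]

    # pass 2: PCGs, upstream-first per strand
    index = {ft.gene: i for i, ft in enumerate(feats)}

    def coding_neighbor(ft, side: str):
        """Neighbouring template feature on the coding-orientation
        *side* ('up' = 5', 'down' = 3')."""
        step = 1 if (ft.strand == "+") == (side == "down") else -1
        i = index[ft.gene] + step
        return feats[i] if 0 <= i < len(feats) else None

    pcgs = [ft for ft in feats if ft.type == "PCG"]
    ordered = ([ft for ft in pcgs if ft.strand == "+"]
               + [ft for ft in reversed(pcgs) if ft.strand == "-"])
    for ft in ordered:
        view = _coding_view(segment, ft.strand)
        up = coding_neighbor(ft, "up")
        down = coding_neighbor(ft, "down")

        def coding_coord(feature, which: str) -> int | None:
            got = located.get(feature.gene) if feature is not None else None
            if got is None:
                return None
            cs, ce = (got.start, got.end) if ft.strand == "+" else \
                _to_forward(L, "-", got.start, got.end)
            return cs if which == "start" else ce

        scan_from = coding_coord(up, "end") if up is not None else 0
        if scan_from is None:
            scan_from = max(0, expected[ft.gene] + drift - slack)
            if ft.strand == "-":
                scan_from = max(0, L - (expected[ft.gene] + drift
                                        + ft.length + len(ft.stop)) - slack)
        scan_from = max(0, scan_from - overlap_allowance.get(ft.gene, 0))
        down_start = (coding_coord(down, "start")
                      if down is not None and down.strand == ft.strand
                      else None)
        try:
            c_start, c_end, start_codon, stop_codon, trunc, notes = \
                annotate_pcg(view, scan_from,
                             ft.length + len(ft.stop),
                             downstream_start=down_start)
        except ValueError as exc:
            ann.notes.append(f"{ft.gene}: {exc}")
            continue
        f_start, f_end = _to_forward(L, ft.strand, c_start, c_end)
        rec = GeneAnnotation(ft.gene, "PCG", ft.strand, f_start, f_end,
                             start_codon=start_codon, stop_codon=stop_codon,
                             truncated_stop=trunc, notes=notes)
        located[ft.gene] = rec

    # pass 3: rRNAs and the control region from tRNA anchors
    for ft in feats:
        if ft.type == "rRNA":
            i = index[ft.gene]
            left = located.get(feats[i - 1].gene) if i > 0 else None
            right = located.get(feats[i + 1].gene) if i + 1 < len(feats) \
                else None
            if right is not None and right.type == "tRNA":
                end = right.start
                start = end - ft.length
                if left is not None:
                    start = max(start, left.end)
            elif left is not None:
                start = left.end
                end = min(start + ft.length, L)
            else:
                ann.notes.append(f"{ft.gene}: no flanking anchor")
                continue
            located[ft.gene] = GeneAnnotation(ft.gene, "rRNA", ft.strand,
                                              start, end)
        elif ft.type == "control_region":
            i = index[ft.gene]
            left = located.get(feats[i - 1].gene) if i > 0 else None
            start = left.end if left is not None else 0
            located[ft.gene] = GeneAnnotation(ft.gene, "control_region",
                                              ft.strand, start, L)

    ann.features = [located[ft.gene] for ft in feats if ft.gene in located]

    # pass 4: spacers between consecutive annotated features
    for a, b in zip(ann.features, ann.features[1:]):
        locus = go.spacer_locus(a.gene, b.gene)
        if b.start < a.end:
            ann.notes.append(f"{locus}: features overlap by "
                             f"{a.end - b.start} nt")
            continue
        ann.spacers.append(IntergenicSpacer(
            locus, a.end, b.start, segment[a.end:b.start]))
    return ann


def annotate_genome(segments: dict[str, str], slack: int = 60,
                    overlap_allowance: dict[str, int] | None = None
                    ) -> dict[str, SegmentAnnotation]:
    """Annotate every segment of one taxon (segment_id -> sequence)."""
    return {seg_id: annotate_segment(seq, seg_id, slack=slack,
                                     overlap_allowance=overlap_allowance)
            for seg_id, seq in segments.items()}


# ---------------------------------------------------------------------------
# tabular and GFF3 output
# ---------------------------------------------------------------------------

def features_table(annotations: dict[str, dict[str, SegmentAnnotation]]
                   ) -> pd.DataFrame:
    """All features of all taxa (taxon -> segment_id -> annotation)."""
    rows = []
    for taxon, per_seg in annotations.items():
        for seg_id, ann in per_seg.items():
            for f in ann.features:
                rows.append({
                    "taxon": taxon, "segment": seg_id, "gene": f.gene,
                    "type": f.type, "strand": f.strand, "start": f.start,
                    "end": f.end, "start_codon": f.start_codon,
                    "stop_codon": f.stop_codon,
                    "truncated_stop": f.truncated_stop, "notes": f.notes})
    return pd.DataFrame(rows)


def spacers_table(annotations: dict[str, dict[str, SegmentAnnotation]]
                  ) -> pd.DataFrame:
    rows = []
    for taxon, per_seg in annotations.items():
        for seg_id, ann in per_seg.items():
            for sp in ann.spacers:
                rows.append({
                    "taxon": taxon, "segment": seg_id, "locus": sp.locus,
                    "start": sp.start, "end": sp.end,
                    "present": sp.present, "sequence": sp.sequence})
    return pd.DataFrame(rows)


def loops_table(annotations: dict[str, dict[str, SegmentAnnotation]]
                ) -> pd.DataFrame:
    rows = []
    for taxon, per_seg in annotations.items():
        for ann in per_seg.values():
            for leaf in ann.trnas.values():
                for loop, seq in leaf.loops.items():
                    rows.append({"taxon": taxon, "trna": leaf.gene,
                                 "loop": loop, "sequence": seq})
    return pd.DataFrame(rows)


def to_gff3(taxon: str, per_seg: dict[str, SegmentAnnotation]) -> str:
    """Minimal GFF3 (1-based inclusive coordinates, as the format demands)."""
    type_map = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                "control_region": "region"}
    lines = ["##gff-version 3"]
    for seg_id, ann in per_seg.items():
        seqid = f"{taxon}|{seg_id}"
        lines.append(f"##sequence-region {seqid} 1 {ann.length}")
        for f in ann.features:
            attrs = f"ID={f.gene};Name={f.gene}"
            if f.truncated_stop:
                attrs += f";Note=truncated stop {f.stop_codon}"
            lines.append("\t".join([
                seqid, "mitosig", type_map[f.type], str(f.start + 1),
                str(f.end), ".", f.strand, "0" if f.type == "PCG" else ".",
                attrs]))
        for sp in ann.spacers:
            if sp.present:
                lines.append("\t".join([
                    seqid, "mitosig", "sequence_feature", str(sp.start + 1),
                    str(sp.end), ".", "+", ".",
                    f"ID={sp.locus};Name={sp.locus}"]))
    return "\n".join(lines) + "\n"
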