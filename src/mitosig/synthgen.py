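"""Synthetic mitogenome-segment generator with a known ground truth.

Simulates a rooted species tree with labelled ingroup clades and a ladder of
outgroups, evolves the three mitochondrial segments plus three nuclear CDSs
feature by feature under an HKY+gamma model, and applies configured
spacer-insertion/deletion events, tRNA loop replacements and categorical
trait changes on named branches.  The result is a :class:`TruthBundle`
carrying the leaf sequences together with exact feature coordinates, spacer
presence, loop motifs, traits and ancestral states for every node.

Design choices that keep the truth clean and recoverable:

* every feature evolves as its own piece (stored in coding orientation) and
  the segments are concatenated per leaf, so coordinates are exact;
* protein-coding genes stay translatable: start codons and (possibly
  truncated) stop codons are frozen, and any in-frame stop created by a
  substitution is repaired deterministically (first base set to C);
* tRNA anticodons are frozen and structural RNAs evolve at reduced rates,
  mirroring their real conservation;
* spacers inserted by events and replaced loops are frozen from the event
  onward, so signature motifs are shared verbatim by the affected leaves.

All randomness flows from a single ``numpy`` generator seeded by the config,
so outputs are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geneorder as go
from .models import SubstModel
from .trees import Node, Tree
from .traitmap import TraitMatrix

__all__ = ["SpacerEvent", "LoopEvent", "TraitSpec", "SimulationConfig",
           "TruthBundle", "default_config", "simulate_tree",
           "evolve_genomes", "simulate"]

_DECODE = np.array(list("ACGT"))
_ENCODE = {b: i for i, b in enumerate("ACGT")}
_STOPS_MITO = ("TAA", "TAG")
_STOPS_NUCLEAR = ("TAA", "TAG", "TGA")


def _to_str(codes: np.ndarray) -> str:
    return "".join(_DECODE[codes])


def _to_codes(seq: str) -> np.ndarray:
    return np.fromiter((_ENCODE[c] for c in seq.upper()), dtype=np.uint8,
                       count=len(seq))


def _revcomp(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1].astype(np.uint8)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpacerEvent:
    locus: str          # e.g. "isp^cox1-trnL2"
    branch: str         # name of the child node of the branch
    action: str         # "insert" | "delete"
    sequence: str = ""  # inserted sequence (forward strand), verbatim

    def __post_init__(self):
        if self.action not in ("insert", "delete"):
            raise ValueError(f"unknown spacer action {self.action!r}")
        if self.action == "insert" and not self.sequence:
            raise ValueError("insert event needs a sequence")


@dataclass(frozen=True)
class LoopEvent:
    trna: str           # e.g. "trnD"
    loop: str           # "DHU" | "TPC"
    branch: str
    motif: str          # replacement loop, coding orientation, 3-11 nt

    def __post_init__(self):
        if self.loop not in ("DHU", "TPC"):
            raise ValueError(f"unknown loop {self.loop!r}")
        if not 3 <= len(self.motif) <= 11:
            raise ValueError("loop motif must be 3-11 nt")


@dataclass(frozen=True)
class TraitSpec:
    name: str
    states: tuple[str, ...]
    root_state: str
    changes: tuple[tuple[str, str], ...] = ()   # (branch, new state)

    def __post_init__(self):
        if self.root_state not in self.states:
            raise ValueError("root state outside the state space")
        for _, s in self.changes:
            if s not in self.states:
                raise ValueError(f"change to unknown state {s!r}")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_outgroups: int = 3
    clade_sizes: tuple[int, ...] = (3, 3, 4)
    branch_length_range: tuple[float, float] = (0.02, 0.12)
    kappa: float = 4.0
    alpha: float = 0.5
    mito_freqs: tuple[float, float, float, float] = (0.40, 0.10, 0.10, 0.40)
    nuclear_freqs: tuple[float, float, float, float] = (0.30, 0.20, 0.20, 0.30)
    # relative substitution rates per feature class
    rate_scales: dict = field(default_factory=lambda: {
        "PCG": 1.0, "tRNA": 0.15, "rRNA": 0.30, "spacer": 0.30,
        "control_region": 1.5, "nuclear": 0.4})
    root_spacers: dict = field(default_factory=dict)   # locus -> sequence
    spacer_events: tuple[SpacerEvent, ...] = ()
    loop_events: tuple[LoopEvent, ...] = ()
    traits: tuple[TraitSpec, ...] = ()
    include_nuclear: bool = True

    @property
    def n_ingroup_taxa(self) -> int:
        return sum(self.clade_sizes)

    def __post_init__(self):
        if self.n_outgroups < 1:
            raise ValueError("need at least one outgroup")
        if any(s < 1 for s in self.clade_sizes) or not self.clade_sizes:
            raise ValueError("clade sizes must be positive")
        lo, hi = self.branch_length_range
        if not 0 < lo <= hi:
            raise ValueError("invalid branch length range")
        for ev in self.spacer_events:
            left, right = ev.locus[len("isp^"):].split("-", 1)
            if ev.locus != go.spacer_locus(left, right):
                raise ValueError(f"malformed spacer locus {ev.locus!r}")

    def mito_model(self) -> SubstModel:
        return SubstModel(freqs=self.mito_freqs, kappa=self.kappa,
                          alpha=self.alpha)

    def nuclear_model(self) -> SubstModel:
        return SubstModel(freqs=self.nuclear_freqs, kappa=self.kappa,
                          alpha=self.alpha)


def default_config(seed: int = 0) -> SimulationConfig:
    """The default study design: 3+3+4 ingroup clades, three outgroups,
    clade-informative spacer and loop events, and three convergence traits."""
    return SimulationConfig(
        seed=seed,
        root_spacers={
            # ubiquitous conserved spacer ahead of nad1
            go.spacer_locus("trnS2", "nad1"): "TATTAATTTATAAATTAATTTTAA",
            # ancestral spacer, lost on the cladeA stem; C-rich so that no
            # legitimate start codon can pre-empt the cox3 5' end
            go.spacer_locus("atp6", "cox3"): "TCCCTCCTTCCCTCC",
        },
        spacer_events=(
            SpacerEvent(go.spacer_locus("atp6", "cox3"), "cladeA", "delete"),
            SpacerEvent(go.spacer_locus("trnK", "trnD"), "og3", "insert",
                        "ATTTA"),
            SpacerEvent(go.spacer_locus("cox1", "trnL2"), "A_1",
                        "insert", "CTCTTAAGCT"),
            SpacerEvent(go.spacer_locus("cox1", "trnL2"), "B1", "insert",
                        "CT"),
            SpacerEvent(go.spacer_locus("cox1", "trnL2"), "C2", "insert",
                        "GAGCCTA"),
            SpacerEvent(go.spacer_locus("trnL1", "rrnL"), "OUT3", "insert",
                        "TTAATTAA"),
        ),
        loop_events=(
            LoopEvent("trnD", "DHU", "cladeA", "ATTATAT"),
            LoopEvent("trnD", "DHU", "cladeBC", "CCTCCAC"),
            LoopEvent("trnD", "TPC", "cladeC", "TATAATA"),
            LoopEvent("trnH", "TPC", "B1", "ATGAAT"),
            LoopEvent("trnH", "TPC", "B2", "ATAGC"),
        ),
        traits=(
            TraitSpec("crested_front", ("absent", "present"), "absent",
                      (("cladeBC", "present"), ("A1", "present"))),
            TraitSpec("host_plant_class", ("angiosperm", "gymnosperm"),
                      "angiosperm", (("cladeBC", "gymnosperm"),)),
            TraitSpec("foraging_type",
                      ("central_place", "nomadic", "patch_restricted"),
                      "central_place",
                      (("cladeC", "patch_restricted"),
                       ("A3", "patch_restricted"),
                       ("A1", "nomadic"))),
        ),
    )


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

def _clade_subtree(label: str, size: int) -> Node:
    """Ladder topology ((X1,X2),X3)... with named internal nodes."""
    leaves = [Node(f"{label}{i + 1}") for i in range(size)]
    if size == 1:
        return leaves[0]
    cur = Node(f"{label}_1", children=[leaves[0], leaves[1]])
    for i, leaf in enumerate(leaves[2:], start=2):
        name = f"{label}_{i}" if i < size - 1 else f"clade{label}"
        cur = Node(name, children=[cur, leaf])
    if size == 2:
        cur.name = f"clade{label}"
    return cur


def simulate_tree(cfg: SimulationConfig,
                  rng: np.random.Generator | None = None
                  ) -> tuple[Tree, dict[str, str]]:
    """Rooted species tree plus the taxon -> clade assignment.

    Topology is deterministic (ladders) so that configured events can name
    branches; only branch lengths are drawn.  Ingroup clades are labelled
    A, B, C, ... with stem nodes ``cladeA`` etc.; successive outgroups
    attach below the ingroup at nodes ``og2`` ... ``og<n>``, so the branch
    ``og<n>`` subtends the closest outgroup plus the ingroup.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    labels = [chr(ord("A") + i) for i in range(len(cfg.clade_sizes))]
    clades = [_clade_subtree(lab, n)
              for lab, n in zip(labels, cfg.clade_sizes)]
    if len(clades) == 1:
        ingroup = clades[0]
        ingroup.name = "ingroup"
    else:
        cur = clades[-1]
        for i in range(len(clades) - 2, -1, -1):
            name = ("ingroup" if i == 0
                    else "clade" + "".join(labels[i:]))
            cur = Node(name, children=[clades[i], cur])
        ingroup = cur

    cur = ingroup
    for k in range(cfg.n_outgroups, 0, -1):
        name = "root" if k == 1 else f"og{k}"
        cur = Node(name, children=[Node(f"OUT{k}"), cur])
    tree = Tree(cur)

    lo, hi = cfg.branch_length_range
    for node in tree.preorder():
        node.length = 0.0 if node.parent is None else float(rng.uniform(lo, hi))

    clade_map = {}
    for lab, n in zip(labels, cfg.clade_sizes):
        for i in range(n):
            clade_map[f"{lab}{i + 1}"] = lab
    for k in range(1, cfg.n_outgroups + 1):
        clade_map[f"OUT{k}"] = "outgroup"
    return tree, clade_map


# ---------------------------------------------------------------------------
# root genome pieces
# ---------------------------------------------------------------------------

@dataclass
class _Piece:
    """One feature's sequence in coding orientation, with evolution state."""
    seq: np.ndarray                  # uint8 codes
    cats: np.ndarray                 # gamma category per site
    frozen: np.ndarray               # immutable positions
    meta: dict = field(default_factory=dict)

    def copy(self) -> "_Piece":
        return _Piece(self.seq.copy(), self.cats.copy(), self.frozen.copy(),
                      dict(self.meta))


def _random_codes(rng, n: int, freqs) -> np.ndarray:
    cum = np.cumsum(freqs)
    out = np.searchsorted(cum, rng.random(n) * cum[-1], side="right")
    return np.minimum(out, 3).astype(np.uint8)


def _random_cds(rng, body_len: int, freqs, stops) -> np.ndarray:
    """ATG + random non-stop codons, *body_len* nt total (multiple of 3)."""
    if body_len % 3:
        raise ValueError("CDS body length must be a multiple of 3")
    codons = [_to_codes("ATG")]
    for _ in range(body_len // 3 - 1):
        while True:
            codon = _random_codes(rng, 3, freqs)
            if _to_str(codon) not in stops:
                break
        codons.append(codon)
    return np.concatenate(codons)


def _new_pcg(rng, template: go.FeatureTemplate, freqs) -> _Piece:
    body = _random_cds(rng, template.length, freqs, _STOPS_MITO)
    tail = _to_codes(template.stop)
    seq = np.concatenate([body, tail])
    frozen = np.zeros(len(seq), dtype=bool)
    frozen[:3] = True                      # start codon
    frozen[len(body):] = True              # (possibly truncated) stop
    cats = rng.integers(0, 4, size=len(seq))
    return _Piece(seq, cats, frozen,
                  {"body_len": len(body), "stop": template.stop})


def _new_trna(rng, gene: str, freqs) -> _Piece:
    geo = go.TRNA_GEOMETRY
    acc = _random_codes(rng, geo["acceptor"], freqs)
    d_stem = _random_codes(rng, geo["d_stem"], freqs)
    ac_stem = _random_codes(rng, geo["ac_stem"], freqs)
    t_stem = _random_codes(rng, geo["t_stem"], freqs)
    dhu = _random_codes(rng, geo["dhu_loop"], freqs)
    ac_loop = _random_codes(rng, geo["ac_loop"], freqs)
    ac_loop[2:5] = _to_codes(go.TRNA_ANTICODONS[gene])
    t_loop = _random_codes(rng, geo["t_loop"], freqs)
    # stem-paired positions are frozen: compensatory selection keeps the
    # cloverleaf stems paired, so only loops and linkers drift
    parts = [(acc, True), (_random_codes(rng, geo["linker1"], freqs), False),
             (d_stem, True), (dhu, False), (_revcomp(d_stem), True),
             (_random_codes(rng, geo["linker2"], freqs), False),
             (ac_stem, True), (ac_loop, False), (_revcomp(ac_stem), True),
             (_random_codes(rng, geo["var_loop"], freqs), False),
             (t_stem, True), (t_loop, False), (_revcomp(t_stem), True),
             (_revcomp(acc), True)]
    seq = np.concatenate([p for p, _ in parts])
    frozen = np.concatenate([np.full(len(p), keep, dtype=bool)
                             for p, keep in parts])
    ac_start = (geo["acceptor"] + geo["linker1"] + 2 * geo["d_stem"]
                + geo["dhu_loop"] + geo["linker2"] + geo["ac_stem"])
    frozen[ac_start + 2:ac_start + 5] = True   # anticodon
    cats = rng.integers(0, 4, size=len(seq))
    return _Piece(seq, cats, frozen,
                  {"dhu": geo["dhu_loop"], "tpc": geo["t_loop"]})


def _trna_loop_span(piece: _Piece, loop: str) -> tuple[int, int]:
    geo = go.TRNA_GEOMETRY
    dhu_start = geo["acceptor"] + geo["linker1"] + geo["d_stem"]
    if loop == "DHU":
        return dhu_start, dhu_start + piece.meta["dhu"]
    tpc_start = (dhu_start + piece.meta["dhu"] + geo["d_stem"]
                 + geo["linker2"] + 2 * geo["ac_stem"] + geo["ac_loop"]
                 + geo["var_loop"] + geo["t_stem"])
    return tpc_start, tpc_start + piece.meta["tpc"]


def _new_plain(rng, length: int, freqs) -> _Piece:
    seq = _random_codes(rng, length, freqs)
    return _Piece(seq, rng.integers(0, 4, size=length),
                  np.zeros(length, dtype=bool))


_EMPTY = _Piece(np.zeros(0, dtype=np.uint8), np.zeros(0, dtype=np.int64),
                np.zeros(0, dtype=bool))


def _piece_order(cfg: SimulationConfig) -> list[tuple[str, str, str]]:
    """Deterministic evolution order: (segment, name, class) triples,
    features interleaved with their spacer loci."""
    order: list[tuple[str, str, str]] = []
    for seg_id in go.SEGMENT_IDS:
        feats = go.SEGMENTS[seg_id]
        for i, ft in enumerate(feats):
            order.append((seg_id, ft.gene, ft.type))
            if i + 1 < len(feats):
                order.append((seg_id,
                              go.spacer_locus(ft.gene, feats[i + 1].gene),
                              "spacer"))
    if cfg.include_nuclear:
        for gene in go.NUCLEAR_GENES:
            order.append(("nuclear", gene, "nuclear"))
    return order


def _root_pieces(cfg: SimulationConfig, rng) -> dict[tuple[str, str], _Piece]:
    pieces: dict[tuple[str, str], _Piece] = {}
    templates = {(seg, ft.gene): ft
                 for seg in go.SEGMENT_IDS for ft in go.SEGMENTS[seg]}
    for seg, name, cls in _piece_order(cfg):
        key = (seg, name)
        if cls == "spacer":
            seq = cfg.root_spacers.get(name, "")
            if seq:
                codes = _to_codes(seq)
                pieces[key] = _Piece(codes, rng.integers(0, 4, len(codes)),
                                     np.zeros(len(codes), dtype=bool))
            else:
                pieces[key] = _EMPTY.copy()
        elif cls == "PCG":
            pieces[key] = _new_pcg(rng, templates[key], cfg.mito_freqs)
        elif cls == "tRNA":
            pieces[key] = _new_trna(rng, name, cfg.mito_freqs)
        elif cls in ("rRNA", "control_region"):
            pieces[key] = _new_plain(rng, templates[key].length,
                                     cfg.mito_freqs)
        elif cls == "nuclear":
            body = _random_cds(rng, go.NUCLEAR_GENES[name],
                               cfg.nuclear_freqs, _STOPS_NUCLEAR)
            seq = np.concatenate([body, _to_codes("TAA")])
            frozen = np.zeros(len(seq), dtype=bool)
            frozen[:3] = True
            frozen[-3:] = True
            pieces[key] = _Piece(seq, rng.integers(0, 4, len(seq)), frozen,
                                 {"body_len": len(body), "stop": "TAA"})
        else:  # pragma: no cover - template classes are closed
            raise AssertionError(cls)
    return pieces


# ---------------------------------------------------------------------------
# evolution
# ---------------------------------------------------------------------------

def _mutate(rng, piece: _Piece, model: SubstModel, t: float) -> _Piece:
    out = piece.copy()
    if t <= 0 or not len(out.seq):
        return out
    rates = model.gamma_rates()
    for k, r in enumerate(rates):
        P = model.transition_matrix(t, rate=float(r))
        cum = np.cumsum(P, axis=1)
        for b in range(4):
            idx = np.flatnonzero((piece.cats == k) & (piece.seq == b)
                                 & ~piece.frozen)
            if not len(idx):
                continue
            draws = np.searchsorted(cum[b], rng.random(len(idx)) * cum[b][-1],
                                    side="right")
            out.seq[idx] = np.minimum(draws, 3).astype(np.uint8)
    return out


def _repair_stops(piece: _Piece, stops=_STOPS_MITO) -> None:
    """Turn any in-frame internal stop back into a sense codon (first base
    -> C), keeping the CDS translatable after substitutions."""
    body_len = piece.meta["body_len"]
    s = _to_str(piece.seq[:body_len])
    for i in range(3, body_len, 3):
        if s[i:i + 3] in stops:
            piece.seq[i] = _ENCODE["C"]


def evolve_genomes(tree: Tree, cfg: SimulationConfig,
                   rng: np.random.Generator | None = None,
                   clade_map: dict[str, str] | None = None) -> "TruthBundle":
    """Evolve all feature pieces over *tree* and assemble the truth bundle."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    for ev in list(cfg.spacer_events) + list(cfg.loop_events):
        if not tree.has_node(ev.branch):
            raise ValueError(f"event names unknown branch {ev.branch!r}")
    for spec in cfg.traits:
        for branch, _ in spec.changes:
            if not tree.has_node(branch):
                raise ValueError(f"trait change on unknown branch {branch!r}")

    order = _piece_order(cfg)
    mito_model = cfg.mito_model()
    nuc_model = cfg.nuclear_model()
    spacer_events = {}
    for ev in cfg.spacer_events:
        spacer_events.setdefault(ev.branch, []).append(ev)
    loop_events = {}
    for ev in cfg.loop_events:
        loop_events.setdefault(ev.branch, []).append(ev)

    states: dict[str, dict[tuple[str, str], _Piece]] = {}
    states[tree.root.name] = _root_pieces(cfg, rng)

    for node in tree.preorder():
        if node.parent is None:
            parent_state = states[node.name]
        else:
            parent_state = states[node.parent.name]
            child: dict[tuple[str, str], _Piece] = {}
            for seg, name, cls in order:
                model = nuc_model if cls == "nuclear" else mito_model
                scale = cfg.rate_scales[cls]
                piece = _mutate(rng, parent_state[(seg, name)], model,
                                node.length * scale)
                if cls in ("PCG", "nuclear"):
                    _repair_stops(piece, _STOPS_NUCLEAR if cls == "nuclear"
                                  else _STOPS_MITO)
                child[(seg, name)] = piece
            for ev in spacer_events.get(node.name, ()):
                seg = _locus_segment(ev.locus)
                if ev.action == "insert":
                    codes = _to_codes(ev.sequence)
                    child[(seg, ev.locus)] = _Piece(
                        codes, np.zeros(len(codes), dtype=np.int64),
                        np.ones(len(codes), dtype=bool))
                else:
                    child[(seg, ev.locus)] = _EMPTY.copy()
            for ev in loop_events.get(node.name, ()):
                seg = _trna_segment(ev.trna)
                piece = child[(seg, ev.trna)]
                start, stop = _trna_loop_span(piece, ev.loop)
                motif = _to_codes(ev.motif)
                piece.seq = np.concatenate(
                    [piece.seq[:start], motif, piece.seq[stop:]])
                piece.cats = np.concatenate(
                    [piece.cats[:start], np.zeros(len(motif), dtype=np.int64),
                     piece.cats[stop:]])
                piece.frozen = np.concatenate(
                    [piece.frozen[:start], np.ones(len(motif), dtype=bool),
                     piece.frozen[stop:]])
                piece.meta["dhu" if ev.loop == "DHU" else "tpc"] = len(motif)
            states[node.name] = child

    if clade_map is None:
        clade_map = {}
    traits, ancestral = _paint_traits(tree, cfg)
    return _assemble(tree, cfg, states, clade_map, traits, ancestral)


def _locus_segment(locus: str) -> str:
    for seg in go.SEGMENT_IDS:
        if locus in go.segment_spacer_loci(seg):
            return seg
    raise ValueError(f"spacer locus {locus!r} not in any segment")


def _trna_segment(trna: str) -> str:
    for seg in go.SEGMENT_IDS:
        for ft in go.SEGMENTS[seg]:
            if ft.gene == trna and ft.type == "tRNA":
                return seg
    raise ValueError(f"{trna!r} is not a template tRNA")


def _paint_traits(tree: Tree, cfg: SimulationConfig):
    """States at every node from the root state plus branch changes."""
    ancestral: dict[str, dict[str, str]] = {}
    leaf_cols: dict[str, dict[str, str]] = {}
    for spec in cfg.traits:
        changes = dict(spec.changes)
        node_state: dict[str, str] = {}
        for node in tree.preorder():
            if node.parent is None:
                node_state[node.name] = changes.get(node.name,
                                                    spec.root_state)
            else:
                node_state[node.name] = changes.get(
                    node.name, node_state[node.parent.name])
        ancestral[spec.name] = node_state
        leaf_cols[spec.name] = {leaf: node_state[leaf]
                                for leaf in tree.leaf_names()}
    taxa = tree.leaf_names()
    matrix = TraitMatrix(
        taxa=taxa,
        traits=leaf_cols,
        state_space={spec.name: list(spec.states) for spec in cfg.traits})
    return matrix, ancestral


# ---------------------------------------------------------------------------
# assembly and truth bundle
# ---------------------------------------------------------------------------

@dataclass
class TruthBundle:
    """Synthetic dataset plus every quantity the pipeline should recover."""
    config: SimulationConfig
    tree: Tree
    clade_map: dict[str, str]
    segments: dict[str, dict[str, str]]   # taxon -> segment_id -> sequence
    features: pd.DataFrame                # exact coordinates per taxon
    spacers: pd.DataFrame                 # spacer presence and sequence
    loops: pd.DataFrame                   # tRNA loop motifs per taxon
    genes: dict[str, dict[str, str]]      # gene -> taxon -> coding sequence
    traits: TraitMatrix
    ancestral_states: dict[str, dict[str, str]]

    @property
    def taxa(self) -> list[str]:
        return self.tree.leaf_names()

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for seg_id in go.SEGMENT_IDS:
            with open(out / f"segment_{seg_id}.fasta", "w") as fh:
                for taxon in self.taxa:
                    fh.write(f">{taxon}\n{self.segments[taxon][seg_id]}\n")
        gene_dir = out / "genes"
        gene_dir.mkdir(exist_ok=True)
        for gene, by_taxon in self.genes.items():
            safe = gene.replace("/", "_")
            with open(gene_dir / f"{safe}.fasta", "w") as fh:
                for taxon, seq in by_taxon.items():
                    fh.write(f">{taxon}\n{seq}\n")
        self.features.to_csv(out / "features.tsv", sep="\t", index=False)
        self.spacers.to_csv(out / "spacers.tsv", sep="\t", index=False)
        self.loops.to_csv(out / "loops.tsv", sep="\t", index=False)
        with open(out / "tree.nwk", "w") as fh:
            fh.write(self.tree.newick() + "\n")
        with open(out / "clades.tsv", "w") as fh:
            fh.write("taxon\tclade\n")
            for taxon in self.taxa:
                fh.write(f"{taxon}\t{self.clade_map.get(taxon, '')}\n")
        with open(out / "traits.tsv", "w") as fh:
            names = list(self.traits.traits)
            fh.write("taxon\t" + "\t".join(names) + "\n")
            for taxon in self.taxa:
                row = [self.traits.traits[t][taxon] for t in names]
                fh.write(taxon + "\t" + "\t".join(row) + "\n")
        rows = []
        for trait, node_state in self.ancestral_states.items():
            for node, state in node_state.items():
                rows.append({"trait": trait, "node": node, "state": state})
        pd.DataFrame(rows).to_csv(out / "ancestral_states.tsv", sep="\t",
                                  index=False)

    @classmethod
    def read(cls, indir, config: SimulationConfig | None = None
             ) -> "TruthBundle":
        """Reload a bundle written by :meth:`write`."""
        from .alignkit import read_fasta
        from .trees import Tree
        indir = Path(indir)
        with open(indir / "tree.nwk") as fh:
            tree = Tree.from_newick(fh.read())
        taxa = tree.leaf_names()
        segments: dict[str, dict[str, str]] = {t: {} for t in taxa}
        for seg_id in go.SEGMENT_IDS:
            seqs = read_fasta(str(indir / f"segment_{seg_id}.fasta"))
            for taxon, seq in seqs.items():
                segments[taxon][seg_id] = seq
        genes: dict[str, dict[str, str]] = {}
        for path in sorted((indir / "genes").glob("*.fasta")):
            genes[path.stem] = read_fasta(str(path))
        clades = pd.read_csv(indir / "clades.tsv", sep="\t")
        clade_map = dict(zip(clades["taxon"], clades["clade"]))
        traits = TraitMatrix.from_tsv(indir / "traits.tsv")
        spacers = pd.read_csv(indir / "spacers.tsv", sep="\t",
                              keep_default_na=False, dtype={"sequence": str})
        spacers["present"] = spacers["present"].map(
            lambda v: v if isinstance(v, (bool, np.bool_))
            else str(v) == "True")
        anc = pd.read_csv(indir / "ancestral_states.tsv", sep="\t")
        ancestral: dict[str, dict[str, str]] = {}
        for _, row in anc.iterrows():
            ancestral.setdefault(row["trait"], {})[row["node"]] = row["state"]
        return cls(
            config=config if config is not None else SimulationConfig(),
            tree=tree, clade_map=clade_map, segments=segments,
            features=pd.read_csv(indir / "features.tsv", sep="\t"),
            spacers=spacers,
            loops=pd.read_csv(indir / "loops.tsv", sep="\t"),
            genes=genes, traits=traits, ancestral_states=ancestral)


def _assemble(tree, cfg, states, clade_map, traits, ancestral) -> TruthBundle:
    segments: dict[str, dict[str, str]] = {}
    feature_rows, spacer_rows, loop_rows = [], [], []
    genes: dict[str, dict[str, str]] = {}

    for taxon in tree.leaf_names():
        pieces = states[taxon]
        segments[taxon] = {}
        for seg_id in go.SEGMENT_IDS:
            feats = go.SEGMENTS[seg_id]
            pos = 0
            parts = []
            for i, ft in enumerate(feats):
                piece = pieces[(seg_id, ft.gene)]
                fwd = piece.seq if ft.strand == "+" else _revcomp(piece.seq)
                start, end = pos, pos + len(fwd)
                parts.append(fwd)
                pos = end
                feature_rows.append({
                    "taxon": taxon, "segment": seg_id, "gene": ft.gene,
                    "type": ft.type, "strand": ft.strand,
                    "start": start, "end": end})
                genes.setdefault(ft.gene, {})[taxon] = _to_str(piece.seq)
                if ft.type == "tRNA":
                    for loop in ("DHU", "TPC"):
                        a, b = _trna_loop_span(piece, loop)
                        loop_rows.append({
                            "taxon": taxon, "trna": ft.gene, "loop": loop,
                            "sequence": _to_str(piece.seq[a:b])})
                if i + 1 < len(feats):
                    locus = go.spacer_locus(ft.gene, feats[i + 1].gene)
                    sp = pieces[(seg_id, locus)]
                    parts.append(sp.seq)
                    spacer_rows.append({
                        "taxon": taxon, "segment": seg_id, "locus": locus,
                        "start": pos, "end": pos + len(sp.seq),
                        "present": bool(len(sp.seq)),
                        "sequence": _to_str(sp.seq)})
                    pos += len(sp.seq)
            segments[taxon][seg_id] = _to_str(np.concatenate(parts))
        if cfg.include_nuclear:
            for gene in go.NUCLEAR_GENES:
                genes.setdefault(gene, {})[taxon] = _to_str(
                    pieces[("nuclear", gene)].seq)

    return TruthBundle(
        config=cfg, tree=tree, clade_map=clade_map, segments=segments,
        features=pd.DataFrame(feature_rows),
        spacers=pd.DataFrame(spacer_rows),
        loops=pd.DataFrame(loop_rows),
        genes=genes, traits=traits, ancestral_states=ancestral)


def config_to_dict(cfg: SimulationConfig) -> dict:
    """JSON/YAML-safe dictionary representation of a config."""
    from dataclasses import asdict
    d = asdict(cfg)
    d["clade_sizes"] = list(cfg.clade_sizes)
    d["branch_length_range"] = list(cfg.branch_length_range)
    d["mito_freqs"] = list(cfg.mito_freqs)
    d["nuclear_freqs"] = list(cfg.nuclear_freqs)
    d["spacer_events"] = [asdict(e) for e in cfg.spacer_events]
    d["loop_events"] = [asdict(e) for e in cfg.loop_events]
    d["traits"] = [{"name": t.name, "states": list(t.states),
                    "root_state": t.root_state,
                    "changes": [list(c) for c in t.changes]}
                   for t in cfg.traits]
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["clade_sizes"] = tuple(d.get("clade_sizes", (3, 3, 4)))
    d["branch_length_range"] = tuple(d.get("branch_length_range",
                                           (0.02, 0.12)))
    d["mito_freqs"] = tuple(d.get("mito_freqs", (0.40, 0.10, 0.10, 0.40)))
    d["nuclear_freqs"] = tuple(d.get("nuclear_freqs",
                                     (0.30, 0.20, 0.20, 0.30)))
    d["spacer_events"] = tuple(SpacerEvent(**e)
                               for e in d.get("spacer_events", ()))
    d["loop_events"] = tuple(LoopEvent(**e) for e in d.get("loop_events", ()))
    d["traits"] = tuple(
        TraitSpec(t["name"], tuple(t["states"]), t["root_state"],
                  tuple((b, s) for b, s in t.get("changes", ())))
        for t in d.get("traits", ()))
    return SimulationConfig(**d)


def simulate_alignment(tree: Tree, model: SubstModel, n_sites: int,
                       seed: int = 0) -> dict[str, str]:
    """Plain site simulation on an arbitrary rooted tree (no features).

    Draws the root from the stationary frequencies, assigns each site a
    gamma category once, and evolves along every branch; returns taxon ->
    ungapped sequence.  Used to study signal behaviour (e.g. quartet
    resolution versus alignment length).
    """
    rng = np.random.default_rng(seed)
    root_seq = _random_codes(rng, n_sites, model.freqs)
    cats = rng.integers(0, max(1, model.ncat if model.alpha else 1),
                        size=n_sites)
    piece = _Piece(root_seq, cats, np.zeros(n_sites, dtype=bool))
    state = {tree.root.name: piece}
    for node in tree.preorder():
        if node.parent is None:
            continue
        state[node.name] = _mutate(rng, state[node.parent.name], model,
                                   node.length)
    return {leaf: _to_str(state[leaf].seq) for leaf in tree.leaf_names()}


def simulate(cfg: SimulationConfig | None = None,
             seed: int | None = None) -> TruthBundle:
    """One-call simulation: tree + genomes + truth, fully seeded."""
    if cfg is None:
        cfg = default_config(seed if seed is not None else 0)
    elif seed is not None:
        raise ValueError("pass the seed inside the config, or alone")
    rng = np.random.default_rng(cfg.seed)
    tree, clade_map = simulate_tree(cfg, rng)
    return evolve_genomes(tree, cfg, rng, clade_map)
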