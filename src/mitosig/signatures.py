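"""Phylogenetic signatures from intergenic spacers and tRNA loop motifs.

Spacer presence/absence patterns across taxa are grouped per locus and
classified on the reference tree by minimum-change (Sankoff) reconstruction;
all most-parsimonious gain/loss scenarios are enumerated, and ties are
broken Dollo-style (fewest independent gains, counting ancestral presence as
one origin).  tRNA loop sequences are screened for minimal IUPAC consensus
motifs that are diagnostic for a clade: every member matches, no non-member
does, and the number of degenerate positions is bounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .traitmap import enumerate_optimal_labelings
from .trees import Tree

__all__ = ["SpacerGroup", "SignaturePattern", "group_spacers",
           "classify_pattern", "classify_all", "extract_loop_motifs",
           "diagnostic_motifs", "iupac_consensus", "matches_iupac"]

# ---------------------------------------------------------------------------
# IUPAC helpers
# ---------------------------------------------------------------------------

_IUPAC_OF = {frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
             frozenset("T"): "T",
             frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
             frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
             frozenset("ACG"): "V", frozenset("ACT"): "H",
             frozenset("AGT"): "D", frozenset("CGT"): "B",
             frozenset("ACGT"): "N"}
_SET_OF = {code: s for s, code in _IUPAC_OF.items()}


def iupac_consensus(seqs: list[str]) -> tuple[str, int] | None:
    """Positionwise-union consensus of equal-length sequences.

    Returns ``(motif, n_degenerate)``; ``None`` when lengths differ or a
    sequence holds a non-ACGT symbol.  The union consensus is the unique
    minimal IUPAC pattern matching all inputs, so any tighter pattern would
    exclude a member and any looser one is not minimal.
    """
    if not seqs or len({len(s) for s in seqs}) != 1:
        return None
    motif, degenerate = [], 0
    for chars in zip(*(s.upper() for s in seqs)):
        key = frozenset(chars)
        if key not in _IUPAC_OF:
            return None
        if len(key) > 1:
            degenerate += 1
        motif.append(_IUPAC_OF[key])
    return "".join(motif), degenerate


def matches_iupac(seq: str, motif: str) -> bool:
    if len(seq) != len(motif):
        return False
    return all(c.upper() in _SET_OF[m] for c, m in zip(seq, motif))


# ---------------------------------------------------------------------------
# spacer groups
# ---------------------------------------------------------------------------

@dataclass
class SpacerGroup:
    locus: str
    present: list[str]                   # taxa carrying the spacer
    absent: list[str]
    sequences: dict[str, str]            # taxon -> spacer sequence
    shared_motif: str | None = None      # strict consensus of the members
    mean_identity: float | None = None


def _pairwise_identity(a: str, b: str) -> float:
    if len(a) != len(b) or not a:
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def group_spacers(spacers: pd.DataFrame,
                  identity_threshold: float = 0.6) -> list[SpacerGroup]:
    """One group per locus with at least one carrier.

    The shared motif is the strict consensus (mismatch positions as N) of
    the carriers' sequences, reported only when all carriers have equal
    lengths and their mean pairwise identity reaches the threshold.
    """
    groups = []
    for locus, sub in spacers.groupby("locus", sort=True):
        present = sorted(sub.loc[sub["present"], "taxon"])
        absent = sorted(sub.loc[~sub["present"].astype(bool), "taxon"])
        if not present:
            continue
        seqs = {t: s for t, s in zip(sub["taxon"], sub["sequence"])
                if t in set(present)}
        motif, identity = None, None
        member_seqs = [seqs[t] for t in present]
        if len({len(s) for s in member_seqs}) == 1:
            if len(member_seqs) == 1:
                identity = 1.0
            else:
                pairs = list(combinations(member_seqs, 2))
                identity = sum(_pairwise_identity(a, b)
                               for a, b in pairs) / len(pairs)
            if identity >= identity_threshold:
                motif = "".join(c[0] if len(set(c)) == 1 else "N"
                                for c in zip(*member_seqs))
        groups.append(SpacerGroup(locus, present, absent, seqs,
                                  motif, identity))
    return groups


# ---------------------------------------------------------------------------
# presence/absence pattern classification
# ---------------------------------------------------------------------------

@dataclass
class SignaturePattern:
    locus: str
    pattern_class: str                   # ubiquitous|lineage_specific|clade_restricted
    supporting_clade: str | None         # node whose leaves equal the carriers
    parsimony_length: int
    root_state: str                      # of the Dollo-leaning scenario
    gains: list[str]                     # branches (child-node names)
    losses: list[str]
    n_scenarios: int
    scenarios: list[dict] = field(default_factory=list)


def _scenario(tree: Tree, labeling: dict[str, str]) -> dict:
    gains, losses = [], []
    for node in tree.preorder():
        if node.parent is None:
            continue
        a, b = labeling[node.parent.name], labeling[node.name]
        if a != b:
            (gains if b == "present" else losses).append(node.name)
    root_state = labeling[tree.root.name]
    origins = len(gains) + (1 if root_state == "present" else 0)
    return {"root_state": root_state, "gains": gains, "losses": losses,
            "origins": origins}


def classify_pattern(tree: Tree, group: SpacerGroup) -> SignaturePattern:
    """Minimum-change classification of one spacer's presence pattern.

    All most-parsimonious scenarios are enumerated; the reported gains and
    losses come from the Dollo-leaning one (fewest independent origins,
    then fewest losses).
    """
    leaves = set(tree.leaf_names())
    carriers = set(group.present)
    unknown = carriers - leaves
    if unknown:
        raise ValueError(f"carriers not on the tree: {sorted(unknown)}")
    column = {leaf: "present" if leaf in carriers else "absent"
              for leaf in leaves}
    labelings, length = enumerate_optimal_labelings(
        tree, column, states=["absent", "present"])
    scenarios = [_scenario(tree, lab) for lab in labelings]
    best = min(scenarios,
               key=lambda s: (s["origins"], len(s["losses"]),
                              tuple(s["gains"]), tuple(s["losses"])))

    if carriers == leaves:
        pattern_class = "ubiquitous"
    elif len(carriers) == 1:
        pattern_class = "lineage_specific"
    else:
        pattern_class = "clade_restricted"
    supporting = None
    for node in tree.preorder():
        if not node.is_leaf and \
                set(tree.leaves_under(node.name)) == carriers:
            supporting = node.name
            break
    if supporting is None and len(carriers) == 1:
        supporting = next(iter(carriers))

    return SignaturePattern(
        locus=group.locus, pattern_class=pattern_class,
        supporting_clade=supporting, parsimony_length=length,
        root_state=best["root_state"], gains=best["gains"],
        losses=best["losses"], n_scenarios=len(scenarios),
        scenarios=scenarios)


def classify_all(tree: Tree, groups: list[SpacerGroup]
                 ) -> tuple[dict[str, SignaturePattern], pd.DataFrame]:
    patterns = {g.locus: classify_pattern(tree, g) for g in groups}
    rows = [{
        "locus": p.locus, "pattern_class": p.pattern_class,
        "supporting_clade": p.supporting_clade,
        "n_carriers": len(g.present),
        "parsimony_length": p.parsimony_length,
        "root_state": p.root_state,
        "gains": ";".join(p.gains), "losses": ";".join(p.losses),
        "n_scenarios": p.n_scenarios,
        "shared_motif": g.shared_motif if g.shared_motif else "",
    } for g, p in ((g, patterns[g.locus]) for g in groups)]
    return patterns, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# diagnostic loop motifs
# ---------------------------------------------------------------------------

def extract_loop_motifs(loops: pd.DataFrame) -> pd.DataFrame:
    """Pivot of loop sequences: one row per (trna, loop), one column per
    taxon."""
    return loops.pivot_table(index=["trna", "loop"], columns="taxon",
                             values="sequence", aggfunc="first")


def diagnostic_motifs(loops: pd.DataFrame, clade_map: dict[str, str],
                      max_degeneracy: int = 2,
                      skip_groups: tuple[str, ...] = ("outgroup",)
                      ) -> pd.DataFrame:
    """Minimal IUPAC consensus motifs exclusive to one clade.

    For every clade and every (tRNA, loop) the positionwise-union consensus
    of the members is computed; it is reported when it has at most
    ``max_degeneracy`` degenerate positions and no taxon outside the clade
    matches it.  Exclusivity is enforced at construction, so reported
    motifs have zero false positives by re-matching.
    """
    rows = []
    clades = sorted({c for c in clade_map.values() if c not in skip_groups})
    for (trna, loop), sub in loops.groupby(["trna", "loop"], sort=True):
        seq_of = dict(zip(sub["taxon"], sub["sequence"]))
        for clade in clades:
            members = sorted(t for t, c in clade_map.items() if c == clade)
            if not members or any(t not in seq_of for t in members):
                continue
            cons = iupac_consensus([seq_of[t] for t in members])
            if cons is None:
                continue
            motif, degenerate = cons
            if degenerate > max_degeneracy:
                continue
            outside = [t for t in seq_of if clade_map.get(t) != clade]
            if any(matches_iupac(seq_of[t], motif) for t in outside):
                continue
            rows.append({"clade": clade, "trna": trna, "loop": loop,
                         "motif": motif, "n_members": len(members),
                         "degenerate_positions": degenerate})
    return pd.DataFrame(rows, columns=["clade", "trna", "loop", "motif",
                                       "n_members", "degenerate_positions"])
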