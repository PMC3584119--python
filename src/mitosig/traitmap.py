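"""Unordered parsimony reconstruction of categorical traits on a rooted tree.

Ancestral states are computed with the Sankoff dynamic programme under unit
costs (equivalent to Fitch on binary trees, but handling polytomies and
missing data natively).  Per-node state sets are unions over all
most-parsimonious reconstructions (MPRs), the display convention of classical
character-mapping software, and the branches reported as changes are those on
which a state change is required in *every* MPR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import Tree, Node

__all__ = ["TraitMatrix", "ReconstructionResult", "parsimony_reconstruct",
           "map_all_traits", "count_min_origins"]

MISSING = "?"
_INF = np.inf
# changes dominate gains lexicographically in the origin-counting DP
_BIG = 1_000_000


@dataclass
class TraitMatrix:
    taxa: list[str]
    traits: dict[str, dict[str, str]]          # trait -> taxon -> state
    state_space: dict[str, list[str]]

    def __post_init__(self):
        for trait, column in self.traits.items():
            space = set(self.state_space[trait])
            for taxon, state in column.items():
                if state != MISSING and state not in space:
                    raise ValueError(
                        f"state {state!r} of {taxon} not in the declared "
                        f"space of trait {trait!r}")

    def column(self, trait: str) -> dict[str, str]:
        return self.traits[trait]

    @classmethod
    def from_tsv(cls, path) -> "TraitMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        taxa = list(df.iloc[:, 0])
        traits, space = {}, {}
        for col in df.columns[1:]:
            column = dict(zip(taxa, df[col].fillna(MISSING)))
            traits[col] = column
            space[col] = sorted({s for s in column.values() if s != MISSING})
        return cls(taxa, traits, space)

    @classmethod
    def from_nexus(cls, path) -> "TraitMatrix":
        import dendropy
        mat = dendropy.StandardCharacterMatrix.get(path=str(path),
                                                   schema="nexus")
        taxa = [t.label for t in mat.taxon_namespace]
        nchar = max(len(mat[t]) for t in mat.taxon_namespace)
        traits, space = {}, {}
        for k in range(nchar):
            name = f"char{k + 1}"
            column = {}
            for t in mat.taxon_namespace:
                sym = str(mat[t][k].symbol) if k < len(mat[t]) else MISSING
                column[t.label] = MISSING if sym in "?-" else sym
            traits[name] = column
            space[name] = sorted({s for s in column.values() if s != MISSING})
        return cls(taxa, traits, space)


@dataclass
class ReconstructionResult:
    trait: str
    tree_length: int
    node_states: dict[str, frozenset]         # node name -> MPR state set
    changes: dict[str, tuple[frozenset, frozenset]]  # child node -> (from, to)
    states: list[str]

    def annotated_newick(self, tree: Tree) -> str:
        """Newick with the MPR state set of each node as a comment."""
        def rec(node: Node) -> str:
            tag = "[&states={%s}]" % "|".join(
                sorted(self.node_states[node.name]))
            if node.is_leaf:
                body = node.name + tag
            else:
                body = ("(" + ",".join(rec(c) for c in node.children) + ")"
                        + node.name + tag)
            if node.parent is not None:
                body += ":%g" % node.length
            return body
        return rec(tree.root) + ";"


def _prepare(tree: Tree, column: dict[str, str],
             states: list[str] | None):
    leaves = set(tree.leaf_names())
    if leaves != set(column):
        raise ValueError("tree leaves and trait taxa differ")
    if states is None:
        states = sorted({s for s in column.values() if s != MISSING})
    else:
        bad = {s for s in column.values()} - set(states) - {MISSING}
        if bad:
            raise ValueError(f"states not in declared space: {sorted(bad)}")
    if not states:
        raise ValueError("trait has no observed states")
    return states


def _down_pass(tree: Tree, column: dict[str, str], states: list[str]):
    """Sankoff subtree costs g[node][state] under unit costs."""
    k = len(states)
    index = {s: i for i, s in enumerate(states)}
    g: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            obs = column[node.name]
            vec = np.zeros(k) if obs == MISSING else np.full(k, _INF)
            if obs != MISSING:
                vec[index[obs]] = 0.0
            g[node.name] = vec
        else:
            vec = np.zeros(k)
            for child in node.children:
                cg = g[child.name]
                best = cg.min()
                # unit cost: staying costs cg[s], moving costs best+1
                vec += np.minimum(cg, best + 1.0)
            g[node.name] = vec
    return g


def parsimony_reconstruct(tree: Tree, column: dict[str, str],
                          states: list[str] | None = None,
                          trait: str = "trait") -> ReconstructionResult:
    """Minimum-change reconstruction of one categorical character.

    Returns the parsimony length, the union-over-MPRs state set per node,
    and the branches on which a change occurs in every MPR (reported with
    the parent and child MPR sets).
    """
    states = _prepare(tree, column, states)
    g = _down_pass(tree, column, states)
    length = g[tree.root.name].min()

    # up-pass: h[node][s] = best cost of the rest of the tree given node=s
    h: dict[str, np.ndarray] = {tree.root.name: np.zeros(len(states))}
    for node in tree.preorder():
        for child in node.children:
            sib = np.zeros(len(states))
            for other in node.children:
                if other is not child:
                    og = g[other.name]
                    sib += np.minimum(og, og.min() + 1.0)
            base = h[node.name] + sib  # cost above+besides, parent state t
            # child state s: min_t base[t] + (0 if t==s else 1)
            h[child.name] = np.minimum(base, base.min() + 1.0)

    node_states: dict[str, frozenset] = {}
    for node in tree.postorder():
        total = g[node.name] + h[node.name]
        node_states[node.name] = frozenset(
            s for i, s in enumerate(states) if total[i] <= length + 1e-9)

    changes: dict[str, tuple[frozenset, frozenset]] = {}
    for node in tree.preorder():
        for child in node.children:
            sib = np.zeros(len(states))
            for other in node.children:
                if other is not child:
                    og = g[other.name]
                    sib += np.minimum(og, og.min() + 1.0)
            same = h[node.name] + sib + g[child.name]
            if same.min() > length + 1e-9:  # no MPR keeps the state equal
                changes[child.name] = (node_states[node.name],
                                       node_states[child.name])

    return ReconstructionResult(trait=trait, tree_length=int(round(length)),
                                node_states=node_states, changes=changes,
                                states=states)


def count_min_origins(tree: Tree, column: dict[str, str], state: str,
                      states: list[str] | None = None) -> int:
    """Minimum number of independent origins of *state* over all MPRs.

    An origin is a branch on which the state is gained, plus one if the root
    itself carries the state.  Among all minimum-change reconstructions the
    smallest origin count is returned (a lexicographic Sankoff pass with
    cost = changes * BIG + gains).
    """
    states = _prepare(tree, column, states)
    if state not in states:
        return 0
    target = states.index(state)
    k = len(states)

    g: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            obs = column[node.name]
            vec = np.zeros(k) if obs == MISSING else np.full(k, _INF)
            if obs != MISSING:
                vec[states.index(obs)] = 0.0
            g[node.name] = vec
        else:
            vec = np.zeros(k)
            for child in node.children:
                cg = g[child.name]
                # cost[s, t]: parent state s, child state t; a change costs
                # BIG, a gain of the target state costs an extra 1
                cost = cg[None, :] + _BIG * (1.0 - np.eye(k))
                cost[:, target] += 1.0
                cost[target, target] -= 1.0
                vec += cost.min(axis=1)
            g[node.name] = vec
    root = g[tree.root.name].copy()
    root[target] += 1.0  # ancestral presence counts as one origin
    combined = root.min()
    return int(round(combined % _BIG))


def enumerate_optimal_labelings(tree: Tree, column: dict[str, str],
                                states: list[str] | None = None
                                ) -> tuple[list[dict[str, str]], int]:
    """All most-parsimonious full labelings of the tree, plus the length.

    Feasible because children's optimal contributions are independent given
    the parent state: a labeling is an MPR iff the root state is optimal and
    every node achieves its per-child minimum, recursively.
    """
    states = _prepare(tree, column, states)
    g = _down_pass(tree, column, states)
    length = g[tree.root.name].min()
    nodes = tree.preorder()
    results: list[dict[str, str]] = []

    def candidates(node, parent_state):
        if parent_state is None:
            vec = g[node.name]
            return [s for i, s in enumerate(states)
                    if vec[i] <= length + 1e-9]
        vec = g[node.name] + np.array(
            [0.0 if s == parent_state else 1.0 for s in states])
        best = vec.min()
        return [s for i, s in enumerate(states) if vec[i] <= best + 1e-9]

    def rec(i: int, assign: dict[str, str]):
        if i == len(nodes):
            results.append(dict(assign))
            return
        node = nodes[i]
        parent_state = assign[node.parent.name] if node.parent else None
        for s in candidates(node, parent_state):
            assign[node.name] = s
            rec(i + 1, assign)
        assign.pop(node.name, None)

    rec(0, {})
    return results, int(round(length))


def map_all_traits(tree: Tree, matrix: TraitMatrix
                   ) -> tuple[dict[str, ReconstructionResult], pd.DataFrame]:
    """Reconstruct every trait and summarize convergence.

    The summary flags traits for which some state has at least two
    independent origins under the most favourable MPR (convergent
    evolution).
    """
    if not matrix.traits:
        raise ValueError("empty trait matrix")
    results: dict[str, ReconstructionResult] = {}
    records = []
    for trait in matrix.traits:
        column = matrix.column(trait)
        res = parsimony_reconstruct(tree, column,
                                    states=matrix.state_space[trait],
                                    trait=trait)
        results[trait] = res
        origins = {s: count_min_origins(tree, column, s,
                                        states=matrix.state_space[trait])
                   for s in matrix.state_space[trait]}
        records.append({
            "trait": trait,
            "tree_length": res.tree_length,
            "n_states": len(matrix.state_space[trait]),
            "max_origins": max(origins.values()) if origins else 0,
            "convergent": any(v >= 2 for v in origins.values()),
            "origins": ";".join(f"{s}={v}" for s, v in sorted(origins.items())),
        })
    return results, pd.DataFrame.from_records(records)
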