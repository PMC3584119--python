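"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own dynamic-programming code paths:
parsimony is checked by exhaustive enumeration of ancestral labelings and
likelihoods by explicit summation over internal-state assignments.
"""

from __future__ import annotations

import itertools

import numpy as np

from mitosig.models import BASE_INDEX
from mitosig.trees import Node, Tree

MISSING = "?"


def random_tree(rng: np.random.Generator, n_leaves: int,
                prefix: str = "t") -> Tree:
    """Random rooted binary tree with uniform(0.02, 0.5) branch lengths."""
    nodes = [Node(f"{prefix}{i}", length=float(rng.uniform(0.02, 0.5)))
             for i in range(n_leaves)]
    counter = itertools.count()
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        parent = Node(f"{prefix}in{next(counter)}",
                      length=float(rng.uniform(0.02, 0.5)))
        parent.add(a)
        parent.add(b)
        nodes.append(parent)
    nodes[0].length = 0.0
    return Tree(nodes[0])


def brute_force_parsimony(tree: Tree, column: dict[str, str],
                          states: list[str]) -> dict:
    """Exhaustive unit-cost parsimony over all ancestral labelings.

    Missing ('?') leaves are free nodes, exactly as in Sankoff with an
    all-zero tip cost vector.  Returns the minimum length, the union MPR
    state set per node, the branches changed in every MPR, the per-state
    minimum origin counts (gains + root presence) and the number of optimal
    labelings.
    """
    nodes = tree.postorder()
    free = [n.name for n in nodes
            if (not n.is_leaf) or column[n.name] == MISSING]
    fixed = {n.name: states.index(column[n.name]) for n in nodes
             if n.is_leaf and column[n.name] != MISSING}
    k, m = len(states), len(free)
    idx = {name: i for i, name in enumerate(free)}
    if m:
        grids = np.indices((k,) * m, dtype=np.int8).reshape(m, -1).T
    else:
        grids = np.zeros((1, 0), dtype=np.int8)
    n_assign = grids.shape[0]

    def col(name: str) -> np.ndarray:
        if name in idx:
            return grids[:, idx[name]]
        return np.full(n_assign, fixed[name], dtype=np.int8)

    cost = np.zeros(n_assign, dtype=np.int32)
    for n in nodes:
        if n.parent is not None:
            cost += col(n.name) != col(n.parent.name)
    best = int(cost.min())
    minimal = np.flatnonzero(cost == best)

    node_sets = {n.name: frozenset(states[v] for v in
                                   np.unique(col(n.name)[minimal]))
                 for n in nodes}

    forced = set()
    for n in nodes:
        if n.parent is not None:
            if (col(n.name)[minimal] != col(n.parent.name)[minimal]).all():
                forced.add(n.name)

    origins = {}
    root = tree.root.name
    for t, state in enumerate(states):
        o = (col(root)[minimal] == t).astype(np.int32)
        for n in nodes:
            if n.parent is not None:
                o += ((col(n.name)[minimal] == t)
                      & (col(n.parent.name)[minimal] != t))
        origins[state] = int(o.min())

    return {"length": best, "node_sets": node_sets, "forced": forced,
            "origins": origins, "n_labelings": int(len(minimal))}


def labeling_length(tree: Tree, labeling: dict[str, str]) -> int:
    """Number of state changes along the tree under a full labeling."""
    return sum(1 for n in tree.postorder() if n.parent is not None
               and labeling[n.name] != labeling[n.parent.name])


def brute_force_loglik(tree: Tree, data: dict[str, str], model) -> float:
    """Log-likelihood by explicit summation over all internal-state
    assignments and discrete-gamma categories (equal category weights)."""
    nodes = tree.postorder()
    internals = [n.name for n in nodes if not n.is_leaf]
    idx = {name: i for i, name in enumerate(internals)}
    rates = model.gamma_rates()
    pi = np.asarray(model.freqs)
    ncols = len(next(iter(data.values())))
    leaf_codes = {n.name: np.array([BASE_INDEX[c] for c in data[n.name]])
                  for n in nodes if n.is_leaf}
    total = np.zeros(ncols)
    for r in rates:
        P = {n.name: model.transition_matrix(n.length, rate=r)
             for n in nodes if n.parent is not None}
        for assign in itertools.product(range(4), repeat=len(internals)):
            lik = np.full(ncols, pi[assign[idx[tree.root.name]]])
            for n in nodes:
                if n.parent is None:
                    continue
                s_par = assign[idx[n.parent.name]]
                if n.is_leaf:
                    lik = lik * P[n.name][s_par, leaf_codes[n.name]]
                else:
                    lik = lik * P[n.name][s_par, assign[idx[n.name]]]
            total += lik
    return float(np.log(total / len(rates)).sum())
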