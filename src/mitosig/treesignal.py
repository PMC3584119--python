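"""Phylogenetic signal by quartet likelihood mapping, plus the likelihood
and distance-tree primitives behind it.

For every quartet of taxa the likelihoods of the three resolved topologies
are computed (branch lengths optimized), converted to posterior weights
w_i = L_i / sum(L), and the weight vector is classified into the seven
regions of the 2-simplex: three corners (fully resolved quartets), three
edges (two topologies tie, partly unresolved), one centre (star-like, fully
unresolved).  The region boundaries put the competing corner at pairwise
weight 1/3, i.e. a corner wins against a competitor only when its weight is
more than twice the competitor's; boundary ties fall to the less resolved
region.  The percentages of quartets per region class (%QFR, %QPU, %QFU)
summarize how tree-like the alignment signal is.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .models import SubstModel, BASE_INDEX
from .trees import Tree, Node

__all__ = ["SubstModel", "QuartetSignal", "site_log_likelihood",
           "quartet_map", "nj_tree", "signal_report"]


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------

def _encode_rows(rows: list[str]) -> np.ndarray:
    """Rows -> integer matrix; 4 encodes anything that is not A/C/G/T."""
    out = np.full((len(rows), len(rows[0]) if rows else 0), 4, dtype=np.int8)
    for i, row in enumerate(rows):
        for j, ch in enumerate(row.upper()):
            out[i, j] = BASE_INDEX.get(ch, 4)
    return out


def _compress(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, counts = np.unique(codes, axis=1, return_counts=True)
    return patterns, counts


_LEAF_PARTIALS = np.vstack([np.eye(4), np.ones(4)])  # row 4 = missing


def site_log_likelihood(tree: Tree, alignment, model: SubstModel,
                        partitions=None) -> float:
    """Total log-likelihood by Felsenstein pruning with discrete-gamma rates.

    *alignment* is an :class:`~mitosig.alignkit.Alignment` or a taxon->row
    mapping.  ``partitions`` optionally lists ``(column_indices, model)``
    pairs for per-partition models (columns not covered use *model*).
    """
    data = alignment.as_dict() if hasattr(alignment, "as_dict") else dict(alignment)
    leaves = tree.leaf_names()
    missing = set(leaves) - set(data)
    if missing:
        raise ValueError(f"alignment lacks tree taxa: {sorted(missing)}")
    rows = [data[t] for t in leaves]
    codes = _encode_rows(rows)

    if partitions:
        covered = np.zeros(codes.shape[1], dtype=bool)
        total = 0.0
        for cols, part_model in partitions:
            cols = np.asarray(cols)
            covered[cols] = True
            total += _pruning_loglik(tree, leaves, codes[:, cols], part_model)
        rest = np.flatnonzero(~covered)
        if len(rest):
            total += _pruning_loglik(tree, leaves, codes[:, rest], model)
        return total
    return _pruning_loglik(tree, leaves, codes, model)


def _pruning_loglik(tree: Tree, leaves: list[str], codes: np.ndarray,
                    model: SubstModel) -> float:
    patterns, counts = _compress(codes)
    ncat = len(model.gamma_rates())
    leaf_idx = {t: i for i, t in enumerate(leaves)}
    partials: dict[str, np.ndarray] = {}  # node -> (ncat, 4, npat)

    for node in tree.postorder():
        if node.is_leaf:
            p = _LEAF_PARTIALS[patterns[leaf_idx[node.name]]].T  # (4, npat)
            partials[node.name] = np.broadcast_to(
                p, (ncat, 4, patterns.shape[1]))
        else:
            acc = np.ones((ncat, 4, patterns.shape[1]))
            for child in node.children:
                P = model.transition_matrices(child.length)  # (ncat, 4, 4)
                acc = acc * np.einsum("kab,kbn->kan", P,
                                      partials[child.name])
            partials[node.name] = acc

    pi = np.asarray(model.freqs)
    root = partials[tree.root.name]                 # (ncat, 4, npat)
    site_lik = np.einsum("a,kan->n", pi, root) / ncat
    if np.any(site_lik <= 0):
        raise FloatingPointError("zero site likelihood (underflow?)")
    return float(np.log(site_lik) @ counts)


# ---------------------------------------------------------------------------
# quartet likelihood mapping
# ---------------------------------------------------------------------------

@dataclass
class QuartetSignal:
    n_quartets: int
    pct_resolved: float     # %QFR
    pct_partly: float       # %QPU
    pct_unresolved: float   # %QFU

    def __post_init__(self):
        total = self.pct_resolved + self.pct_partly + self.pct_unresolved
        if self.n_quartets and abs(total - 100.0) > 0.1:
            raise ValueError("region percentages must sum to 100")


def classify_weights(w) -> str:
    """Region of the likelihood-weight simplex for one quartet.

    ``resolved`` when one weight beats each competitor more than 2:1
    (competitor below 1/3 in the pairwise contest), ``partly`` when two
    weights tie but both beat the third, else ``unresolved``.  Boundary ties
    go to the less resolved class.
    """
    w = np.asarray(w, dtype=float)
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        if w[i] > 2 * w[j] and w[i] > 2 * w[k]:
            return "resolved"
    for i, j in ((0, 1), (0, 2), (1, 2)):
        k = 3 - i - j
        if w[i] > 2 * w[k] and w[j] > 2 * w[k]:
            return "partly"
    return "unresolved"


def _quartet_loglik(patterns: np.ndarray, counts: np.ndarray,
                    model: SubstModel, pairing: tuple, lengths: np.ndarray
                    ) -> float:
    """Log-likelihood of one resolved quartet topology.

    ``pairing`` gives the two cherries as row-index pairs, e.g.
    ``((0, 1), (2, 3))``; ``lengths`` holds the four terminal branch lengths
    (in row order) followed by the internal branch.
    """
    (a, b), (c, d) = pairing
    ncat = len(model.gamma_rates())

    def tip(i):
        return _LEAF_PARTIALS[patterns[i]].T  # (4, npat)

    Ps = [model.transition_matrices(t) for t in lengths]  # 5 x (ncat,4,4)
    up = np.einsum("kab,bn->kan", Ps[a], tip(a)) * \
        np.einsum("kab,bn->kan", Ps[b], tip(b))
    vp = np.einsum("kab,bn->kan", Ps[c], tip(c)) * \
        np.einsum("kab,bn->kan", Ps[d], tip(d))
    vp = np.einsum("kab,kbn->kan", Ps[4], vp)
    pi = np.asarray(model.freqs)
    site = np.einsum("a,kan,kan->n", pi, up, vp) / ncat
    site = np.maximum(site, 1e-300)
    return float(np.log(site) @ counts)


_PAIRINGS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


def _optimize_topology(patterns, counts, model, pairing,
                       tol: float = 1e-6, max_passes: int = 100) -> float:
    """Maximize one topology's log-likelihood over its five branch lengths
    by coordinate-wise Brent iterations.

    Equivalent to maximizing :func:`_quartet_loglik`, but caches the
    per-branch partials so each trial recomputes only the branch being
    optimized.
    """
    (a, b), (c, d) = pairing
    pi = np.asarray(model.freqs)
    ncat = len(model.gamma_rates())
    tip = {i: _LEAF_PARTIALS[patterns[i]].T for i in (a, b, c, d)}

    def through(i, t):
        return np.einsum("kab,bn->kan", model.transition_matrices(t), tip[i])

    lengths = np.full(5, 0.1)
    T = {i: through(i, lengths[i]) for i in (a, b, c, d)}
    P4 = model.transition_matrices(lengths[4])

    def loglik(T, P4):
        up = T[a] * T[b]
        low = np.einsum("kab,kbn->kan", P4, T[c] * T[d])
        site = np.einsum("a,kan,kan->n", pi, up, low) / ncat
        site = np.maximum(site, 1e-300)
        return float(np.log(site) @ counts)

    best = loglik(T, P4)
    for _ in range(max_passes):
        previous = best
        for i in (a, b, c, d, 4):
            def neg(t, i=i):
                if i == 4:
                    return -loglik(T, model.transition_matrices(t))
                trial = dict(T)
                trial[i] = through(i, t)
                return -loglik(trial, P4)
            res = minimize_scalar(neg, bounds=(1e-8, 10.0),
                                  method="bounded",
                                  options={"xatol": 1e-5})
            if -res.fun > best:
                best = -res.fun
                lengths[i] = res.x
                if i == 4:
                    P4 = model.transition_matrices(res.x)
                else:
                    T[i] = through(i, res.x)
        if abs(best - previous) <= tol * (abs(previous) + 1e-12):
            break
    return best


def quartet_map(alignment, model: SubstModel | None = None,
                quartet_sample="all", max_exhaustive: int = 20_000
                ) -> QuartetSignal:
    """Likelihood mapping of all (or a seeded sample of) quartets.

    For every quartet the three resolved topologies are fitted and the
    likelihood weights are classified into resolved / partly / unresolved
    regions.  Quartets whose columns are entirely missing are counted as
    unresolved with a warning.
    """
    data = alignment.as_dict() if hasattr(alignment, "as_dict") else dict(alignment)
    taxa = list(data)
    if len(taxa) < 4:
        raise ValueError("need at least four taxa")
    if not len(next(iter(data.values()))):
        raise ValueError("empty alignment")
    if model is None:
        from .models import empirical_model
        model = empirical_model(data.values())

    codes = _encode_rows([data[t] for t in taxa])
    all_quartets = list(itertools.combinations(range(len(taxa)), 4))
    if quartet_sample == "all" and len(all_quartets) > max_exhaustive:
        quartet_sample = (max_exhaustive, 0)
    if quartet_sample != "all":
        k, seed = quartet_sample
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(all_quartets), size=min(k, len(all_quartets)),
                         replace=False)
        quartets = [all_quartets[i] for i in sorted(idx)]
    else:
        quartets = all_quartets

    tallies = {"resolved": 0, "partly": 0, "unresolved": 0}
    for quartet in quartets:
        sub = codes[list(quartet)]
        informative = (sub < 4).any(axis=0)
        if not informative.any():
            warnings.warn("quartet with only missing columns counted as "
                          "unresolved")
            tallies["unresolved"] += 1
            continue
        patterns, counts = _compress(sub)
        logs = np.array([
            _optimize_topology(patterns, counts, model, pairing)
            for pairing in _PAIRINGS])
        w = np.exp(logs - logs.max())
        w /= w.sum()
        tallies[classify_weights(w)] += 1

    n = len(quartets)
    return QuartetSignal(
        n_quartets=n,
        pct_resolved=100.0 * tallies["resolved"] / n,
        pct_partly=100.0 * tallies["partly"] / n,
        pct_unresolved=100.0 * tallies["unresolved"] / n)


def signal_report(named_alignments: dict[str, "object"],
                  model: SubstModel | None = None,
                  quartet_sample="all"):
    """Signal table (ALN name, length, %QFR, %QPU, %QFU) for several ALNs."""
    import pandas as pd
    records = []
    for name, aln in named_alignments.items():
        sig = quartet_map(aln, model=model, quartet_sample=quartet_sample)
        records.append({"ALN": name, "length": aln.length,
                        "pct_QFR": round(sig.pct_resolved, 2),
                        "pct_QPU": round(sig.pct_partly, 2),
                        "pct_QFU": round(sig.pct_unresolved, 2)})
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# neighbor joining (scikit-bio backend)
# ---------------------------------------------------------------------------

def nj_tree(distance_matrix) -> Tree:
    """Neighbor-joining tree; negative branch lengths are clamped to zero.

    Accepts a :class:`~mitosig.cladedist.DistanceMatrix` or a
    ``(taxa, values)`` pair.
    """
    import io

    import skbio

    if hasattr(distance_matrix, "taxa"):
        taxa, values = distance_matrix.taxa, distance_matrix.values
    else:
        taxa, values = distance_matrix
    values = np.asarray(values, dtype=float)
    if not np.allclose(values, values.T):
        raise ValueError("distance matrix must be symmetric")
    if len(taxa) == 3:
        # unique unrooted star with closed-form branch lengths
        d01, d02, d12 = values[0, 1], values[0, 2], values[1, 2]
        root = Node("star")
        for t, b in zip(taxa, ((d01 + d02 - d12) / 2,
                               (d01 + d12 - d02) / 2,
                               (d02 + d12 - d01) / 2)):
            root.add(Node(t, length=max(0.0, b)))
        return Tree(root)
    dm = skbio.DistanceMatrix(values, ids=list(taxa))
    buf = io.StringIO()
    skbio.tree.nj(dm).write(buf, format="newick")
    tree = Tree.from_newick(buf.getvalue())
    for node in tree.postorder():
        if node.length < 0:
            node.length = 0.0
    return tree
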