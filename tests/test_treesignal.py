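"""Likelihood and quartet-mapping tests against brute-force enumeration."""

import numpy as np
import pytest

from mitosig import synthgen, treesignal
from mitosig.cladedist import DistanceMatrix
from mitosig.models import SubstModel, hky_at_rich
from mitosig.trees import Tree
from oracles import brute_force_loglik, random_tree


def _random_rows(rng, taxa, n):
    return {t: "".join(rng.choice(list("ACGT"), size=n)) for t in taxa}


def test_pruning_matches_brute_force_small_cases():
    rng = np.random.default_rng(0)
    models = [SubstModel(), hky_at_rich(),
              SubstModel(freqs=(0.3, 0.2, 0.2, 0.3),
                         exchangeabilities=(1, 3, 0.5, 1.2, 4, 1),
                         alpha=0.7)]
    for case in range(12):
        tree = random_tree(rng, int(rng.integers(3, 6)))
        data = _random_rows(rng, tree.leaf_names(), 8)
        model = models[case % len(models)]
        got = treesignal.site_log_likelihood(tree, data, model)
        want = brute_force_loglik(tree, data, model)
        assert got == pytest.approx(want, abs=1e-8)


def test_pruning_handles_gaps_as_missing():
    tree = Tree.from_newick("((a:0.1,b:0.1):0.05,c:0.1);")
    model = hky_at_rich()
    with_gap = treesignal.site_log_likelihood(
        tree, {"a": "A", "b": "-", "c": "C"}, model)
    # marginalizing the gapped leaf equals summing its four states
    parts = []
    for base in "ACGT":
        parts.append(np.exp(treesignal.site_log_likelihood(
            tree, {"a": "A", "b": base, "c": "C"}, model)))
    # P(b column) sums over b's state, weighting by transition already
    assert with_gap == pytest.approx(float(np.log(np.sum(parts))), abs=1e-9)


def test_partitioned_likelihood_adds_up():
    tree = Tree.from_newick("((a:0.1,b:0.2):0.05,(c:0.15,d:0.1):0.07);")
    model1, model2 = hky_at_rich(), SubstModel()
    rng = np.random.default_rng(5)
    data = _random_rows(rng, tree.leaf_names(), 10)
    both = treesignal.site_log_likelihood(
        tree, data, model2,
        partitions=[(list(range(4)), model1)])
    first = treesignal.site_log_likelihood(
        tree, {t: s[:4] for t, s in data.items()}, model1)
    rest = treesignal.site_log_likelihood(
        tree, {t: s[4:] for t, s in data.items()}, model2)
    assert both == pytest.approx(first + rest, abs=1e-9)


def test_missing_taxon_raises():
    tree = Tree.from_newick("(a:0.1,b:0.1);")
    with pytest.raises(ValueError):
        treesignal.site_log_likelihood(tree, {"a": "ACG"}, hky_at_rich())


def test_classify_weights_regions_and_boundaries():
    assert treesignal.classify_weights([0.9, 0.05, 0.05]) == "resolved"
    assert treesignal.classify_weights([1 / 3] * 3) == "unresolved"
    assert treesignal.classify_weights([0.46, 0.46, 0.08]) == "partly"
    # exact 2:1 boundaries fall to the less resolved class
    assert treesignal.classify_weights([0.5, 0.25, 0.25]) == "unresolved"
    assert treesignal.classify_weights([0.4, 0.4, 0.2]) == "unresolved"
    assert treesignal.classify_weights([0.41, 0.41, 0.18]) == "partly"


def test_quartet_percentages_sum_to_100():
    rng = np.random.default_rng(7)
    tree = random_tree(rng, 5)
    aln = synthgen.simulate_alignment(tree, hky_at_rich(), 300, seed=7)
    sig = treesignal.quartet_map(aln, model=hky_at_rich())
    assert sig.n_quartets == 5
    assert (sig.pct_resolved + sig.pct_partly + sig.pct_unresolved
            == pytest.approx(100.0))


def test_long_alignment_on_resolved_quartet_is_fully_resolved():
    tree = Tree.from_newick(
        "((a:0.1,b:0.1):0.08,(c:0.1,d:0.1):0.08);")
    aln = synthgen.simulate_alignment(tree, hky_at_rich(), 4000, seed=11)
    sig = treesignal.quartet_map(aln, model=hky_at_rich())
    assert sig.pct_resolved == pytest.approx(100.0)


def test_optimized_topology_beats_fixed_branch_reference():
    tree = Tree.from_newick("((a:0.1,b:0.1):0.06,(c:0.1,d:0.1):0.06);")
    aln = synthgen.simulate_alignment(tree, hky_at_rich(), 400, seed=3)
    model = hky_at_rich()
    rows = [aln[t] for t in ("a", "b", "c", "d")]
    codes = treesignal._encode_rows(rows)
    patterns, counts = treesignal._compress(codes)
    for pairing in treesignal._PAIRINGS:
        fixed = treesignal._quartet_loglik(patterns, counts, model, pairing,
                                           np.full(5, 0.1))
        opt = treesignal._optimize_topology(patterns, counts, model, pairing)
        assert opt >= fixed - 1e-6


def test_signal_report_structure():
    tree = Tree.from_newick(
        "((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05,e:0.12);")
    from mitosig.alignkit import Alignment

    def aln_of(n, seed):
        d = synthgen.simulate_alignment(tree, hky_at_rich(), n, seed=seed)
        return Alignment(list(d), list(d.values()), role="concatenated")

    named = {"setA": aln_of(500, 1), "setB": aln_of(200, 2)}
    report = treesignal.signal_report(named, quartet_sample=(3, 0))
    assert list(report.columns) == ["ALN", "length", "pct_QFR", "pct_QPU",
                                    "pct_QFU"]
    assert sorted(report["ALN"]) == ["setA", "setB"]
    sums = report[["pct_QFR", "pct_QPU", "pct_QFU"]].sum(axis=1)
    assert np.allclose(sums, 100.0)
    assert set(report["length"]) == {500, 200}


def test_nj_recovers_additive_tree_splits():
    true = Tree.from_newick(
        "((a:0.1,b:0.2):0.05,(c:0.15,(d:0.1,e:0.2):0.1):0.07);")
    leaves = true.leaf_names()
    # path-length (additive) distances
    def depth(name):
        node, d = true.node(name), 0.0
        while node.parent is not None:
            d += node.length
            node = node.parent
        return d

    vals = np.zeros((5, 5))
    for i, x in enumerate(leaves):
        for j, y in enumerate(leaves):
            if i < j:
                anc = true.mrca({x, y})
                d = depth(x) + depth(y) - 2 * depth(anc.name) \
                    if anc.parent is not None else depth(x) + depth(y)
                vals[i, j] = vals[j, i] = d
    nj = treesignal.nj_tree(DistanceMatrix(leaves, vals))
    assert sorted(nj.leaf_names()) == sorted(leaves)

    def clades(tree):
        all_leaves = frozenset(tree.leaf_names())
        out = set()
        for node in tree.postorder():
            under = frozenset(tree.leaves_under(node.name))
            if 0 < len(under) < len(all_leaves):
                out.add(under)
                out.add(all_leaves - under)
        return out

    cl = clades(nj)
    assert frozenset({"a", "b"}) in cl
    assert frozenset({"d", "e"}) in cl


def test_nj_three_taxa_closed_form():
    vals = np.array([[0.0, 0.3, 0.4],
                     [0.3, 0.0, 0.5],
                     [0.4, 0.5, 0.0]])
    nj = treesignal.nj_tree(DistanceMatrix(["a", "b", "c"], vals))
    lengths = {n.name: n.length for n in nj.postorder() if n.is_leaf}
    assert lengths["a"] == pytest.approx(0.1)
    assert lengths["b"] == pytest.approx(0.2)
    assert lengths["c"] == pytest.approx(0.3)
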