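"""Pairwise p-distances and within/among-clade summaries.

The p-distance between two aligned sequences is the proportion of differing
sites among their comparable sites; a site is comparable for a pair when both
sequences carry an unambiguous base (A, C, G or T) there.  Summaries average
the unordered pairs within each clade and across clade pairs, and report both
the sample standard deviation and a bootstrap standard error over pairs,
because the two conventions are common and often left unstated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .trees import Tree

__all__ = ["DistanceMatrix", "CladeModel", "p_distance_matrix",
           "clade_summary", "round3"]

_VALID = set("ACGT")


def round3(x: float) -> float:
    """Round half-up to 3 decimals (the convention of printed tables)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.001"),
                                           rounding=ROUND_HALF_UP))


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray
    comparable_sites: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(np.diag(self.values), 0.0, equal_nan=True):
            raise ValueError("diagonal must be zero")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        """Read a square or lower-triangular TSV matrix (first column taxa)."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        taxa = list(df.index)
        vals = df.to_numpy(dtype=float)
        # mirror a lower triangle if the upper one is empty
        upper = np.triu_indices(len(taxa), k=1)
        if np.all(np.isnan(vals[upper])):
            vals[upper] = vals.T[upper]
        np.fill_diagonal(vals, 0.0)
        return cls(taxa, vals)

    def to_tsv(self, path, decimals: int | None = None) -> None:
        vals = self.values
        if decimals is not None:
            vals = np.vectorize(
                lambda v: round(v, decimals) if np.isfinite(v) else v)(vals)
        pd.DataFrame(vals, index=self.taxa,
                     columns=self.taxa).to_csv(path, sep="\t")


@dataclass
class CladeModel:
    """Rooted reference tree plus taxon -> clade assignment."""

    tree: Tree
    assignment: dict[str, str]

    def __post_init__(self):
        leaves = set(self.tree.leaf_names())
        unknown = set(self.assignment) - leaves
        if unknown:
            raise ValueError(f"assigned taxa not on the tree: {sorted(unknown)}")

    def clade(self, taxon: str) -> str:
        return self.assignment[taxon]

    def clades(self) -> list[str]:
        seen = []
        for c in self.assignment.values():
            if c not in seen:
                seen.append(c)
        return seen

    def members(self, clade: str) -> list[str]:
        return [t for t, c in self.assignment.items() if c == clade]

    def check_monophyly(self) -> dict[str, bool]:
        out = {}
        for clade in self.clades():
            members = set(self.members(clade))
            node = self.tree.mrca(members)
            under = set(self.tree.leaves_under(node.name))
            out[clade] = under == members
        return out

    @classmethod
    def from_files(cls, tree_path, clades_tsv) -> "CladeModel":
        with open(tree_path) as fh:
            tree = Tree.from_newick(fh.read())
        df = pd.read_csv(clades_tsv, sep="\t")
        assignment = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        return cls(tree, assignment)


def p_distance_matrix(alignment, deletion: str = "pairwise") -> DistanceMatrix:
    """p-distance matrix under pairwise or complete deletion.

    *alignment* may be an :class:`~mitosig.alignkit.Alignment` or a mapping
    taxon -> aligned sequence.  Gaps and ambiguity codes never count as
    comparable.  A pair with zero comparable sites gets a NaN entry.
    """
    if hasattr(alignment, "as_dict"):
        data = alignment.as_dict()
    else:
        data = dict(alignment)
    if not data:
        raise ValueError("empty alignment")
    taxa = list(data)
    arrs = [np.frombuffer(data[t].upper().encode(), dtype="S1") for t in taxa]
    L = len(arrs[0])
    if any(len(a) != L for a in arrs):
        raise ValueError("rows have unequal lengths")
    valid = np.stack([np.isin(a, [b"A", b"C", b"G", b"T"]) for a in arrs])
    if deletion == "complete":
        keep = valid.all(axis=0)
        valid = valid[:, keep]
        arrs = [a[keep] for a in arrs]
    elif deletion != "pairwise":
        raise ValueError("deletion must be 'pairwise' or 'complete'")

    n = len(taxa)
    dist = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            comp[i, j] = comp[j, i] = m
            if m == 0:
                dist[i, j] = dist[j, i] = np.nan
            else:
                diff = int(((arrs[i] != arrs[j]) & both).sum())
                dist[i, j] = dist[j, i] = diff / m
    return DistanceMatrix(taxa, dist, comp)


def _bootstrap_se(values: np.ndarray, n_boot: int, seed: int) -> float:
    if len(values) < 2:
        return float("nan")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    return float(values[idx].mean(axis=1).std(ddof=1))


def clade_summary(matrix: DistanceMatrix, clades: CladeModel | dict,
                  include: list[str] | None = None,
                  n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Within-clade and among-clade mean p-distances.

    Within-clade means average the unordered pairs inside the clade;
    among-clade means average all cross-clade pairs.  Values are reported at
    full precision and rounded half-up to 3 decimals, with the sample SD and
    a seeded bootstrap SE over pairs.  Singleton clades yield NaN within
    means.  Clades named ``outgroup`` (any case) are excluded from
    summaries unless explicitly listed in *include*.
    """
    assignment = clades.assignment if isinstance(clades, CladeModel) else dict(clades)
    order: list[str] = []
    for t in matrix.taxa:
        c = assignment.get(t)
        if c is not None and c not in order:
            order.append(c)
    if include is None:
        include = [c for c in order if c.lower() != "outgroup"]

    def pair_values(taxa_a, taxa_b, cross):
        vals = []
        if cross:
            for a in taxa_a:
                for b in taxa_b:
                    vals.append(matrix.get(a, b))
        else:
            for i, a in enumerate(taxa_a):
                for b in taxa_a[i + 1:]:
                    vals.append(matrix.get(a, b))
        return np.array([v for v in vals if np.isfinite(v)])

    records = []
    for k, clade in enumerate(include):
        members = [t for t in matrix.taxa if assignment.get(t) == clade]
        vals = pair_values(members, None, cross=False)
        mean = float(vals.mean()) if len(vals) else float("nan")
        records.append({
            "comparison": clade, "kind": "within", "n_pairs": len(vals),
            "mean": mean,
            "mean_3dp": round3(mean) if np.isfinite(mean) else float("nan"),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            "boot_se": _bootstrap_se(vals, n_boot, seed + k),
        })
    for i, ca in enumerate(include):
        for j in range(i + 1, len(include)):
            cb = include[j]
            ma = [t for t in matrix.taxa if assignment.get(t) == ca]
            mb = [t for t in matrix.taxa if assignment.get(t) == cb]
            vals = pair_values(ma, mb, cross=True)
            mean = float(vals.mean()) if len(vals) else float("nan")
            records.append({
                "comparison": f"{ca} vs {cb}", "kind": "among",
                "n_pairs": len(vals), "mean": mean,
                "mean_3dp": round3(mean) if np.isfinite(mean) else float("nan"),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                "boot_se": _bootstrap_se(vals, n_boot, seed + 100 + i * 31 + j),
            })
    return pd.DataFrame.from_records(records)
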