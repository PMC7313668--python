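"""Heterozygosity-aware distances and BioNJ tree building.

Isolates are represented as IUPAC strings over the union of polymorphic
positions; the distance between two isolates is the mean per-column
expected mismatch under equal-probability resolution of ambiguity codes
(the "average state" treatment of heterozygous positions).  Trees are built
with BioNJ — neighbor joining with variance-weighted distance updates —
with deterministic lexicographic tie-breaking.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .diversity import EXPECTED_MISMATCH, encode, iupac_char, _CHAR_TO_INDEX


@dataclasses.dataclass
class PolymorphicMatrix:
    names: list[str]
    chars: np.ndarray                     # (n_isolates, n_columns) uint8 indices
    positions: list[tuple[str, int]]      # (scaffold, 1-based pos) per column

    @property
    def n_columns(self) -> int:
        return self.chars.shape[1]


@dataclasses.dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.isfinite(d).all():
            raise ValueError("entries must be finite")
        self.d = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


class TreeNode:
    """Node of a rooted representation of the (unrooted) NJ tree."""

    __slots__ = ("name", "children", "length")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.children: list[TreeNode] = []
        self.length = length

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.10g}"


@dataclasses.dataclass
class Tree:
    root: TreeNode
    n_negative_clamped: int = 0

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def newick(self) -> str:
        inner = ",".join(c.newick() for c in self.root.children)
        return f"({inner});"

    def edges(self) -> list[tuple[TreeNode, TreeNode, float]]:
        out = []

        def walk(node: TreeNode) -> None:
            for c in node.children:
                out.append((node, c, c.length))
                walk(c)

        walk(self.root)
        return out


def polymorphic_matrix(
    calls_by_isolate: Mapping[str, pd.DataFrame], genome
) -> PolymorphicMatrix:
    """IUPAC matrix over the union of positions polymorphic in >= 1 isolate."""
    names = sorted(calls_by_isolate)
    poly: set[tuple[str, int]] = set()
    for name in names:
        calls = calls_by_isolate[name]
        var = calls[calls["genotype_class"] != "hom_ref"]
        poly.update(zip(var["scaffold"], var["pos"].astype(int)))
    scaffold_order = {scaf: i for i, (scaf, _) in enumerate(genome.scaffolds)}
    positions = sorted(poly, key=lambda sp: (scaffold_order[sp[0]], sp[1]))
    col_of = {sp: i for i, sp in enumerate(positions)}

    chars = np.empty((len(names), len(positions)), dtype=np.uint8)
    for col, (scaf, pos) in enumerate(positions):
        chars[:, col] = _CHAR_TO_INDEX[ord(genome.sequence(scaf)[pos - 1])]
    for row, name in enumerate(names):
        for rec in calls_by_isolate[name].itertuples(index=False):
            key = (rec.scaffold, int(rec.pos))
            if key not in col_of:
                continue
            if rec.genotype_class == "hom_ref":
                char = rec.ref
            elif rec.genotype_class == "hom_alt":
                char = rec.alt
            else:
                char = iupac_char(rec.ref, rec.alt)
            chars[row, col_of[key]] = _CHAR_TO_INDEX[ord(char)]
    return PolymorphicMatrix(names=names, chars=chars, positions=positions)


def average_state_distance(s1, s2) -> float:
    """Mean per-column expected mismatch between two IUPAC sequences."""
    a = encode(s1) if isinstance(s1, (str, bytes)) else np.asarray(s1)
    b = encode(s2) if isinstance(s2, (str, bytes)) else np.asarray(s2)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    if len(a) == 0:
        return 0.0
    return float(EXPECTED_MISMATCH[a, b].mean())


def distance_matrix(pm: PolymorphicMatrix) -> DistanceMatrix:
    n = len(pm.names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = average_state_distance(pm.chars[i], pm.chars[j])
    return DistanceMatrix(labels=list(pm.names), d=d)


def _closed_form_three(nodes: list[TreeNode], d: np.ndarray) -> TreeNode:
    root = TreeNode()
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
    for node, ln in zip(nodes, (la, lb, lc)):
        node.length = ln
        root.children.append(node)
    return root


def nj_tree(dm: DistanceMatrix, method: str = "bionj") -> Tree:
    """Agglomerate a tree with BioNJ (default) or classic NJ.

    BioNJ follows neighbor joining for pair selection and branch lengths but
    propagates distances with variance-minimising weights.  Ties in the
    selection criterion break on the lexicographically smallest label pair,
    so the result is independent of input order.  Negative branch lengths
    are clamped to zero and counted.
    """
    if method not in ("bionj", "nj"):
        raise ValueError(f"unknown method {method!r}")
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValueError("need at least 3 labels")

    d = dm.d.copy()
    v = dm.d.copy()  # initial variance estimates equal the distances
    nodes = [TreeNode(name) for name in dm.labels]
    # tie-break label of a subtree: its lexicographically smallest leaf
    tie = list(dm.labels)
    active = list(range(n0))
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = d[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((tie[idx[i]], tie[idx[j]]))), i, j)
            for i, j in cand
            if i < j
        )
        ai, aj = best[1], best[2]
        i, j = idx[ai], idx[aj]
        dij = d[i, j]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li), clamp(lj)

        if method == "bionj" and v[i, j] > 1e-12:
            others = [k for k in active if k not in (i, j)]
            lam = 0.5 + sum(v[j, k] - v[i, k] for k in others) / (
                2.0 * (m - 2) * v[i, j]
            )
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5

        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.children = [nodes[i], nodes[j]]

        new = len(nodes)
        nodes.append(parent)
        tie.append(min(tie[i], tie[j]))
        d = np.pad(d, ((0, 1), (0, 1)))
        v = np.pad(v, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            dk = lam * (d[i, k] - li) + (1.0 - lam) * (d[j, k] - lj)
            d[new, k] = d[k, new] = dk
            v[new, k] = v[k, new] = (
                lam * v[i, k] + (1.0 - lam) * v[j, k] - lam * (1.0 - lam) * v[i, j]
            )
        active = [k for k in active if k not in (i, j)] + [new]

    last = sorted(active, key=lambda k: tie[k])
    sub = d[np.ix_(last, last)]
    root = _closed_form_three([nodes[k] for k in last], sub)
    for c in root.children:
        c.length = clamp(c.length)
    return Tree(root=root, n_negative_clamped=clamped)


def write_newick(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")
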