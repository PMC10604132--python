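"""Distance-based phylogeny: p/JC69/K2P distances, neighbor joining,
bootstrap support, bipartition utilities (monophyly, Robinson-Foulds).

Trees are stored rooted at an arbitrary node but all topology comparisons
(bipartitions, RF, monophyly) are in the unrooted sense. Neighbor joining
follows Saitou & Nei's Q-criterion with a deterministic tie-break (lowest
index pair wins), so identical inputs always yield identical trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .msa import Alignment, _BASE_IDX

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class Tree:
    root: Node

    def leaves(self) -> list[Node]:
        return [n for n in self.root.walk() if n.is_leaf()]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def nodes(self) -> list[Node]:
        return list(self.root.walk())

    def bipartitions(self, include_trivial: bool = False) -> set[frozenset]:
        """Unrooted bipartitions, each canonicalized as the side NOT
        containing the lexicographically smallest leaf. Trivial (single
        leaf / all-but-one) splits are excluded by default."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out: set[frozenset] = set()
        for node in self.root.walk():
            if node is self.root:
                continue
            side = frozenset(n.name for n in node.walk() if n.is_leaf())
            if ref in side:
                side = all_leaves - side
            if not include_trivial and (len(side) < 2 or len(side) > len(all_leaves) - 2):
                continue
            if side:
                out.add(side)
        return out

    def newick(self, support_as_label: bool = True) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf():
                return f"{n.name}:{n.length:.6g}"
            inner = ",".join(fmt(c) for c in n.children)
            label = ""
            if support_as_label and n.support is not None:
                label = f"{n.support:g}"
            elif n.name:
                label = n.name
            return f"({inner}){label}:{n.length:.6g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        import dendropy

        dt = dendropy.Tree.get(data=text, schema="newick")

        def conv(dn) -> Node:
            node = Node(
                name=dn.taxon.label.replace(" ", "_") if dn.taxon else None,
                length=dn.edge.length or 0.0,
            )
            if dn.label is not None and not dn.is_leaf():
                try:
                    node.support = float(dn.label)
                except ValueError:
                    node.name = dn.label
            node.children = [conv(c) for c in dn.child_nodes()]
            return node

        return cls(root=conv(dt.seed_node))


def _encode(aln: Alignment) -> np.ndarray:
    arr = np.full((len(aln.rows), aln.ncol), -1, dtype=np.int8)
    for i, r in enumerate(aln.rows):
        for j, b in enumerate(r):
            arr[i, j] = _BASE_IDX.get(b, -1)
    return arr


def distance_matrix(aln: Alignment, model: str = "JC69") -> np.ndarray:
    """Pairwise distances with pairwise deletion of gap/N sites.

    p: raw proportion of differing sites. JC69: d = -(3/4) ln(1 - 4p/3).
    K2P: d = -(1/2) ln((1 - 2P - Q) sqrt(1 - 2Q)) with P, Q the transition
    and transversion proportions. Saturated pairs (log argument <= 0) raise
    an error naming the pair.
    """
    arr = _encode(aln)
    n = arr.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] >= 0) & (arr[j] >= 0)
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites for {aln.taxa[i]}/{aln.taxa[j]}"
                )
            diff = arr[i, ok] != arr[j, ok]
            p = float(diff.sum()) / m
            if model == "p":
                d = p
            elif model == "JC69":
                arg = 1.0 - 4.0 * p / 3.0
                if arg <= 0:
                    raise ValueError(
                        f"saturated pair {aln.taxa[i]}/{aln.taxa[j]} (p={p:.3f})"
                    )
                d = -0.75 * np.log(arg)
            elif model == "K2P":
                # transitions: A<->G (codes 0,2), C<->T (codes 1,3)
                xi, xj = arr[i, ok], arr[j, ok]
                ts = ((xi != xj) & ((xi % 2) == (xj % 2))).sum() / m
                tv = p - ts
                a1 = 1.0 - 2.0 * ts - tv
                a2 = 1.0 - 2.0 * tv
                if a1 <= 0 or a2 <= 0:
                    raise ValueError(
                        f"saturated pair {aln.taxa[i]}/{aln.taxa[j]}"
                    )
                d = -0.5 * np.log(a1 * np.sqrt(a2))
            else:
                raise ValueError(f"unknown model {model!r}")
            D[i, j] = D[j, i] = d
    return D


def nj_tree(D: np.ndarray, taxa: list[str]) -> Tree:
    """Saitou-Nei neighbor joining; ties broken toward the lowest index
    pair; negative branch lengths clamped to 0 with a warning."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [Node(name=t) for t in taxa]
    active = list(range(n))
    D = D.copy()
    clamped = False
    while len(active) > 3:
        r = len(active)
        sums = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        if li < 0 or lj < 0:
            clamped = True
        li, lj = max(li, 0.0), max(lj, 0.0)
        nodes[i].length, nodes[j].length = li, lj
        new = Node(children=[nodes[i], nodes[j]])
        # grow matrix
        D = np.pad(D, ((0, 1), (0, 1)))
        k = D.shape[0] - 1
        for m in active:
            if m in (i, j):
                continue
            D[k, m] = D[m, k] = 0.5 * (D[i, m] + D[j, m] - D[i, j])
        nodes.append(new)
        active = [m for m in active if m not in (i, j)] + [k]
    # final three-way join
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        if ln < 0:
            clamped = True
        nodes[idx].length = max(ln, 0.0)
    if clamped:
        warnings.warn("negative branch length(s) clamped to 0")
    root = Node(children=[nodes[i], nodes[j], nodes[k]])
    return Tree(root=root)


def bootstrap_support(
    aln: Alignment,
    model: str = "JC69",
    n_reps: int = 100,
    seed: int = 0,
) -> Tree:
    """NJ tree with bootstrap percentages on internal edges.

    Columns are resampled with replacement per replicate; support is the
    percentage of replicate trees containing each internal bipartition of
    the point-estimate tree. With no variable columns, supports stay None.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    taxa = list(aln.taxa)
    D = distance_matrix(aln, model)
    tree = nj_tree(D, taxa)
    if np.allclose(D, 0):
        return tree
    rng = np.random.default_rng(seed)
    arr = _encode(aln)
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    for _ in range(n_reps):
        cols = rng.integers(0, aln.ncol, size=aln.ncol)
        rep = Alignment(
            taxa=taxa,
            rows=[
                "".join("ACGT-"[arr[i, c]] if arr[i, c] >= 0 else "-"
                        for c in cols)
                for i in range(len(taxa))
            ],
        )
        try:
            rt = nj_tree(distance_matrix(rep, model), taxa)
        except ValueError:
            continue
        rep_bps = rt.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    all_leaves = frozenset(taxa)
    ref = min(all_leaves)
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf():
            continue
        side = frozenset(n.name for n in node.walk() if n.is_leaf())
        if ref in side:
            side = all_leaves - side
        if side in counts:
            node.support = 100.0 * counts[side] / n_reps
    return tree


def is_monophyletic(t: Tree, taxa: set[str] | list[str]) -> bool:
    """True when the taxon set forms one side of some edge bipartition of
    the unrooted tree (single taxa are trivially monophyletic)."""
    want = frozenset(taxa)
    all_leaves = frozenset(t.leaf_names())
    if not want <= all_leaves:
        raise ValueError("taxa not all present in tree")
    if len(want) in (1, len(all_leaves)):
        return True
    ref = min(all_leaves)
    if ref in want:
        want = all_leaves - want
    return want in t.bipartitions(include_trivial=True)


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds: symmetric difference of internal bipartitions."""
    if set(t1.leaf_names()) != set(t2.leaf_names()):
        raise ValueError("trees have different leaf sets")
    return len(t1.bipartitions() ^ t2.bipartitions())
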