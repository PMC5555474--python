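"""Distance-based phylogenetics: p-distance, Kimura two-parameter,
neighbor-joining, bootstrap supports and functional/pseudogene clade purity.

The K2P distance is d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q), with P and Q the
transition and transversion proportions over comparable (gap-free,
unambiguous) sites of a pair. Missing data follow either *pairwise*
deletion (each pair uses its own comparable columns) or *complete* deletion
(columns gapped in any sequence of the alignment are dropped for all
pairs). Neighbor-joining is the canonical Saitou-Nei agglomeration with a
deterministic lexicographic tie-break, so trees are reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .seqs import encode


# ---------------------------------------------------------------------------
# distances

def _codes(seq: str) -> np.ndarray:
    return encode(seq)


def _pair_counts(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None):
    ok = (a != 255) & (b != 255)
    if mask is not None:
        ok &= mask
    n = int(ok.sum())
    da, db = a[ok], b[ok]
    diff = da != db
    # encoding A=0,C=1,G=2,T=3: transitions (A<->G, C<->T) differ by exactly 2
    ts = int((diff & (np.abs(da.astype(int) - db.astype(int)) == 2)).sum())
    return n, int(diff.sum()), ts, int(diff.sum()) - ts


def p_distance(
    a: str,
    b: str,
    deletion: str = "pairwise",
    column_mask: np.ndarray | None = None,
) -> tuple[float, int]:
    """Proportion of differing sites among comparable sites.

    With ``deletion="complete"`` a ``column_mask`` from the full alignment
    must be supplied (True for columns gap-free in every sequence).
    Returns ``(distance, comparable_sites)``; distance is NaN when no site
    is comparable.
    """
    if len(a) != len(b):
        raise ValueError("gapped lengths differ")
    if deletion == "complete" and column_mask is None:
        raise ValueError("complete deletion requires the alignment column mask")
    n, ndiff, _, _ = _pair_counts(_codes(a), _codes(b), column_mask)
    if n == 0:
        return math.nan, 0
    return ndiff / n, n


def k2p_distance(
    a: str,
    b: str,
    deletion: str = "pairwise",
    column_mask: np.ndarray | None = None,
) -> float:
    """Kimura two-parameter distance; NaN when saturated (log arg <= 0)."""
    if len(a) != len(b):
        raise ValueError("gapped lengths differ")
    if deletion == "complete" and column_mask is None:
        raise ValueError("complete deletion requires the alignment column mask")
    n, _, ts, tv = _pair_counts(_codes(a), _codes(b), column_mask)
    if n == 0:
        return math.nan
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def complete_deletion_mask(alignment: dict[str, str]) -> np.ndarray:
    rows = [_codes(s) for s in alignment.values()]
    mat = np.vstack(rows)
    return np.all(mat != 255, axis=0)


def average_p_distance(alignment: dict[str, str], deletion: str = "pairwise") -> float:
    """Arithmetic mean of pairwise p-distances over defined pairs."""
    ids = sorted(alignment)
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    mask = complete_deletion_mask(alignment) if deletion == "complete" else None
    vals = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d, _ = p_distance(alignment[ids[i]], alignment[ids[j]], deletion, mask)
            if not math.isnan(d):
                vals.append(d)
    if not vals:
        raise ValueError("no defined pairs")
    return float(np.mean(vals))


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    model: str  # "p" | "k2p"
    deletion: str  # "pairwise" | "complete"
    comparable: np.ndarray | None = None

    def saturated_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                if math.isnan(self.d[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out


def distance_matrix(
    alignment: dict[str, str],
    model: str = "k2p",
    deletion: str = "pairwise",
) -> DistanceMatrix:
    ids = sorted(alignment)
    n = len(ids)
    mask = complete_deletion_mask(alignment) if deletion == "complete" else None
    d = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    codes = {i: _codes(alignment[i]) for i in ids}
    for i in range(n):
        for j in range(i + 1, n):
            if model == "p":
                dij, nij = p_distance(alignment[ids[i]], alignment[ids[j]], deletion, mask)
            else:
                nij, _, _, _ = _pair_counts(codes[ids[i]], codes[ids[j]], mask)
                dij = k2p_distance(alignment[ids[i]], alignment[ids[j]], deletion, mask)
            d[i, j] = d[j, i] = dij
            comp[i, j] = comp[j, i] = nij
    return DistanceMatrix(ids, d, model, deletion, comp)


# ---------------------------------------------------------------------------
# trees

@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree stored with a (possibly trifurcating) root node."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return sorted(n.name for n in self.root.leaves())

    def newick(self, *, supports: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            ln = node.length + 0.0  # normalise IEEE -0.0
            if node.is_leaf:
                return f"{node.name}:{ln:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = str(node.support) if (supports and node.support is not None) else ""
            return f"({inner}){label}:{ln:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        label = str(self.root.support) if (supports and self.root.support is not None) else ""
        return f"({inner}){label};"

    def _edge_clades(self) -> list[tuple[TreeNode, frozenset]]:
        """Every node below the root with the leaf set of its subtree."""
        out = []

        def walk(node: TreeNode):
            if node.is_leaf:
                leafset = frozenset([node.name])
            else:
                leafset = frozenset()
                for c in node.children:
                    leafset |= walk(c)
            out.append((node, leafset))
            return leafset

        for c in self.root.children:
            walk(c)
        return out

    def bipartitions(self) -> set[frozenset]:
        """Canonical non-trivial bipartitions (side not holding the first leaf)."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out = set()
        for _node, clade in self._edge_clades():
            if len(clade) < 2 or len(all_leaves - clade) < 2:
                continue
            side = clade if anchor not in clade else all_leaves - clade
            out.add(side)
        return out


def parse_newick(text: str) -> Tree:
    """Minimal Newick reader (names, branch lengths, internal labels)."""
    s = text.strip().rstrip(";")
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if s[pos] == ",":
                    pos += 1
                elif s[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        name = s[start:pos]
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",():;":
                pos += 1
            node.length = float(s[start:pos])
        if name:
            if node.children:
                node.support = int(float(name))
            else:
                node.name = name
        return node

    return Tree(parse_node())


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor-joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    (cluster key, cluster key) pair, cluster key being the smallest leaf id
    in the cluster. Negative branch lengths are clamped to zero with the
    deficit moved onto the sister branch.
    """
    sat = dm.saturated_pairs()
    if sat:
        raise ValueError(f"distance matrix has saturated/undefined entries: {sat}")
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least three taxa")
    nodes = [TreeNode(name=i) for i in dm.ids]
    keys = list(dm.ids)  # smallest leaf id per cluster, for tie-breaking
    d = dm.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                if q[ai, aj] <= qmin + 1e-12:
                    key = tuple(sorted((keys[active[ai]], keys[active[aj]])))
                    if best is None or key < best[0]:
                        best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        new = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        # distances from the new node to the remaining clusters
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, dnew])
        d = np.column_stack([d, np.append(dnew, 0.0)])
        nodes.append(new)
        keys.append(min(keys[i], keys[j]))
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(0.0, ln)
    order = sorted((a, b, c), key=lambda idx: keys[idx])
    return Tree(TreeNode(children=[nodes[idx] for idx in order]))


def bootstrap_support(
    alignment: dict[str, str],
    model: str = "k2p",
    n_replicates: int = 1000,
    rng_seed: int = 0,
    deletion: str = "pairwise",
) -> Tree:
    """NJ tree on the full alignment with bootstrap supports (0-100).

    Columns are resampled with replacement; the support of each internal
    edge is the percentage of successful replicate trees containing its
    bipartition. Replicates whose distance matrix has undefined entries are
    dropped and counted; a warning is issued when more than 5% drop.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    ids = sorted(alignment)
    ncol = len(next(iter(alignment.values())))
    tree = nj_tree(distance_matrix(alignment, model, deletion))
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(rng_seed)
    dropped = 0
    done = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        sub = {i: "".join(alignment[i][c] for c in cols) for i in ids}
        try:
            rep = nj_tree(distance_matrix(sub, model, deletion))
        except ValueError:
            dropped += 1
            continue
        done += 1
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1
    if dropped > 0.05 * n_replicates:
        warnings.warn(
            f"{dropped}/{n_replicates} bootstrap replicates dropped "
            "(undefined distances)",
            stacklevel=2,
        )
    all_leaves = frozenset(ids)
    anchor = min(all_leaves)
    for node, clade in tree._edge_clades():
        if node.is_leaf or len(clade) < 2 or len(all_leaves - clade) < 2:
            continue
        side = clade if anchor not in clade else all_leaves - clade
        node.support = int(round(100.0 * counts[side] / max(1, done)))
    return tree


def clade_purity(tree: Tree, labels: dict[str, str]) -> dict:
    """Does some edge separate functional from pseudogene leaves exactly?

    Returns ``is_bipartition_separating`` and ``best_split_impurity``: the
    minimum number of misplaced leaves over all edges of the tree.
    """
    leaves = tree.leaf_names()
    unlabeled = [x for x in leaves if x not in labels]
    if unlabeled:
        raise ValueError(f"unlabeled leaves: {unlabeled}")
    func = {x for x in leaves if labels[x] == "functional"}
    pseudo = {x for x in leaves if labels[x] == "pseudogene"}
    target = frozenset(func)
    best = min(len(func), len(pseudo))
    separating = False
    all_leaves = frozenset(leaves)
    for _node, clade in tree._edge_clades():
        other = all_leaves - clade
        if clade in (target, frozenset(pseudo)):
            separating = True
        impurity = min(
            len(clade & func) + len(other & pseudo),
            len(clade & pseudo) + len(other & func),
        )
        best = min(best, impurity)
    if separating:
        best = 0
    return {"is_bipartition_separating": separating, "best_split_impurity": best}
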