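"""Distance-based phylogenetics: p-distances, neighbor joining, bootstrap.

Protein sets (TnpB, Y1, SR) are related by pairwise p-distances over the
mutually ungapped columns of a multiple alignment; trees are built with
the classical neighbor-joining algorithm (Saitou–Nei Q criterion, ties to
the smallest index pair) and internal-edge support comes from Felsenstein
column-resampling bootstrap.  Negative NJ branch-length estimates are
clamped to zero and flagged.

Trees are kept as parent-pointer arrays with a small node class; Newick
serialisation writes support values as internal node labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import Alignment


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray                       # symmetric, zero diagonal
    low_support_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(d)).max() > 1e-12:
            raise ValueError("diagonal must be zero")
        self.d = d


@dataclass
class TreeNode:
    name: str = ""                      # taxon name for leaves
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.0                 # branch to the parent
    support: float | None = None        # bootstrap % for internal edges
    clamped: bool = False               # negative NJ estimate set to 0

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._nwk() for c in self.children)
        label = "" if self.support is None else f"{self.support:.0f}"
        return f"({inner}){label}:{self.length:.6g}"


def protein_distance(aln: Alignment, poisson_correction: bool = False,
                     min_comparable: int = 20) -> DistanceMatrix:
    """Pairwise p-distance over mutually ungapped columns.

    Pairs with fewer than min_comparable comparable columns are flagged;
    a pair with none raises, naming the pair.  With poisson_correction
    the distance is -ln(1 - p).
    """
    if aln.n_rows < 3:
        raise ValueError("need at least 3 sequences")
    n = aln.n_rows
    rows = np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in aln.rows])
    gap = ord("-")
    d = np.zeros((n, n))
    flagged = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = (rows[i] != gap) & (rows[j] != gap)
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {aln.ids[i]} and {aln.ids[j]}")
            if m < min_comparable:
                flagged.append((aln.ids[i], aln.ids[j]))
            p = float((rows[i][ok] != rows[j][ok]).sum()) / m
            if poisson_correction:
                if p >= 1.0:
                    raise ValueError("p-distance of 1 cannot be Poisson corrected")
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(list(aln.ids), d, flagged)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classical NJ; deterministic (ties to the smallest index pair).

    On an additive input matrix the tree realises the distances exactly.
    Returns an unrooted tree represented with a trifurcating root.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [TreeNode(name=t) for t in dm.ids]
    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _q, i, j = best
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        parent = TreeNode()
        for child, length in ((nodes[i], vi), (nodes[j], vj)):
            child.length = max(length, 0.0)
            child.clamped = length < 0
            parent.children.append(child)
        # new distances
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        for x in active:
            if x in (i, j):
                continue
            d[k, x] = d[x, k] = 0.5 * (d[i, x] + d[j, x] - d[i, j])
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [k]

    i, j, k = active
    vi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    vj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    vk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = TreeNode()
    for child, length in ((nodes[i], vi), (nodes[j], vj), (nodes[k], vk)):
        child.length = max(length, 0.0)
        child.clamped = length < 0
        root.children.append(child)
    return root


def bipartitions(tree: TreeNode) -> dict[frozenset[str], TreeNode]:
    """Internal-edge bipartitions, keyed by the smaller... by the child-side
    leaf set of each internal non-root edge."""
    out: dict[frozenset[str], TreeNode] = {}

    def walk(node: TreeNode, is_root: bool):
        for c in node.children:
            if not c.is_leaf():
                out[c.leaf_names()] = c
            walk(c, False)

    walk(tree, True)
    return out


def tree_path_lengths(tree: TreeNode) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths (for additivity checks)."""
    dists: dict[tuple[str, str], float] = {}

    def walk(node: TreeNode) -> dict[str, float]:
        if node.is_leaf():
            return {node.name: 0.0}
        sub = [walk(c) for c in node.children]
        for a in range(len(sub)):
            for b in range(a + 1, len(sub)):
                for la, da in sub[a].items():
                    for lb, db in sub[b].items():
                        key = (la, lb) if la < lb else (lb, la)
                        dists[key] = (da + node.children[a].length
                                      + db + node.children[b].length)
        merged = {}
        for c, s in zip(node.children, sub):
            for leaf, dist in s.items():
                merged[leaf] = dist + c.length
        return merged

    walk(tree)
    return dists


def bootstrap_support(aln: Alignment, b: int = 1000, seed: int = 0,
                      poisson_correction: bool = False) -> TreeNode:
    """NJ tree with Felsenstein bootstrap supports (percent of replicates
    containing the same bipartition); deterministic given the seed."""
    if b < 1:
        raise ValueError("need at least one bootstrap replicate")
    base_dm = protein_distance(aln, poisson_correction)
    tree = neighbor_joining(base_dm)
    target = bipartitions(tree)
    counts = {k: 0 for k in target}

    rng = np.random.default_rng(seed)
    ncols = aln.n_cols
    rows = [r for r in aln.rows]
    for _ in range(b):
        idx = rng.integers(0, ncols, size=ncols)
        rep_rows = ["".join(r[c] for c in idx) for r in rows]
        rep = Alignment(list(aln.ids), rep_rows)
        try:
            rep_dm = protein_distance(rep, poisson_correction)
        except ValueError:
            continue
        rep_tree = neighbor_joining(rep_dm)
        rep_bips = set(bipartitions(rep_tree))
        full = frozenset(aln.ids)
        for k in counts:
            if k in rep_bips or (full - k) in rep_bips:
                counts[k] += 1
    for k, node in target.items():
        node.support = 100.0 * counts[k] / b
    return tree


def root_on_outgroup(tree: TreeNode, outgroup_ids: set[str]) -> TreeNode:
    """Reroot on the edge separating the outgroup from the ingroup.

    Requires every outgroup taxon in the tree; prefers an edge whose
    bipartition equals the outgroup exactly, falling back to the edge
    that best separates outgroup from ingroup.  The tree is rebuilt (the
    input is not modified); the chosen edge's length is split in half.
    """
    leaves_all = tree.leaf_names()
    og = frozenset(outgroup_ids)
    missing = og - leaves_all
    if missing:
        raise ValueError(f"outgroup taxa absent from tree: {sorted(missing)}")

    parents: dict[int, TreeNode] = {}
    edges: list[TreeNode] = []

    def collect(node):
        for c in node.children:
            parents[id(c)] = node
            edges.append(c)
            collect(c)

    collect(tree)

    def edge_key(c: TreeNode):
        s = c.leaf_names()
        if s == og or (leaves_all - s) == og:
            return (2, 0.0)
        inside, wrong = len(s & og), len(s - og)
        return (1, inside - wrong - 1e-3 * len(s))

    best = max(edges, key=edge_key)
    parent = parents[id(best)]

    # undirected adjacency with edge attributes taken from the child side
    adj: dict[int, list[tuple[TreeNode, float, float | None]]] = {}

    def addedge(a, b, length, support):
        adj.setdefault(id(a), []).append((b, length, support))
        adj.setdefault(id(b), []).append((a, length, support))

    def walk(node):
        for c in node.children:
            addedge(node, c, c.length, c.support)
            walk(c)

    walk(tree)

    def build(node: TreeNode, come_from: TreeNode) -> TreeNode:
        nn = TreeNode(name=node.name)
        for nb, length, support in adj.get(id(node), []):
            if nb is come_from:
                continue
            c = build(nb, node)
            c.length = length
            c.support = support
            nn.children.append(c)
        return nn

    half = best.length / 2.0
    r1 = build(best, parent)
    r1.length = half
    r1.support = best.support
    r2 = build(parent, best)
    r2.length = half
    r2.support = best.support
    return TreeNode(children=[r1, r2])


def label_branches(tree: TreeNode, outgroup_ids: set[str],
                   support_min: float = 70.0) -> dict[str, str]:
    """Branch-group labels for the ingroup taxa.

    The tree is rooted on the outgroup; the maximal supported proper
    ingroup clades (support >= support_min) become groups labelled A, B, …
    in decreasing size; ingroup taxa not covered by any supported clade
    form one residual group.
    """
    rooted = root_on_outgroup(tree, outgroup_ids)
    og = set(outgroup_ids)
    groups: list[frozenset[str]] = []

    def walk(node):
        for c in node.children:
            s = c.leaf_names()
            if not (s - og):
                continue            # outgroup side
            if s & og:
                walk(c)             # mixed: descend
                continue
            if not c.is_leaf() and (c.support or 0.0) >= support_min \
                    and s != rooted.leaf_names() - og:
                groups.append(s)
            else:
                walk(c)

    walk(rooted)
    covered = set().union(*groups) if groups else set()
    residual = frozenset(set(tree.leaf_names()) - og - covered)
    if residual:
        groups.append(residual)
    groups.sort(key=lambda s: (-len(s), sorted(s)[0]))
    out = {}
    for label_i, s in enumerate(groups):
        label = chr(ord("A") + label_i)
        for taxon in sorted(s):
            out[taxon] = label
    return out


def write_phylip(dm: DistanceMatrix) -> str:
    """PHYLIP square distance-matrix format."""
    lines = [f"    {len(dm.ids)}"]
    for i, t in enumerate(dm.ids):
        row = " ".join(f"{x:.6f}" for x in dm.d[i])
        lines.append(f"{t[:10]:<10}  {row}")
    return "\n".join(lines) + "\n"
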