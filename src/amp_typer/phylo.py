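"""Trees and networks over AMP alleles.

Neighbor-joining trees with column-bootstrap support, trans-specific
polymorphism quantified as species mixture within supported clades, and
minimum-spanning haplotype networks on Hamming distances. A deterministic
center-star aligner is provided for the (rare, indel-containing) case where
input alleles are not already equal-length.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    model: str = "p"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")


def p_distance_matrix(seqs: dict[str, str], model: str = "p") -> DistanceMatrix:
    """Pairwise p-distances (optionally Jukes-Cantor corrected) with pairwise
    deletion of gap/ambiguous positions."""
    labels = sorted(seqs)
    arrs = [np.frombuffer(seqs[l].encode(), dtype=np.uint8) for l in labels]
    valid = [np.isin(a, np.frombuffer(b"ACGT", dtype=np.uint8)) for a in arrs]
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            L = int(both.sum())
            p = float((arrs[i][both] != arrs[j][both]).sum()) / L if L else 0.0
            if model == "jc":
                p = -0.75 * math.log(1 - 4 * p / 3) if p < 0.75 else float("inf")
            m[i, j] = m[j, i] = p
    return DistanceMatrix(labels=labels, matrix=m, model=model)


def hamming_distance_matrix(seqs: dict[str, str]) -> DistanceMatrix:
    labels = sorted(seqs)
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[labels[i]], seqs[labels[j]]
            if len(a) != len(b):
                raise ValueError("hamming distance needs equal lengths")
            d = sum(x != y for x, y in zip(a, b))
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels=labels, matrix=m, model="hamming")


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self


@dataclass
class Tree:
    root: TreeNode
    n_clamped: int = 0  # negative NJ branch lengths clamped to zero

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.root.leaves()]

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:.4g}"
            return f"({inner}){label}:{node.length:.6g}"
        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Non-trivial bipartitions, keyed canonically as the side *not*
        containing the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out = {}
        for node in self.root.postorder():
            if node is self.root or node.is_leaf():
                continue
            side = frozenset(lf.name for lf in node.leaves())
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue
            key = side if ref not in side else all_leaves - side
            out[key] = node
        return out


def nj_tree(dist: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The Q-criterion minimum is resolved toward the lexicographically lowest
    label pair; cluster labels are the smallest leaf name they contain.
    Negative branch lengths are clamped to zero and counted.
    """
    n = len(dist.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    nodes = [TreeNode(name=l) for l in dist.labels]
    labels = list(dist.labels)
    d = dist.matrix.astype(float).copy()
    active = list(range(n))
    clamped = 0

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for i, j in itertools.combinations(sorted(active, key=lambda x: labels[x]), 2):
            q = (m - 2) * d[i, j] - r[i] - r[j]
            key = (q, *sorted((labels[i], labels[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            clamped += 1
            li = 0.0
        if lj < 0:
            clamped += 1
            lj = 0.0
        nodes[i].length, nodes[j].length = li, lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_idx = len(nodes)
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new_idx, k] = d[k, new_idx] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        active = [k for k in active if k not in (i, j)] + [new_idx]

    i, j, k = sorted(active, key=lambda x: labels[x])
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        if ln < 0:
            clamped += 1
            ln = 0.0
        nodes[idx].length = ln
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return Tree(root=root, n_clamped=clamped)


def bootstrap_support(aligned: dict[str, str], n_reps: int = 1000,
                      seed: int | None = 0, model: str = "p",
                      mask_below: float | None = None) -> Tree:
    """NJ tree with column-bootstrap support percentages.

    Columns are resampled with replacement ``n_reps`` times; the support of
    each bipartition of the point-estimate tree is the percentage of
    replicate trees containing it. With ``mask_below`` set, supports at or
    below the threshold are blanked on output (the conventional ">50%" display
    rule).
    """
    point = nj_tree(p_distance_matrix(aligned, model))
    biparts = point.bipartitions()
    hits = {bp: 0 for bp in biparts}
    labels = sorted(aligned)
    L = len(aligned[labels[0]])
    rng = np.random.default_rng(seed)
    arrs = {l: np.frombuffer(aligned[l].encode(), np.uint8) for l in labels}
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep = {l: arrs[l][cols].tobytes().decode() for l in labels}
        rep_tree = nj_tree(p_distance_matrix(rep, model))
        rep_bp = set(rep_tree.bipartitions())
        for bp in hits:
            if bp in rep_bp:
                hits[bp] += 1
    for bp, node in biparts.items():
        support = 100.0 * hits[bp] / n_reps
        if mask_below is not None and support <= mask_below:
            node.support = None
        else:
            node.support = support
    return point


@dataclass
class CladeMixtureReport:
    rows: list[dict]
    fraction_mixed: float


def clade_species_mixture(tree: Tree, species_of: dict[str, str],
                          support_threshold: float = 50.0) -> CladeMixtureReport:
    """Species composition of every supported bipartition.

    For each non-trivial bipartition (with support above the threshold when
    supports are present) the smaller side's per-species allele counts are
    reported; a clade is *mixed* if both species occur in it — the signature
    of trans-specific polymorphism.
    """
    leaves = tree.leaf_names()
    missing = [l for l in leaves if l not in species_of]
    if missing:
        raise ValueError(f"unlabeled leaves: {missing}")
    all_set = frozenset(leaves)
    rows = []
    n_mixed = 0
    for bp, node in tree.bipartitions().items():
        if node.support is not None and node.support <= support_threshold:
            continue
        side = frozenset(lf.name for lf in node.leaves())
        small = side if len(side) <= len(all_set - side) else all_set - side
        comp: dict[str, int] = {}
        for l in sorted(small):
            comp[species_of[l]] = comp.get(species_of[l], 0) + 1
        mixed = len(comp) > 1
        n_mixed += mixed
        rows.append({"clade": ",".join(sorted(small)), "size": len(small),
                     "composition": comp, "mixed": mixed,
                     "support": node.support})
    frac = n_mixed / len(rows) if rows else 0.0
    return CladeMixtureReport(rows=rows, fraction_mixed=frac)


# ---------------------------------------------------------------------------
# minimum-spanning network


def mst_network(dist: DistanceMatrix, epsilon: float = 0.0):
    """Kruskal minimum spanning tree / epsilon-relaxed spanning network.

    Returns a deterministic edge list [(label_a, label_b, weight)]. With
    epsilon > 0, every non-tree edge whose weight is within ``epsilon`` of
    the weight at which its two endpoints' components were first joined is
    retained as well, turning the tree into a haplotype network.
    """
    labels = dist.labels
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    edges = sorted(
        ((dist.matrix[i, j], labels[i], labels[j], i, j)
         for i in range(n) for j in range(i + 1, n)),
        key=lambda e: (e[0], e[1], e[2]))
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mst = []
    join_weight: dict[frozenset, float] = {}
    for w, la, lb, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            mst.append((la, lb, float(w)))
            join_weight[frozenset((la, lb))] = float(w)
    if epsilon <= 0:
        return mst

    # bottleneck weight between two nodes = max edge on their MST path
    adj: dict[str, list[tuple[str, float]]] = {l: [] for l in labels}
    for la, lb, w in mst:
        adj[la].append((lb, w))
        adj[lb].append((la, w))

    def bottleneck(a, b):
        stack = [(a, 0.0)]
        seen = {a}
        while stack:
            node, mx = stack.pop()
            if node == b:
                return mx
            for nb, w in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append((nb, max(mx, w)))
        return float("inf")

    out = list(mst)
    in_mst = {frozenset((a, b)) for a, b, _ in mst}
    for w, la, lb, i, j in edges:
        if frozenset((la, lb)) in in_mst:
            continue
        if w <= bottleneck(la, lb) + epsilon:
            out.append((la, lb, float(w)))
    return out


# ---------------------------------------------------------------------------
# center-star multiple alignment


def _nw_align(a: str, b: str, match: int = 1, mismatch: int = -1,
              gap: int = -2) -> tuple[str, str]:
    """Global Needleman-Wunsch with linear gaps and deterministic traceback
    (diagonal preferred, then gap-in-b, then gap-in-a)."""
    la, lb = len(a), len(b)
    score = np.zeros((la + 1, lb + 1), dtype=np.int64)
    score[:, 0] = gap * np.arange(la + 1)
    score[0, :] = gap * np.arange(lb + 1)
    for i in range(1, la + 1):
        si = score[i - 1]
        row = score[i]
        ai = a[i - 1]
        for j in range(1, lb + 1):
            diag = si[j - 1] + (match if ai == b[j - 1] else mismatch)
            up = si[j] + gap
            left = row[j - 1] + gap
            row[j] = max(diag, up, left)
    out_a, out_b = [], []
    i, j = la, lb
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (
                match if a[i - 1] == b[j - 1] else mismatch):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def _edit_distance(a: str, b: str) -> int:
    try:
        import edlib
        return edlib.align(a, b)["editDistance"]
    except ImportError:  # pragma: no cover - edlib is normally present
        la, lb = len(a), len(b)
        prev = list(range(lb + 1))
        for i in range(1, la + 1):
            cur = [i] + [0] * lb
            for j in range(1, lb + 1):
                cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                             prev[j - 1] + (a[i - 1] != b[j - 1]))
            prev = cur
        return prev[lb]


def msa_center_star(seqs: dict[str, str]) -> dict[str, str]:
    """Center-star multiple alignment.

    The center is the sequence minimizing total pairwise edit distance (ties
    to the lexicographically smallest label); pairwise global alignments to
    the center are merged under "once a gap, always a gap". Equal-length
    inputs with no indels come back unchanged.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    labels = sorted(seqs)
    if len(labels) == 1:
        return dict(seqs)
    totals = {}
    for l in labels:
        totals[l] = sum(_edit_distance(seqs[l], seqs[m]) for m in labels if m != l)
    center = min(labels, key=lambda l: (totals[l], l))

    master = seqs[center]           # center with accumulated gaps
    aligned: dict[str, str] = {center: master}
    for l in labels:
        if l == center:
            continue
        ac, al = _nw_align(master.replace("-", ""), seqs[l])
        # merge the gap pattern of the current master with the new pairwise
        # alignment: each output column consumes a master column ("old"), a
        # pairwise column ("new"), or both
        cols = []
        mi = pi = 0
        while mi < len(master) or pi < len(ac):
            if mi < len(master) and master[mi] == "-":
                cols.append(("old", mi, -1))
                mi += 1
            elif pi < len(ac) and ac[pi] == "-":
                cols.append(("new", -1, pi))
                pi += 1
            else:
                cols.append(("both", mi, pi))
                mi += 1
                pi += 1
        for key, s in aligned.items():
            aligned[key] = "".join(
                s[m] if kind in ("old", "both") else "-" for kind, m, _ in cols)
        aligned[l] = "".join(
            al[p] if kind in ("new", "both") else "-" for kind, _, p in cols)
        master = aligned[center]
    return {l: aligned[l] for l in labels}
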