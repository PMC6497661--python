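"""Morphology dendrograms, tanglegram untangling, and the tip-displacement test.

A UPGMA dendrogram built from pairwise Procrustes distances is co-rotated
against the phylogeny to optimize tip matching (hill climbing over node
rotations, exact for small trees); discordance is summarized as the mean
absolute difference in tip position ("tip displacement", TD) and compared to
a null distribution from multivariate Brownian-motion landmark simulations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .disparity import estimate_rate_matrix, simulate_bm_shape_matrix
from .landmarks import pairwise_procrustes_distances
from .trees import PhyloTree

__all__ = ["OrderedTree", "TanglegramResult", "upgma", "untangle",
           "tip_displacement", "displacement_null_test", "plot_tanglegram"]


class OrderedTree:
    """A rooted tree whose child order is meaningful and rotatable."""

    def __init__(self, children: list[list[int]], root: int,
                 labels: dict[int, str], heights: dict[int, float] | None = None):
        self.children = [list(c) for c in children]
        self.root = root
        self.labels = dict(labels)
        self.heights = dict(heights or {})

    @classmethod
    def from_phylo(cls, tree: PhyloTree) -> "OrderedTree":
        labels = {int(t): l for t, l in zip(tree.tips, tree.tip_labels)}
        heights = {i: float(d) for i, d in enumerate(tree.depths)}
        return cls(tree.children, tree.root, labels, heights)

    @classmethod
    def from_linkage(cls, Z: np.ndarray, labels: list[str]) -> "OrderedTree":
        n = len(labels)
        children: list[list[int]] = [[] for _ in range(2 * n - 1)]
        heights = {i: 0.0 for i in range(n)}
        for i, (a, b, h, _) in enumerate(Z):
            children[n + i] = [int(a), int(b)]
            heights[n + i] = float(h) / 2.0   # ultrametric node height
        return cls(children, 2 * n - 2, {i: l for i, l in enumerate(labels)},
                   heights)

    def copy(self) -> "OrderedTree":
        return OrderedTree(self.children, self.root, self.labels, self.heights)

    @property
    def internal_nodes(self) -> list[int]:
        return sorted(i for i, c in enumerate(self.children) if c)

    def tip_order(self) -> list[str]:
        order, stack = [], [self.root]
        while stack:
            nd = stack.pop()
            if self.children[nd]:
                stack.extend(reversed(self.children[nd]))
            else:
                order.append(self.labels[nd])
        return order

    def subtree_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}

        def rec(nd: int) -> int:
            sizes[nd] = sum(rec(c) for c in self.children[nd]) if self.children[nd] else 1
            return sizes[nd]

        rec(self.root)
        return sizes

    def cophenetic_distances(self) -> tuple[list[str], np.ndarray]:
        """Tip labels and matrix of 2 x height of the MRCA (ultrametric trees)."""
        tips = [i for i in range(len(self.children)) if not self.children[i]]
        labels = [self.labels[t] for t in tips]
        pos = {t: i for i, t in enumerate(tips)}
        D = np.zeros((len(tips), len(tips)))

        def rec(nd: int) -> list[int]:
            if not self.children[nd]:
                return [nd]
            groups = [rec(c) for c in self.children[nd]]
            for ga, gb in itertools.combinations(groups, 2):
                for x in ga:
                    for y in gb:
                        D[pos[x], pos[y]] = D[pos[y], pos[x]] = 2 * self.heights[nd]
            return [x for g in groups for x in g]

        rec(self.root)
        return labels, D

    def to_newick(self) -> str:
        def rec(nd: int) -> str:
            h = self.heights.get(nd, 0.0)
            if not self.children[nd]:
                return self.labels[nd].replace(" ", "_")
            inner = ",".join(
                f"{rec(c)}:{abs(self.heights.get(c, 0.0) - h):.10g}"
                for c in self.children[nd])
            return f"({inner})"
        return rec(self.root) + ";"


@dataclass
class TanglegramResult:
    tree_order: list[str]
    dendrogram_order: list[str]
    displacements: dict[str, int]
    tip_displacement: float
    inversions: dict[str, int]
    null_tds: np.ndarray = field(default_factory=lambda: np.empty(0))
    p_value: float | None = None
    n_sim: int = 0
    seed: int | None = None


# ----------------------------------------------------------------------- UPGMA

def upgma(dist: np.ndarray, labels: list[str] | None = None) -> OrderedTree:
    """Average-linkage (UPGMA) dendrogram with ultrametric node heights.

    Node heights are half the merge distance, so cophenetic distances
    reproduce ultrametric inputs exactly.  Scipy's deterministic lowest-index
    merge resolves ties.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.abs(D - D.T).max() > 1e-8:
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0) or np.any(D < 0):
        raise ValueError("distances must be nonnegative with zero diagonal")
    labels = list(labels or [str(i) for i in range(len(D))])
    Z = hierarchy.linkage(squareform(0.5 * (D + D.T), checks=False),
                          method="average")
    return OrderedTree.from_linkage(Z, labels)


# ------------------------------------------------------------------ untangling

def _objective(order_a: list[str], order_b: list[str]) -> float:
    pos_b = {l: i for i, l in enumerate(order_b)}
    return float(sum((i - pos_b[l]) ** 2 for i, l in enumerate(order_a)))


def _optimize_side(tree: OrderedTree, other_order: list[str]) -> None:
    """Exact one-sided rotation optimization by interval dynamic programming."""
    pos = {l: i for i, l in enumerate(other_order)}
    sizes = tree.subtree_sizes()
    cost_memo: dict[tuple[int, int], float] = {}
    choice: dict[tuple[int, int], tuple] = {}

    def cost(nd: int, start: int) -> float:
        key = (nd, start)
        if key in cost_memo:
            return cost_memo[key]
        if not tree.children[nd]:
            c = float((start - pos[tree.labels[nd]]) ** 2)
            cost_memo[key] = c
            return c
        best, best_perm = np.inf, None
        for perm in itertools.permutations(tree.children[nd]):
            s, off = 0.0, start
            for ch in perm:
                s += cost(ch, off)
                off += sizes[ch]
                if s >= best:
                    break
            if s < best:
                best, best_perm = s, perm
        cost_memo[key] = best
        choice[key] = best_perm
        return best

    cost(tree.root, 0)

    def apply(nd: int, start: int) -> None:
        if not tree.children[nd]:
            return
        perm = choice[(nd, start)]
        tree.children[nd] = list(perm)
        off = start
        for ch in perm:
            apply(ch, off)
            off += sizes[ch]

    apply(tree.root, 0)


def _exact_untangle(a: OrderedTree, b: OrderedTree) -> None:
    """Joint brute force over all child permutations of both trees (small trees)."""

    def configs(t: OrderedTree):
        nodes = t.internal_nodes
        for combo in itertools.product(
                *[list(itertools.permutations(t.children[nd])) for nd in nodes]):
            for nd, perm in zip(nodes, combo):
                t.children[nd] = list(perm)
            yield

    best = np.inf
    best_ca = best_cb = None
    for _ in configs(a):
        oa = a.tip_order()
        for _ in configs(b):
            obj = _objective(oa, b.tip_order())
            if obj < best:
                best = obj
                best_ca = [list(c) for c in a.children]
                best_cb = [list(c) for c in b.children]
    a.children, b.children = best_ca, best_cb


def untangle(tree: PhyloTree | OrderedTree, dendrogram: OrderedTree,
             max_passes: int = 10) -> tuple[OrderedTree, OrderedTree]:
    """Co-rotate a phylogeny and a dendrogram to optimize tip matching.

    Minimizes the sum of squared differences between matched tip positions by
    alternating exact one-sided rotation optimization (interval DP) over both
    structures; instances with few internal nodes are solved by joint
    enumeration.  The objective never increases.
    """
    a = OrderedTree.from_phylo(tree) if isinstance(tree, PhyloTree) else tree.copy()
    b = dendrogram.copy()
    la, lb = set(a.tip_order()), set(b.tip_order())
    if la != lb:
        raise ValueError(f"tip label mismatch: {sorted(la ^ lb)}")
    n_int = len(a.internal_nodes) + len(b.internal_nodes)
    if n_int <= 14 and all(len(a.children[nd]) <= 3 for nd in a.internal_nodes) \
            and all(len(b.children[nd]) <= 3 for nd in b.internal_nodes):
        _exact_untangle(a, b)
        return a, b
    obj = _objective(a.tip_order(), b.tip_order())
    for _ in range(max_passes):
        _optimize_side(a, b.tip_order())
        _optimize_side(b, a.tip_order())
        new_obj = _objective(a.tip_order(), b.tip_order())
        if new_obj >= obj - 1e-12:
            break
        obj = new_obj
    return a, b


# ------------------------------------------------------------- displacement

def tip_displacement(order_a: list[str], order_b: list[str]):
    """Per-species |rank difference| between two tip orders and their mean TD."""
    if len(set(order_a)) != len(order_a) or len(set(order_b)) != len(order_b):
        raise ValueError("duplicate labels in tip order")
    if set(order_a) != set(order_b):
        raise ValueError(f"label mismatch: {sorted(set(order_a) ^ set(order_b))}")
    pos_b = {l: i for i, l in enumerate(order_b)}
    disp = {l: abs(i - pos_b[l]) for i, l in enumerate(order_a)}
    return disp, float(np.mean(list(disp.values())))


def _inversions(order_a: list[str], order_b: list[str]) -> dict[str, int]:
    ra = {l: i for i, l in enumerate(order_a)}
    rb = {l: i for i, l in enumerate(order_b)}
    labels = order_a
    out = {}
    for l in labels:
        out[l] = sum(1 for m in labels if m != l
                     and (ra[l] - ra[m]) * (rb[l] - rb[m]) < 0)
    return out


def _observed_td(tree: PhyloTree, D: np.ndarray) -> TanglegramResult:
    dend = upgma(D, tree.tip_labels)
    a, b = untangle(tree, dend)
    oa, ob = a.tip_order(), b.tip_order()
    disp, td = tip_displacement(oa, ob)
    return TanglegramResult(tree_order=oa, dendrogram_order=ob,
                            displacements=disp, tip_displacement=td,
                            inversions=_inversions(oa, ob))


def displacement_null_test(tree: PhyloTree, mean_shapes: np.ndarray,
                           n_sim: int = 1000, seed: int = 0,
                           species: list[str] | None = None) -> TanglegramResult:
    """Tip-displacement test against a multivariate Brownian-motion null.

    The observed TD comes from UPGMA on pairwise Procrustes distances,
    untangling, and rank displacement; the null distribution repeats the
    identical pipeline on ``n_sim`` BM landmark simulations with the rate
    matrix estimated from the data.  p is the fraction of null TDs strictly
    lower (better phylogeny-morphology match) than observed.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    shapes = np.asarray(mean_shapes, dtype=float)
    species = list(species or tree.tip_labels)
    idx_in_tree = {l: i for i, l in enumerate(tree.tip_labels)}
    shapes = shapes[np.argsort([idx_in_tree[s] for s in species])]
    n, k, _ = shapes.shape
    result = _observed_td(tree, pairwise_procrustes_distances(shapes))
    rate = estimate_rate_matrix(tree, shapes.reshape(n, -1))
    sims = simulate_bm_shape_matrix(tree, rate, k, n_sim, seed)
    null_tds = np.empty(n_sim)
    for s in range(n_sim):
        null_tds[s] = _observed_td(
            tree, pairwise_procrustes_distances(sims[s])).tip_displacement
    result.null_tds = null_tds
    result.p_value = float(np.mean(null_tds < result.tip_displacement))
    result.n_sim = n_sim
    result.seed = seed
    return result


def plot_tanglegram(result: TanglegramResult, path=None, ax=None):
    """Side-by-side tip orders with dotted links between matching species."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 0.18 * len(result.tree_order) + 1))
    pos_b = {l: i for i, l in enumerate(result.dendrogram_order)}
    n = len(result.tree_order)
    for i, label in enumerate(result.tree_order):
        ax.plot([0, 1], [n - i, n - pos_b[label]], "k:", lw=0.7)
        ax.text(-0.02, n - i, label, ha="right", va="center", fontsize=6)
        ax.text(1.02, n - pos_b[label], label, ha="left", va="center",
                fontsize=6)
    ax.set_xlim(-0.6, 1.6)
    ax.axis("off")
    title = f"TD = {result.tip_displacement:.2f}"
    if result.p_value is not None:
        title += f", p = {result.p_value:.3f}"
    ax.set_title(title, fontsize=9)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
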