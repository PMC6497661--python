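"""Rooted, time-calibrated phylogenies as lightweight array structures.

Newick/NEXUS parsing is delegated to dendropy; everything that sits in a hot
loop (tip covariances, descendant masks, regime paintings) is precomputed into
numpy arrays.  Branches are identified by the id of the node *below* them, so
every node except the root names exactly one branch.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["PhyloTree", "prune_and_match"]


class PhyloTree:
    """A rooted tree with branch lengths and labelled tips.

    Parameters
    ----------
    parent : array of int
        ``parent[i]`` is the parent node of node ``i`` (-1 for the root).
    length : array of float
        Length of the branch above each node (0 for the root).
    tip_labels : dict
        Mapping node id -> label for every leaf node.
    """

    def __init__(self, parent: Sequence[int], length: Sequence[float],
                 tip_labels: dict[int, str]):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=float)
        self.n_nodes = len(self.parent)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        root = -1
        for i, p in enumerate(self.parent):
            if p < 0:
                root = i
            else:
                self.children[p].append(i)
        if root < 0:
            raise ValueError("tree has no root")
        self.root = root
        self.tips = np.array([i for i in range(self.n_nodes) if not self.children[i]],
                             dtype=np.int64)
        self.n_tips = len(self.tips)
        self.tip_labels = [tip_labels[i] for i in self.tips]
        self._tip_rank = {node: r for r, node in enumerate(self.tips)}
        self._cache: dict[str, object] = {}

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(dtree)

    @classmethod
    def from_file(cls, path, schema: str = "newick") -> "PhyloTree":
        dtree = dendropy.Tree.get(path=str(path), schema=schema)
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "PhyloTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        length = np.zeros(len(nodes))
        labels: dict[int, str] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                length[i] = float(nd.edge.length or 0.0)
            if nd.is_leaf():
                labels[i] = nd.taxon.label if nd.taxon is not None else f"t{i}"
        return cls(parent, length, labels)

    def to_newick(self) -> str:
        out = io.StringIO()

        def rec(node: int) -> None:
            if self.children[node]:
                out.write("(")
                for j, c in enumerate(self.children[node]):
                    if j:
                        out.write(",")
                    rec(c)
                out.write(")")
            else:
                out.write(self.tip_labels[self._tip_rank[node]].replace(" ", "_"))
            if node != self.root:
                out.write(f":{self.length[node]:.12g}")

        rec(self.root)
        out.write(";")
        return out.getvalue()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ----------------------------------------------------------- traversals
    @property
    def preorder(self) -> np.ndarray:
        if "preorder" not in self._cache:
            order = []
            stack = [self.root]
            while stack:
                nd = stack.pop()
                order.append(nd)
                stack.extend(reversed(self.children[nd]))
            self._cache["preorder"] = np.array(order, dtype=np.int64)
        return self._cache["preorder"]

    @property
    def postorder(self) -> np.ndarray:
        if "postorder" not in self._cache:
            self._cache["postorder"] = self.preorder[::-1].copy()
        return self._cache["postorder"]

    @property
    def depths(self) -> np.ndarray:
        """Time from the root to each node (root = 0)."""
        if "depths" not in self._cache:
            d = np.zeros(self.n_nodes)
            for nd in self.preorder:
                if nd != self.root:
                    d[nd] = d[self.parent[nd]] + self.length[nd]
            self._cache["depths"] = d
        return self._cache["depths"]

    @property
    def depth(self) -> float:
        """Total tree depth (maximum tip depth)."""
        return float(self.depths[self.tips].max())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        td = self.depths[self.tips]
        return bool(np.ptp(td) <= rel_tol * max(td.max(), 1e-300))

    @property
    def tip_masks(self) -> np.ndarray:
        """(n_nodes, n_tips) boolean: tip j descends from (or is) node i."""
        if "tip_masks" not in self._cache:
            m = np.zeros((self.n_nodes, self.n_tips), dtype=bool)
            for r, t in enumerate(self.tips):
                m[t, r] = True
            for nd in self.postorder:
                for c in self.children[nd]:
                    m[nd] |= m[c]
            self._cache["tip_masks"] = m
        return self._cache["tip_masks"]

    @property
    def branch_nodes(self) -> np.ndarray:
        """Ids of all non-root nodes, i.e. valid branch ids."""
        if "branch_nodes" not in self._cache:
            self._cache["branch_nodes"] = np.array(
                [i for i in self.preorder if i != self.root], dtype=np.int64)
        return self._cache["branch_nodes"]

    # --------------------------------------------------------- covariances
    @property
    def vcv(self) -> np.ndarray:
        """Brownian-motion tip covariance C: shared root-to-tip path lengths."""
        if "vcv" not in self._cache:
            m = self.tip_masks.astype(float)
            C = np.zeros((self.n_tips, self.n_tips))
            for nd in self.branch_nodes:
                C += self.length[nd] * np.outer(m[nd], m[nd])
            self._cache["vcv"] = C
        return self._cache["vcv"]

    @property
    def mrca_depths(self) -> np.ndarray:
        """Depth of the MRCA of each tip pair (equals C for clock trees)."""
        return self.vcv

    @property
    def patristic(self) -> np.ndarray:
        d = self.depths[self.tips]
        return d[:, None] + d[None, :] - 2.0 * self.vcv

    # -------------------------------------------------------------- editing
    def rescaled(self, new_depth: float = 1.0) -> "PhyloTree":
        """Return a copy with all branch lengths multiplied so depth == new_depth."""
        f = new_depth / self.depth
        labels = {t: lab for t, lab in zip(self.tips, self.tip_labels)}
        return PhyloTree(self.parent.copy(), self.length * f, labels)

    def prune_to(self, keep: Iterable[str]) -> "PhyloTree":
        """Induced subtree on the given tip labels (suppressing unifurcations)."""
        keep = set(keep)
        missing = keep - set(self.tip_labels)
        if missing:
            raise ValueError(f"labels not in tree: {sorted(missing)}")
        keep_ranks = {self._tip_rank[t] for t in self.tips
                      if self.tip_labels[self._tip_rank[t]] in keep}
        wanted = np.zeros(self.n_tips, dtype=bool)
        wanted[list(keep_ranks)] = True
        counts = self.tip_masks[:, wanted].sum(axis=1)
        # new root: smallest subtree containing every kept tip
        full = [nd for nd in range(self.n_nodes) if counts[nd] == wanted.sum()]
        new_root = min(full, key=lambda nd: self.tip_masks[nd].sum())
        parent_out, length_out, labels_out = [], [], {}

        def build(node: int, parent_idx: int, stem: float) -> None:
            live = [c for c in self.children[node] if counts[c] > 0]
            if not self.children[node] or (node != new_root and not live):
                idx = len(parent_out)
                parent_out.append(parent_idx)
                length_out.append(stem)
                labels_out[idx] = self.tip_labels[self._tip_rank[node]]
                return
            if len(live) == 1 and node != new_root:   # suppress unifurcation
                build(live[0], parent_idx, stem + self.length[live[0]])
                return
            idx = len(parent_out)
            parent_out.append(parent_idx)
            length_out.append(stem)
            for c in live:
                build(c, idx, self.length[c])

        build(new_root, -1, 0.0)
        return PhyloTree(parent_out, length_out, labels_out)

    def mrca(self, labels: Iterable[str]) -> int:
        ranks = [self.tip_labels.index(l) for l in labels]
        mask = np.zeros(self.n_tips, dtype=bool)
        mask[ranks] = True
        best, best_size = self.root, self.n_tips + 1
        for nd in range(self.n_nodes):
            m = self.tip_masks[nd]
            if mask[m].sum() == mask.sum() and m.sum() < best_size:
                best, best_size = nd, m.sum()
        return best

    def reorder_index(self, labels: Sequence[str]) -> np.ndarray:
        """Indices mapping this tree's tip order onto ``labels`` order."""
        pos = {l: i for i, l in enumerate(self.tip_labels)}
        try:
            return np.array([pos[l] for l in labels], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"label {exc} not among tree tips") from exc

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_tips={self.n_tips}, depth={self.depth:.4g})"


def _normalize(name: str) -> str:
    return "_".join(str(name).strip().split())


def prune_and_match(tree: PhyloTree, species: Sequence[str]):
    """Prune a tree to the species shared with ``species``.

    Names are normalized (trimmed, internal whitespace collapsed to ``_``);
    exact matches are preferred, then case-insensitive ones.  Returns the
    pruned tree and a report dict listing dropped tips and unmatched species.
    """
    tip_norm = {_normalize(l): l for l in tree.tip_labels}
    tip_lower = {k.lower(): v for k, v in tip_norm.items()}
    matched, unmatched, case_fixed = [], [], []
    for sp in species:
        key = _normalize(sp)
        if key in tip_norm:
            matched.append(tip_norm[key])
        elif key.lower() in tip_lower:
            matched.append(tip_lower[key.lower()])
            case_fixed.append(sp)
        else:
            unmatched.append(sp)
    matched = list(dict.fromkeys(matched))
    if len(matched) < 2:
        raise ValueError("fewer than 2 species shared between tree and data")
    pruned = tree.prune_to(matched)
    report = {
        "kept": matched,
        "dropped_tips": sorted(set(tree.tip_labels) - set(matched)),
        "unmatched_species": unmatched,
        "case_insensitive_matches": case_fixed,
    }
    return pruned, report
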