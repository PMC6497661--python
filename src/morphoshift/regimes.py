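"""Regime paintings: per-branch (segmented) assignments of selective regimes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trees import PhyloTree

__all__ = ["RegimePainting"]


@dataclass
class RegimePainting:
    """Assignment of every branch (possibly split at change points) to a state.

    ``segments[branch] = [(t_start, t_end, state), ...]`` in absolute time from
    the root, covering the branch contiguously; ``root_state`` is the state at
    the root itself.
    """

    segments: dict[int, list[tuple[float, float, str]]]
    states: list[str]
    root_state: str
    source: str = "unknown"

    def validate(self, tree: PhyloTree) -> None:
        depths = tree.depths
        for b in tree.branch_nodes:
            segs = self.segments.get(int(b))
            if not segs:
                raise ValueError(f"branch {b} not covered by painting")
            t0, t1 = depths[tree.parent[b]], depths[b]
            if abs(segs[0][0] - t0) > 1e-8 or abs(segs[-1][1] - t1) > 1e-8:
                raise ValueError(f"branch {b} segments do not span the branch")
            for (a0, a1, _), (b0, _, _) in zip(segs, segs[1:]):
                if abs(a1 - b0) > 1e-8:
                    raise ValueError(f"branch {b} segments overlap or leave gaps")

    def tip_state(self, tree: PhyloTree) -> dict[str, str]:
        out = {}
        for r, t in enumerate(tree.tips):
            out[tree.tip_labels[r]] = self.segments[int(t)][-1][2]
        return out

    @classmethod
    def single_state(cls, tree: PhyloTree, state: str = "0") -> "RegimePainting":
        depths = tree.depths
        segs = {int(b): [(float(depths[tree.parent[b]]), float(depths[b]), state)]
                for b in tree.branch_nodes}
        return cls(segments=segs, states=[state], root_state=state,
                   source="constant")

    def n_regimes(self) -> int:
        used = {self.root_state}
        for segs in self.segments.values():
            used.update(s for _, _, s in segs)
        return len(used)

    def to_simmap_newick(self, tree: PhyloTree) -> str:
        """SIMMAP-style annotated Newick: branch comments {state,duration:...}."""

        def annot(b: int) -> str:
            parts = ",".join(f"{s}:{t1 - t0:.10g}" for t0, t1, s in self.segments[int(b)])
            return "{" + parts + "}"

        rank = {node: r for r, node in enumerate(tree.tips)}

        def rec(node: int) -> str:
            if tree.children[node]:
                inner = ",".join(rec(c) for c in tree.children[node])
                s = f"({inner})"
            else:
                s = tree.tip_labels[rank[node]].replace(" ", "_")
            if node != tree.root:
                s += f":{annot(node)}{tree.length[node]:.10g}"
            return s

        return rec(tree.root) + ";"
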