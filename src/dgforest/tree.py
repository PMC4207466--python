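"""Rooted morphology tree container and topology utilities.

A :class:`MorphTree` stores node coordinates, parent links (root has
parent -1 and index 0), per-node diameters and optional per-node layer
tags.  Topology helpers (branch decomposition, path lengths, branch
orders) are shared by the growth and morphometrics modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["MorphTree"]


@dataclass
class MorphTree:
    coords: np.ndarray                 # (n, 3) um
    parent: np.ndarray                 # (n,) int, parent[0] == -1
    diam: np.ndarray | None = None     # (n,) um
    layer: np.ndarray | None = None    # (n,) int8 LayerLabel codes
    cell_id: int | None = None
    subgroup: int | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.parent = np.asarray(self.parent, dtype=int)
        if self.diam is None:
            self.diam = np.ones(self.n_nodes)
        self.validate()

    # -- structure -------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    def validate(self) -> None:
        n = self.n_nodes
        if self.parent.shape != (n,):
            raise ValueError("parent/coords length mismatch")
        if n == 0 or self.parent[0] != -1:
            raise ValueError("root must be node 0 with parent -1")
        if np.sum(self.parent == -1) != 1:
            raise ValueError("exactly one root required")
        if np.any((self.parent[1:] < 0) | (self.parent[1:] >= n)):
            raise ValueError("parent index out of range")
        # acyclicity / connectivity via pointer-jumping to the root
        anc = self.parent.copy()
        for _ in range(int(np.ceil(np.log2(max(n, 2)))) + 1):
            anc = np.where(anc > 0, anc[np.clip(anc, 0, n - 1)], anc)
        if np.any(anc[1:] > 0):
            raise ValueError("parent links contain a cycle")

    @property
    def n_children(self) -> np.ndarray:
        cnt = np.zeros(self.n_nodes, dtype=int)
        np.add.at(cnt, self.parent[1:], 1)
        return cnt

    @property
    def tips(self) -> np.ndarray:
        return np.nonzero(self.n_children == 0)[0]

    @property
    def branch_point_nodes(self) -> np.ndarray:
        """Non-root nodes with two or more children."""
        bp = np.nonzero(self.n_children >= 2)[0]
        return bp[bp != 0]

    @property
    def n_stems(self) -> int:
        return int(self.n_children[0])

    # -- metric ----------------------------------------------------------
    @property
    def edge_lengths(self) -> np.ndarray:
        """Length of the edge to the parent (0 for the root)."""
        el = np.zeros(self.n_nodes)
        el[1:] = np.linalg.norm(self.coords[1:] - self.coords[self.parent[1:]], axis=1)
        return el

    @property
    def total_length(self) -> float:
        return float(self.edge_lengths.sum())

    @property
    def path_length(self) -> np.ndarray:
        """Arc length from the root to each node (nodes are topologically
        sorted by construction: parent[i] < i)."""
        el = self.edge_lengths
        pl = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            pl[i] = pl[self.parent[i]] + el[i]
        return pl

    # -- branch decomposition -------------------------------------------
    def topological_points(self) -> np.ndarray:
        """Root, branch points and tips."""
        nc = self.n_children
        mask = (nc == 0) | (nc >= 2)
        mask[0] = True
        return np.nonzero(mask)[0]

    def branches(self) -> list[np.ndarray]:
        """Paths (node-index arrays) between consecutive topological
        points, each running from the proximal topological point to the
        distal one."""
        nc = self.n_children
        topo = (nc == 0) | (nc >= 2)
        topo[0] = True
        out = []
        ends = np.nonzero(topo)[0]
        for e in ends:
            if e == 0:
                continue
            path = [e]
            j = self.parent[e]
            while not topo[j]:
                path.append(j)
                j = self.parent[j]
            path.append(j)
            out.append(np.array(path[::-1]))
        return out

    def branch_order(self) -> np.ndarray:
        """Number of branch points on the root-to-node path (exclusive
        of the node itself)."""
        nc = self.n_children
        order = np.zeros(self.n_nodes, dtype=int)
        for i in range(1, self.n_nodes):
            p = self.parent[i]
            order[i] = order[p] + (1 if (p != 0 and nc[p] >= 2) else 0)
        return order

    def subtree_tip_counts(self) -> np.ndarray:
        """Number of terminal tips in the subtree rooted at each node."""
        nc = self.n_children
        cnt = np.where(nc == 0, 1, 0).astype(int)
        for i in range(self.n_nodes - 1, 0, -1):
            cnt[self.parent[i]] += cnt[i]
        return cnt

    def copy(self) -> "MorphTree":
        return MorphTree(
            coords=self.coords.copy(),
            parent=self.parent.copy(),
            diam=None if self.diam is None else self.diam.copy(),
            layer=None if self.layer is None else self.layer.copy(),
            cell_id=self.cell_id,
            subgroup=self.subgroup,
        )
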