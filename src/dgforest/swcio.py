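"""Reading and writing morphologies in the SWC format.

SWC is the community-standard columnar text format for neuronal
morphologies: one node per line with columns
``id type x y z radius parent``, 1-based ids, parent -1 for the root.
The writer emits type 1 (soma) for the root and type 3 (basal/granule
dendrite) elsewhere; the reader is tolerant of comment headers,
whitespace dialects and forward-referenced parents, and rejects cyclic
or multi-root files.
"""

from __future__ import annotations

import numpy as np

from .tree import MorphTree

__all__ = ["write_swc", "read_swc"]


def write_swc(tree: MorphTree, path) -> None:
    """Write a :class:`MorphTree` as a standard SWC file."""
    n = tree.n_nodes
    diam = tree.diam if tree.diam is not None else np.ones(n)
    with open(path, "w") as fh:
        fh.write("# SWC morphology written by dgforest\n")
        fh.write("# id type x y z radius parent\n")
        for i in range(n):
            t = 1 if i == 0 else 3
            par = -1 if tree.parent[i] == -1 else tree.parent[i] + 1
            x, y, z = tree.coords[i]
            fh.write(
                f"{i + 1} {t} {x:.4f} {y:.4f} {z:.4f} {diam[i] / 2.0:.4f} {par}\n"
            )


def read_swc(path) -> MorphTree:
    """Parse an SWC file into a :class:`MorphTree`.

    Two-pass: ids may appear in any order and parents may be forward
    references.  Raises ``ValueError`` on cycles, missing parents or
    multiple roots.
    """
    ids, parents, rows = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 7:
                raise ValueError(f"malformed SWC line: {line!r}")
            ids.append(int(parts[0]))
            parents.append(int(parts[6]))
            rows.append([float(parts[2]), float(parts[3]), float(parts[4]),
                         float(parts[5])])
    if not ids:
        raise ValueError("empty SWC file")
    ids = np.asarray(ids)
    parents = np.asarray(parents)
    rows = np.asarray(rows)
    id_to_pos = {int(i): k for k, i in enumerate(ids)}
    if len(id_to_pos) != len(ids):
        raise ValueError("duplicate SWC ids")

    roots = np.nonzero(parents == -1)[0]
    if len(roots) != 1:
        raise ValueError(f"expected exactly one root, found {len(roots)}")

    # order nodes root-first so that parent[i] < i (topological order)
    children: dict[int, list[int]] = {}
    for k, p in enumerate(parents):
        if p == -1:
            continue
        if int(p) not in id_to_pos:
            raise ValueError(f"parent id {p} not present")
        children.setdefault(id_to_pos[int(p)], []).append(k)
    # keep the file's own order when it is already topological (so
    # write -> read -> write is byte-stable); otherwise DFS-order it
    file_topological = roots[0] == 0 and all(
        p == -1 or id_to_pos[int(p)] < k for k, p in enumerate(parents)
    )
    if file_topological:
        order = list(range(len(ids)))
        # still guard against cycles among forward refs (none possible here)
    else:
        order = []
        stack = [int(roots[0])]
        while stack:
            k = stack.pop()
            order.append(k)
            stack.extend(reversed(children.get(k, [])))
    if len(order) != len(ids):
        raise ValueError("cyclic or disconnected parent links in SWC file")
    pos_to_new = {k: j for j, k in enumerate(order)}
    coords = rows[order, :3]
    diam = rows[order, 3] * 2.0
    parent = np.empty(len(order), dtype=int)
    parent[0] = -1
    for j, k in enumerate(order[1:], start=1):
        parent[j] = pos_to_new[id_to_pos[int(parents[k])]]
    return MorphTree(coords=coords, parent=parent, diam=diam)
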