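"""Population-level voxel and surface analyses of the dendritic forest.

The molecular layer is divided into 25 um cubes; for each cube the
analyses count the unique granule cells whose dendrites reach into it,
sum the dendritic cable length, and compute the cable density and the
percent volumetric occupancy.  A wiring-based axon-complexity measure
estimates how many branch points a minimal axon needs to contact every
cell present in a cube.  Surface maps average per-cell statistics over
a 5000-face triangulation of the GCL boundary.

Dendrite positions are taken from segment centers of the 5 um
resampled trees, so per-cube length and volume are approximations at
that resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import LayerLabel
from .growth import grow_tree, resample_tree

__all__ = [
    "OccupancyGrid",
    "build_grid",
    "axon_complexity",
    "occupancy_correlations",
    "surface_map",
]

CUBE_EDGE = 25.0  # um


@dataclass
class OccupancyGrid:
    """Per-cube occupancy statistics on a 25 um lattice.

    ``table`` has one row per occupied ML cube with columns
    ``i, j, k`` (integer cube index), ``n_unique`` (distinct cells),
    ``length`` (um of cable), ``density`` (um/um^3) and ``occupancy``
    (percent of the cube volume filled by dendritic cylinders).
    """

    table: pd.DataFrame
    edge: float = CUBE_EDGE
    origin: np.ndarray | None = None

    def __len__(self):
        return len(self.table)

    @property
    def cube_volume(self) -> float:
        return self.edge ** 3


def _segment_centers(tree):
    c = tree.coords
    par = tree.parent[1:]
    mids = 0.5 * (c[1:] + c[par])
    lengths = np.linalg.norm(c[1:] - c[par], axis=1)
    radii = (
        0.25 * (tree.diam[1:] + tree.diam[par])
        if tree.diam is not None
        else np.full(len(mids), 0.5)
    )
    return mids, lengths, radii


def build_grid(
    trees,
    volume=None,
    slice_predicate=None,
    edge: float = CUBE_EDGE,
    ml_only: bool = True,
) -> OccupancyGrid:
    """Bin dendritic segment centers of a population into cubes.

    Segments are attributed to the cube containing their center; each
    cube records the distinct cell ids, summed length and summed
    cylinder volume.  With ``ml_only`` (default) only cubes whose
    centers classify into the molecular layer are kept; a
    ``slice_predicate`` (e.g. :class:`~dgforest.TransverseSlice`)
    restricts the analysis to a slab.
    """
    mids_all, len_all, vol_all, cell_all = [], [], [], []
    for t in trees:
        if t.n_nodes < 2:
            continue
        mids, lengths, radii = _segment_centers(t)
        mids_all.append(mids)
        len_all.append(lengths)
        vol_all.append(lengths * np.pi * radii ** 2)
        cid = t.cell_id if t.cell_id is not None else id(t)
        cell_all.append(np.full(len(mids), cid, dtype=np.int64))
    if not mids_all:
        raise ValueError("no segments to bin")
    mids = np.concatenate(mids_all)
    lengths = np.concatenate(len_all)
    cylvol = np.concatenate(vol_all)
    cells = np.concatenate(cell_all)

    if slice_predicate is not None:
        keep = slice_predicate(mids)
        mids, lengths, cylvol, cells = mids[keep], lengths[keep], cylvol[keep], cells[keep]

    origin = np.floor(mids.min(axis=0) / edge) * edge
    ijk = np.floor((mids - origin) / edge).astype(np.int64)
    df = pd.DataFrame(
        {
            "i": ijk[:, 0], "j": ijk[:, 1], "k": ijk[:, 2],
            "cell": cells, "length": lengths, "cylvol": cylvol,
        }
    )
    g = df.groupby(["i", "j", "k"]).agg(
        n_unique=("cell", "nunique"),
        length=("length", "sum"),
        cylvol=("cylvol", "sum"),
    ).reset_index()
    g["density"] = g["length"] / edge ** 3
    g["occupancy"] = 100.0 * g["cylvol"] / edge ** 3
    if ml_only and volume is not None:
        centers = origin + (g[["i", "j", "k"]].to_numpy() + 0.5) * edge
        lab = volume.classify_points(centers)
        ml = np.isin(lab, [int(l) for l in (LayerLabel.IML, LayerLabel.MML, LayerLabel.OML)])
        g = g[ml].reset_index(drop=True)
    return OccupancyGrid(table=g, edge=edge, origin=origin)


def layer_profile(grid: OccupancyGrid, volume) -> pd.DataFrame:
    """Mean occupancy statistics per molecular sublayer."""
    centers = grid.origin + (grid.table[["i", "j", "k"]].to_numpy() + 0.5) * grid.edge
    lab = volume.classify_points(centers)
    out = {}
    for l in (LayerLabel.IML, LayerLabel.MML, LayerLabel.OML):
        sub = grid.table[lab == int(l)]
        out[l.name] = {
            "n_cubes": len(sub),
            "mean_unique": sub.n_unique.mean(),
            "mean_density": sub.density.mean(),
            "mean_occupancy": sub.occupancy.mean(),
        }
    return pd.DataFrame(out).T


def laminar_cable_density(
    trees,
    volume,
    layer_volumes_mm3: dict | None = None,
    n_mc: int = 1_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Dense-limit cable density and occupancy per molecular sublayer.

    Attributes each 5 um segment to the sublayer of its midpoint and
    divides by the sublayer volume (Monte-Carlo estimated unless
    supplied), i.e. the mean over *all* cubes of the layer including
    empty ones.  Per-occupied-cube means are biased low in large
    sparsely-covered layers, so this is the appropriate statistic for
    laminar gradients at less-than-full population density.
    """
    from .geometry import estimate_volume

    layers = (LayerLabel.IML, LayerLabel.MML, LayerLabel.OML)
    if layer_volumes_mm3 is None:
        layer_volumes_mm3 = {
            l: estimate_volume(volume, l, n_samples=n_mc, seed=seed + int(l))[0]
            for l in layers
        }
    cable = {l: 0.0 for l in layers}
    cyl = {l: 0.0 for l in layers}
    for t in trees:
        if t.n_nodes < 2:
            continue
        mids, lengths, radii = _segment_centers(t)
        lab = volume.classify_points(mids)
        for l in layers:
            m = lab == int(l)
            cable[l] += float(lengths[m].sum())
            cyl[l] += float((lengths[m] * np.pi * radii[m] ** 2).sum())
    rows = {}
    for l in layers:
        vol_um3 = layer_volumes_mm3[l] * 1e9
        rows[l.name] = {
            "cable_um": cable[l],
            "density_um_per_um3": cable[l] / vol_um3,
            "occupancy_pct": 100.0 * cyl[l] / vol_um3,
        }
    return pd.DataFrame(rows).T


def occupancy_correlations(grid: OccupancyGrid) -> dict:
    """Pearson correlations between the three occupancy measures."""
    t = grid.table
    if len(t) < 10:
        raise ValueError("need at least 10 cubes for correlations")
    return {
        "unique_vs_density": float(np.corrcoef(t.n_unique, t.density)[0, 1]),
        "unique_vs_occupancy": float(np.corrcoef(t.n_unique, t.occupancy)[0, 1]),
        "density_vs_occupancy": float(np.corrcoef(t.density, t.occupancy)[0, 1]),
    }


def axon_complexity(
    cube_origin,
    trees,
    edge: float = CUBE_EDGE,
    n_repeats: int = 10,
    seed: int = 0,
    reach: float = 5.0,
    increment: int = 5,
    max_points: int = 400,
) -> float:
    """Branch points a minimal axon needs to contact every cell in a cube.

    Random points in the cube are wired with the optimal wiring
    algorithm at balancing factor zero (a minimum spanning tree); the
    number of points grows in increments until the resampled axon
    passes within ``reach`` um of every cell's dendrite inside the
    cube.  The branch-point count is averaged over ``n_repeats``
    independent point collections.
    """
    cube_origin = np.asarray(cube_origin, dtype=float)
    cell_nodes = []
    for t in trees:
        mids, _, _ = _segment_centers(t)
        inside = np.all((mids >= cube_origin) & (mids < cube_origin + edge), axis=1)
        if inside.any():
            cell_nodes.append(mids[inside])
    if not cell_nodes:
        raise ValueError("no cell dendrites inside the cube")
    counts = []
    for rep in range(n_repeats):
        rng = np.random.default_rng([seed, rep])
        pts = np.empty((0, 3))
        root = cube_origin + rng.random(3) * edge
        # first batch of 2 keeps a reachable single-cell case branchless
        batch = 2
        while True:
            extra = cube_origin + rng.random((batch, 3)) * edge
            batch = increment
            pts = np.concatenate([pts, extra])
            axon = grow_tree(root, pts, bf=0.0)
            axon = resample_tree(axon, spacing=1.0)
            tree_kd = cKDTree(axon.coords)
            ok = all(
                tree_kd.query(nodes, k=1)[0].min() <= reach for nodes in cell_nodes
            )
            if ok or len(pts) >= max_points:
                counts.append(len(axon.branch_point_nodes))
                break
    return float(np.mean(counts))


def surface_map(
    trees,
    volume,
    values,
    L: float = 0.0,
    n_faces: int = 5000,
    deep_mask=None,
):
    """Average a per-cell statistic over a triangulated GCL surface.

    Each tree is assigned to the nearest of the ``n_faces`` face
    centroids of the GCL shell triangulation; per-face means of
    ``values`` are returned (NaN for faces with no cells).  With
    ``deep_mask`` two maps (deep, superficial) are returned.
    """
    nu = int(round(np.sqrt(n_faces / 2.0))) + 1
    verts, faces = volume.surface_mesh(L, nu=nu, nv=nu)
    centroids = verts[faces].mean(axis=1)
    kd = cKDTree(centroids)
    somata = np.array([t.coords[0] for t in trees])
    values = np.asarray(values, dtype=float)
    _, fidx = kd.query(somata)

    def face_means(sel):
        out = np.full(len(centroids), np.nan)
        if not np.any(sel):
            return out
        sums = np.bincount(fidx[sel], weights=values[sel], minlength=len(centroids))
        cnts = np.bincount(fidx[sel], minlength=len(centroids))
        np.divide(sums, cnts, out=out, where=cnts > 0)
        return out

    if deep_mask is None:
        return centroids, face_means(np.ones(len(trees), dtype=bool)), fidx
    deep_mask = np.asarray(deep_mask, dtype=bool)
    return centroids, face_means(deep_mask), face_means(~deep_mask), fidx
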