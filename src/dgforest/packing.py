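"""Packing of granule-cell somata inside the granule cell layer.

Somata are modelled as equal spheres (12.54 um diameter, the volume of
the average ellipsoidal granule-cell soma) placed on a close-packed
lattice of hexagonal layers (ABC stacking) with a 3.5 um gap between
neighbouring spheres.  Lattice sites whose sphere would protrude from
the GCL are discarded.  Each kept soma is labelled with its anatomical
subgroup: suprapyramidal vs infrapyramidal blade (split at the midpoint
of the transverse ``v`` parameter) and deep vs superficial half of the
GCL (split at normalized depth 0.5, superficial being the half closest
to the molecular layer).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import DGVolume, LayerLabel

__all__ = ["Subgroup", "SomaSet", "pack_somata", "assign_subgroups"]

SOMA_DIAMETER = 12.54  # um
SOMA_GAP = 3.5         # um


class Subgroup(enum.IntEnum):
    SUPRA_SUPERFICIAL = 0
    SUPRA_DEEP = 1
    INFRA_SUPERFICIAL = 2
    INFRA_DEEP = 3

    @property
    def blade(self) -> str:
        return "supra" if self in (Subgroup.SUPRA_SUPERFICIAL, Subgroup.SUPRA_DEEP) else "infra"

    @property
    def depth_class(self) -> str:
        return (
            "superficial"
            if self in (Subgroup.SUPRA_SUPERFICIAL, Subgroup.INFRA_SUPERFICIAL)
            else "deep"
        )


@dataclass
class SomaSet:
    """Packed soma centers with per-soma anatomical annotations."""

    centers: np.ndarray                   # (n, 3) um
    diameter: float = SOMA_DIAMETER
    u: np.ndarray | None = None           # septotemporal coordinate
    v: np.ndarray | None = None           # transverse coordinate
    gcl_depth: np.ndarray | None = None   # normalized depth in [0, 1]
    subgroup: np.ndarray | None = None    # Subgroup codes (int8)

    def __len__(self) -> int:
        return self.centers.shape[0]

    def subset(self, mask) -> "SomaSet":
        take = lambda a: None if a is None else a[mask]
        return SomaSet(
            centers=self.centers[mask],
            diameter=self.diameter,
            u=take(self.u),
            v=take(self.v),
            gcl_depth=take(self.gcl_depth),
            subgroup=take(self.subgroup),
        )

    def subgroup_fractions(self) -> dict:
        if self.subgroup is None:
            raise ValueError("subgroups not assigned")
        n = len(self)
        return {
            sg: float(np.sum(self.subgroup == int(sg))) / n for sg in Subgroup
        }

    def to_table(self) -> np.ndarray:
        """Plain columnar export: x, y, z, subgroup code, depth."""
        cols = [self.centers]
        if self.subgroup is not None:
            cols.append(self.subgroup[:, None].astype(float))
        if self.gcl_depth is not None:
            cols.append(self.gcl_depth[:, None])
        return np.concatenate(cols, axis=1)


def _close_packed_layer(lo, hi, a, phase, z):
    """Sites of one triangular layer covering [lo, hi] in x-y at height z."""
    row_dy = a * np.sqrt(3.0) / 2.0
    rows = np.arange(int(np.floor((lo[1] - phase[1]) / row_dy)) - 1,
                     int(np.ceil((hi[1] - phase[1]) / row_dy)) + 2)
    cols = np.arange(int(np.floor((lo[0] - phase[0]) / a)) - 1,
                     int(np.ceil((hi[0] - phase[0]) / a)) + 2)
    jj, ii = np.meshgrid(rows, cols, indexing="ij")
    x = phase[0] + ii * a + (jj % 2) * (a / 2.0)
    y = phase[1] + jj * row_dy
    m = (x >= lo[0] - a) & (x <= hi[0] + a) & (y >= lo[1] - a) & (y <= hi[1] + a)
    pts = np.stack([x[m], y[m], np.full(m.sum(), z)], axis=1)
    return pts


def pack_somata(
    volume,
    diameter: float = SOMA_DIAMETER,
    gap: float = SOMA_GAP,
    seed: int = 0,
    chunk_layers: int = 12,
) -> SomaSet:
    """Pack spherical somata on a close-packed lattice inside the GCL.

    The lattice (nearest-neighbour spacing ``diameter + gap``) is
    aligned to the bounding-box axes with a seeded random phase.
    Spheres with any portion outside the GCL are discarded.

    ``volume`` must provide ``bounding_box`` and either
    ``contains_sphere_in_gcl(centers, radius)`` or ``classify_points``
    (in which case only the sphere center is tested).
    """
    if diameter <= 0 or gap < 0:
        raise ValueError("diameter must be > 0 and gap >= 0")
    a = diameter + gap
    radius = diameter / 2.0
    lo, hi = volume.bounding_box
    rng = np.random.default_rng(seed)
    dz = a * np.sqrt(2.0 / 3.0)
    phase = rng.random(3) * np.array([a, a * np.sqrt(3.0) / 2.0, dz])

    # ABC close-packed stacking shifts within each layer
    shift = np.array([[0.0, 0.0], [a / 2.0, a / (2.0 * np.sqrt(3.0))],
                      [a, a / np.sqrt(3.0)]])

    strict = hasattr(volume, "contains_sphere_in_gcl")
    layers = np.arange(int(np.floor((lo[2] - phase[2]) / dz)) - 1,
                       int(np.ceil((hi[2] - phase[2]) / dz)) + 2)
    kept = []
    for start in range(0, len(layers), chunk_layers):
        pts = []
        for k in layers[start:start + chunk_layers]:
            z = phase[2] + k * dz
            if z < lo[2] - a or z > hi[2] + a:
                continue
            lay = _close_packed_layer(lo, hi, a, phase[:2] + shift[k % 3], z)
            pts.append(lay)
        if not pts:
            continue
        pts = np.concatenate(pts, axis=0)
        if strict:
            ok = volume.contains_sphere_in_gcl(pts, radius)
        else:
            ok = volume.classify_points(pts) == int(LayerLabel.GCL)
        if np.any(ok):
            kept.append(pts[ok])
    centers = (
        np.concatenate(kept, axis=0) if kept else np.empty((0, 3), dtype=float)
    )
    return SomaSet(centers=centers, diameter=diameter)


def assign_subgroups(somata: SomaSet, volume: DGVolume) -> SomaSet:
    """Annotate packed somata with depth and blade subgroup labels.

    Superficial somata lie in the half of the GCL closest to the ML
    (normalized depth >= 0.5); the suprapyramidal blade is the side of
    the "C" with ``v`` at or below the midpoint of the ``v`` range
    (ties resolve to suprapyramidal).
    """
    p = volume.params
    u, v, off, inside = volume.invert_points(somata.centers)
    if not np.all(inside):
        raise ValueError("soma center outside the volume")
    depth = (off - p.offset_inner) / (0.0 - p.offset_inner)
    # atan2 wraps v beyond pi onto (-pi, v_min); unwrap before the split
    v = np.where(v < p.v_min - 1e-9, v + 2 * np.pi, v)
    supra = v <= p.v_mid + 1e-9
    superficial = depth >= 0.5
    code = np.where(
        supra,
        np.where(superficial, int(Subgroup.SUPRA_SUPERFICIAL), int(Subgroup.SUPRA_DEEP)),
        np.where(superficial, int(Subgroup.INFRA_SUPERFICIAL), int(Subgroup.INFRA_DEEP)),
    ).astype(np.int8)
    somata.u = u
    somata.v = v
    somata.gcl_depth = depth
    somata.subgroup = code
    return somata


def min_pairwise_distance(centers: np.ndarray, sample: int | None = None, seed: int = 0) -> float:
    """Smallest center-to-center distance (optionally on a subsample)."""
    pts = centers
    if sample is not None and len(pts) > sample:
        rng = np.random.default_rng(seed)
        pts = pts[rng.choice(len(pts), size=sample, replace=False)]
    tree = cKDTree(centers)
    d, _ = tree.query(pts, k=2, workers=-1)
    return float(d[:, 1].min())
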