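"""Deterministic small-scale test inputs.

Toy volumes with closed-form geometry (box, sphere, concentric
spherical shells) stand in for the full parametric volume in unit
tests, and template trees with exactly known morphometrics (straight,
Y, full binary, comb, and a small granule-cell-like tree) exercise
the morphometric and SWC code paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from types import SimpleNamespace

import numpy as np

from .geometry import LayerLabel
from .growth import grow_tree
from .swcio import write_swc
from .tree import MorphTree

__all__ = ["ToyVolume", "make_toy_volume", "FixtureTree", "make_fixture_tree"]


class ToyVolume:
    """Analytic stand-in volume with a closed-form size.

    ``kind='box'``: everything inside an axis-aligned box is GCL.
    ``kind='sphere'``: everything inside a sphere is GCL.
    ``kind='shell'``: a spherical GCL shell of thickness ``width``
    (boundary clouds at ``L=0`` and ``L=3`` are spheres of radius
    ``radius`` and ``radius + width``, giving an exactly known
    ml-width).
    """

    def __init__(self, kind: str, **dims):
        self.kind = kind
        self.dims = dims
        if kind == "box":
            self.size = np.asarray(dims["size"], dtype=float)
            if np.any(self.size <= 0):
                raise ValueError("box dimensions must be positive")
            self.closed_form_volume_mm3 = float(np.prod(self.size)) * 1e-9
            self._lo = np.zeros(3)
            self._hi = self.size
        elif kind == "sphere":
            r = float(dims["radius"])
            if r <= 0:
                raise ValueError("radius must be positive")
            self.radius = r
            self.closed_form_volume_mm3 = 4.0 / 3.0 * np.pi * r ** 3 * 1e-9
            self._lo = -np.full(3, r)
            self._hi = np.full(3, r)
        elif kind == "shell":
            r, w = float(dims["radius"]), float(dims["width"])
            if r <= 0 or w <= 0:
                raise ValueError("radius and width must be positive")
            self.radius, self.width = r, w
            self.closed_form_volume_mm3 = (
                4.0 / 3.0 * np.pi * ((r + w) ** 3 - r ** 3) * 1e-9
            )
            self._lo = -np.full(3, r + w)
            self._hi = np.full(3, r + w)
            # minimal parameter surface so ml_width() can run unchanged
            self.params = SimpleNamespace(L_outer_gcl=0.0, L_oml=3.0)
        else:
            raise ValueError(f"unknown toy volume kind {kind!r}")

    @property
    def bounding_box(self):
        pad = 1.0
        return self._lo - pad, self._hi + pad

    def classify_points(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.kind == "box":
            inside = np.all((pts >= 0) & (pts <= self.size), axis=1)
        elif self.kind == "sphere":
            inside = np.linalg.norm(pts, axis=1) <= self.radius
        else:
            r = np.linalg.norm(pts, axis=1)
            inside = (r >= self.radius) & (r <= self.radius + self.width)
        return np.where(inside, int(LayerLabel.GCL), int(LayerLabel.OUTSIDE)).astype(np.int8)

    def contains_sphere_in_gcl(self, centers, radius: float) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(centers, dtype=float))
        if self.kind == "box":
            return np.all((pts >= radius) & (pts <= self.size - radius), axis=1)
        if self.kind == "sphere":
            return np.linalg.norm(pts, axis=1) <= self.radius - radius
        r = np.linalg.norm(pts, axis=1)
        return (r >= self.radius + radius) & (r <= self.radius + self.width - radius)

    def boundary_cloud(self, L: float, n: int, seed=0) -> np.ndarray:
        """Uniform points on the shell boundary spheres (kind='shell')."""
        if self.kind != "shell":
            raise ValueError("boundary clouds only exist for shell volumes")
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = self.radius if L <= 0 else self.radius + self.width
        return r * v


def make_toy_volume(kind: str, **dims) -> ToyVolume:
    return ToyVolume(kind, **dims)


@dataclass
class FixtureTree:
    tree: MorphTree
    expected: dict

    def write(self, swc_path, sidecar_path=None) -> None:
        write_swc(self.tree, swc_path)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(self.expected, fh, indent=1)


def _straight(length=100.0, n_seg=10):
    z = np.linspace(0, length, n_seg + 1)
    coords = np.stack([np.zeros_like(z), np.zeros_like(z), z], axis=1)
    parent = np.arange(-1, n_seg)
    t = MorphTree(coords=coords, parent=parent)
    return t, {
        "n_branches": 1, "n_tips": 1, "n_branch_points": 0,
        "max_branch_order": 0, "total_length": length,
        "contraction": [1.0],
    }


def _y_tree(stem=50.0, arm=50.0):
    coords = np.array(
        [[0, 0, 0], [0, 0, stem],
         [arm * 0.6, 0, stem + arm * 0.8],
         [-arm * 0.6, 0, stem + arm * 0.8]]
    )
    parent = np.array([-1, 0, 1, 1])
    t = MorphTree(coords=coords, parent=parent)
    return t, {
        "n_branches": 3, "n_tips": 2, "n_branch_points": 1,
        "max_branch_order": 1, "asymmetry": 0.0,
        "total_length": stem + 2 * arm,
    }


def _binary(levels=3, seg=20.0):
    # single stem, then full bifurcation for levels-1 further levels
    coords = [np.zeros(3)]
    parent = [-1]

    def add(parent_idx, depth, x, width):
        idx = len(coords)
        coords.append(np.array([x, 0.0, (depth + 1) * seg]))
        parent.append(parent_idx)
        if depth < levels - 1:
            add(idx, depth + 1, x - width, width / 2)
            add(idx, depth + 1, x + width, width / 2)

    add(0, 0, 0.0, 40.0)
    t = MorphTree(coords=np.array(coords), parent=np.array(parent))
    return t, {
        "n_branches": 2 ** levels - 1,
        "n_tips": 2 ** (levels - 1),
        "n_branch_points": 2 ** (levels - 1) - 1,
        "max_branch_order": levels - 1,
        "asymmetry": 0.0,
    }


def _comb(n_tips=8, spine=20.0, tooth=15.0):
    coords = [np.zeros(3)]
    parent = [-1]
    prev = 0
    for k in range(n_tips - 1):
        idx = len(coords)
        coords.append(np.array([(k + 1) * spine, 0.0, 0.0]))
        parent.append(prev)
        coords.append(np.array([(k + 1) * spine, 0.0, tooth]))
        parent.append(idx)
        prev = idx
    coords.append(np.array([n_tips * spine, 0.0, 0.0]))
    parent.append(prev)
    t = MorphTree(coords=np.array(coords), parent=np.array(parent))
    # each partition is (1, k); the final (1,1) contributes 0, so the
    # mean is (n-2)/(n-1), approaching 1 for large combs
    return t, {
        "n_tips": n_tips,
        "n_branch_points": n_tips - 1,
        "asymmetry": (n_tips - 2) / (n_tips - 1),
    }


def _gc_like(seed=42, n_targets=40):
    rng = np.random.default_rng(seed)
    z = 250.0 * rng.random(n_targets) ** (1 / 3)
    r = 120.0 * np.sqrt(rng.random(n_targets)) * z / 250.0
    th = rng.uniform(0, 2 * np.pi, n_targets)
    pts = np.stack([r * np.cos(th), r * np.sin(th) * 0.6, z], axis=1)
    t = grow_tree(np.zeros(3), pts, bf=1.0)
    bs_total = float(t.total_length)
    return t, {"n_nodes": t.n_nodes, "total_length": bs_total}


_TEMPLATES = {
    "straight": _straight,
    "y": _y_tree,
    "binary": _binary,
    "comb": _comb,
    "gc_like": _gc_like,
}


def make_fixture_tree(template: str, **kwargs) -> FixtureTree:
    """Build a template tree with exactly known statistics."""
    if template not in _TEMPLATES:
        raise ValueError(f"unknown template {template!r}; choose from {sorted(_TEMPLATES)}")
    tree, expected = _TEMPLATES[template](**kwargs)
    return FixtureTree(tree=tree, expected=expected)
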