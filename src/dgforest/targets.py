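"""Dendritic target points and elliptical-cone dendritic fields.

Each granule cell connects a set of target points that lie inside an
elliptical cone with its apex at the soma.  The cone axis points toward
the nearest point of the OML boundary (so trees span the molecular
layer), the transverse cone radius (along the local ``v`` tangent)
exceeds the longitudinal radius (along the septotemporal ``u``
tangent), and per-layer target counts are drawn so that, once wired,
the population reproduces the observed laminar distribution of branch
and termination points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import DGVolume, LayerLabel

__all__ = [
    "EllipticalCone",
    "TargetPointCloud",
    "orient_cone",
    "cone_select",
    "sample_in_cone",
    "draw_quota",
    "sample_targets",
]


@dataclass
class EllipticalCone:
    """Apex-at-soma elliptical cone bounding a dendritic field.

    The cross-section at height ``z`` is an ellipse with semi-axes
    ``radius_t * z / height`` (transverse) and ``radius_l * z / height``
    (longitudinal).
    """

    apex: np.ndarray          # (3,) um
    axis: np.ndarray          # unit vector toward the OML
    t_hat: np.ndarray         # transverse unit vector
    l_hat: np.ndarray         # longitudinal unit vector
    radius_t: float           # um, transverse semi-axis at the base
    radius_l: float           # um, longitudinal semi-axis at the base
    height: float             # um, apex to OML boundary

    def __post_init__(self):
        if self.radius_t <= 0 or self.radius_l <= 0 or self.height <= 0:
            raise ValueError("cone radii and height must be positive")
        if self.radius_t <= self.radius_l:
            raise ValueError("transverse radius must exceed longitudinal radius")

    def local_frame(self, points: np.ndarray):
        w = np.atleast_2d(points) - self.apex
        return w @ self.t_hat, w @ self.l_hat, w @ self.axis

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points satisfying the cone inequality
        ``(x/a)^2 + (y/b)^2 <= (z/h)^2`` with ``z`` in ``[0, h]``."""
        x, y, z = self.local_frame(points)
        with np.errstate(invalid="ignore"):
            inside = (
                (z >= 0)
                & (z <= self.height)
                & (
                    (x / self.radius_t) ** 2 + (y / self.radius_l) ** 2
                    <= (z / self.height) ** 2
                )
            )
        return inside


@dataclass
class TargetPointCloud:
    """Pool of candidate target points tagged by layer.

    ``available`` supports the optional shared-pool mode in which
    points consumed by one cell are withdrawn from the pool.
    """

    points: np.ndarray
    layer: np.ndarray
    available: np.ndarray | None = None

    def __post_init__(self):
        if self.available is None:
            self.available = np.ones(len(self.points), dtype=bool)

    def __len__(self):
        return len(self.points)

    def consume(self, indices) -> None:
        self.available[indices] = False


def uniform_cloud(volume, layers, n_per_layer, seed=0, batch=200_000) -> TargetPointCloud:
    """Volume-uniform target pool with ``n_per_layer`` points per layer."""
    rng = np.random.default_rng(seed)
    lo, hi = volume.bounding_box
    want = {int(l): n_per_layer for l in layers}
    pts, labs = [], []
    while any(v > 0 for v in want.values()):
        cand = lo + rng.random((batch, 3)) * (hi - lo)
        lab = volume.classify_points(cand)
        for l, left in list(want.items()):
            if left <= 0:
                continue
            sel = np.nonzero(lab == l)[0][:left]
            pts.append(cand[sel])
            labs.append(np.full(len(sel), l, dtype=np.int8))
            want[l] -= len(sel)
    return TargetPointCloud(points=np.concatenate(pts), layer=np.concatenate(labs))


def orient_cone(
    volume: DGVolume,
    soma: np.ndarray,
    radius_t: float,
    radius_l: float,
    oml_tree: cKDTree | None = None,
) -> EllipticalCone:
    """Place a cell's elliptical cone at its soma.

    The axis points from the soma toward the closest point of the OML
    boundary cloud, the cone height reaches that boundary point, and
    the transverse/longitudinal radii are aligned with the local ``v``
    and ``u`` surface tangents (orthogonalized against the axis).
    """
    soma = np.asarray(soma, dtype=float)
    u, v, off, inside = volume.invert_points(soma[None, :])
    if not inside[0]:
        raise ValueError("soma outside the volume")
    tree = oml_tree if oml_tree is not None else volume.oml_tree()
    dist, idx = tree.query(soma)
    target = tree.data[idx]
    axis = target - soma
    height = float(np.linalg.norm(axis))
    axis = axis / height
    lon, trans, _ = volume.tangent_frame(u[0], v[0], 0.0)
    t_hat = trans - (trans @ axis) * axis
    t_hat /= np.linalg.norm(t_hat)
    l_hat = np.cross(axis, t_hat)
    if l_hat @ lon < 0:
        l_hat = -l_hat
    return EllipticalCone(
        apex=soma, axis=axis, t_hat=t_hat, l_hat=l_hat,
        radius_t=float(radius_t), radius_l=float(radius_l), height=height,
    )


def cone_select(cone: EllipticalCone, cloud: TargetPointCloud) -> np.ndarray:
    """Indices of available pool points lying inside the cone."""
    mask = cone.contains(cloud.points) & cloud.available
    return np.nonzero(mask)[0]


def sample_in_cone(cone: EllipticalCone, n: int, rng, radial_exp: float = 0.5) -> np.ndarray:
    """Sample ``n`` points inside the cone volume.

    ``radial_exp`` biases the radial placement within each
    cross-section: 0.5 is area-uniform, smaller values concentrate
    points toward the cone surface (the periphery of the dendritic
    fan, where real granule-cell terminals accumulate).
    """
    z = cone.height * rng.random(n) ** (1.0 / 3.0)
    r = rng.random(n) ** radial_exp
    th = rng.uniform(0, 2 * np.pi, n)
    scale = z / cone.height
    x = r * np.cos(th) * cone.radius_t * scale
    y = r * np.sin(th) * cone.radius_l * scale
    return (
        cone.apex
        + np.outer(z, cone.axis)
        + np.outer(x, cone.t_hat)
        + np.outer(y, cone.l_hat)
    )


#: order in which per-layer quotas are stored
QUOTA_LAYERS = (LayerLabel.GCL, LayerLabel.IML, LayerLabel.MML, LayerLabel.OML)


def draw_quota(quota_means, rng) -> dict[int, int]:
    """Draw per-layer target-point counts for one cell.

    ``quota_means`` maps the four layers (GCL, IML, MML, OML) to mean
    counts; per-cell counts are Poisson draws around those means, the
    calibrated values of which reproduce the laminar branch-point
    distribution of the population.
    """
    out = {}
    for lab in QUOTA_LAYERS:
        mu = float(quota_means[int(lab)])
        out[int(lab)] = int(rng.poisson(mu)) if mu > 0 else 0
    return out


def sample_targets(
    volume,
    cone: EllipticalCone,
    quota: dict[int, int],
    rng,
    batch: int = 512,
    max_batches: int = 60,
    radial_exp=0.5,
    oml_band: tuple | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Independently sample a cell's target points inside its cone.

    Draws cone-uniform candidates, classifies them into layers and
    keeps up to the quota per layer.  Layers the cone cannot reach are
    filled as far as possible.  ``oml_band`` optionally restricts OML
    targets to a normalized depth band of the OML shell (e.g. ``(0.4,
    1.0)`` keeps the outer 60%), which sends terminal branches through
    the full molecular layer as observed in reconstructions.

    Returns
    -------
    points : (m, 3) ndarray
    layer : (m,) int8 ndarray
    """
    want = {l: q for l, q in quota.items() if q > 0}
    pts = {l: [] for l in want}
    got = {l: 0 for l in want}
    use_band = oml_band is not None and hasattr(volume, "invert_points")
    if not isinstance(radial_exp, dict):
        radial_exp = {l: radial_exp for l in want}
    for _ in range(max_batches):
        todo = [l for l in want if got[l] < want[l]]
        if not todo:
            break
        # candidates are drawn per distinct radial exponent
        exps = sorted({radial_exp.get(l, 0.5) for l in todo})
        cand = np.concatenate(
            [sample_in_cone(cone, batch, rng, radial_exp=e) for e in exps]
        )
        exp_of = np.concatenate([np.full(batch, e) for e in exps])
        lab = volume.classify_points(cand)
        # a candidate only counts for layers sharing its exponent
        lab_by_exp = {e: np.where(exp_of == e, lab, -1) for e in exps}
        if use_band:
            _, _, off, _ = volume.invert_points(cand)
            w = volume.params.w_ml
            depth_in_oml = off / w - 2.0
            bad = (depth_in_oml < oml_band[0]) | (depth_in_oml > oml_band[1])
            for e in exps:
                lab_by_exp[e] = np.where(
                    (lab_by_exp[e] == int(LayerLabel.OML)) & bad,
                    int(LayerLabel.OUTSIDE), lab_by_exp[e],
                )
        for l in todo:
            need = want[l] - got[l]
            sel = np.nonzero(lab_by_exp[radial_exp.get(l, 0.5)] == l)[0][:need]
            if len(sel):
                pts[l].append(cand[sel])
                got[l] += len(sel)
    points, labels = [], []
    for l in want:
        if pts[l]:
            p = np.concatenate(pts[l])
            points.append(p)
            labels.append(np.full(len(p), l, dtype=np.int8))
    if not points:
        return np.empty((0, 3)), np.empty(0, dtype=np.int8)
    return np.concatenate(points), np.concatenate(labels)
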