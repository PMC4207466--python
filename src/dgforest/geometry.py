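"""Parametric model of the rat dentate gyrus layered volume.

The granule cell layer (GCL) and molecular layer (ML) are modelled as a
stack of offset surfaces built from a section of an elliptical torus: a
"C"-shaped elliptical cross-section (parameter ``v``) is swept along an
elliptical septotemporal center curve (parameter ``u``), with a smooth
deflection in z and unequal septal/temporal ends.  A third coordinate
``L`` indexes the layer shells: -1.95 (inner GCL), 0 (outer GCL), 1
(IML), 2 (MML), 3 (OML).  ``L`` is affine within the GCL and within the
ML, with separate micrometre-per-unit scales for the two compartments.

All lengths are in micrometres; volumes are reported in mm^3 only at
the reporting boundary (:func:`estimate_volume`).

The free coefficients of the surface family are calibrated (see
``scripts/calibrate_geometry.py``) so that the model reproduces the
anatomical reference values: GCL volume 3.78 mm^3, ML volume 9.02 mm^3
and ML width 247 um.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "LayerLabel",
    "DGSurfaceParams",
    "DGVolume",
    "estimate_volume",
    "ml_width",
    "TransverseSlice",
]

PI = np.pi


class LayerLabel(enum.IntEnum):
    """Anatomical layer classification of a 3D point."""

    OUTSIDE = 0
    GCL = 1
    IML = 2
    MML = 3
    OML = 4


#: Layers making up the molecular layer.
ML_LAYERS = (LayerLabel.IML, LayerLabel.MML, LayerLabel.OML)


@dataclass
class DGSurfaceParams:
    """Coefficients of the parametric layer-boundary family.

    ``v`` sweeps the "C"-shaped transverse cross-section, ``u`` the
    septotemporal extent.  The angular ranges and the layer offsets
    ``L`` are anatomical constants; the micrometre-valued coefficients
    are calibration parameters.

    Attributes
    ----------
    rx, ry : float
        Semi-axes of the elliptical septotemporal center curve (um).
    defl_z : float
        Amplitude of the smooth z-deflection of the center curve (um).
    xsec_a : float
        In-plane semi-axis of the transverse cross-section at the
        crest of the structure (um).
    q_septal, q_temporal : float
        Aspect ratio (z semi-axis over in-plane semi-axis) of the
        cross-section at the septal / temporal ends.  A taller, narrower
        section gives the septal "V" shape; a flatter one the temporal
        "U" shape.
    end_floor : float
        Relative cross-section size retained at the two ends of the
        septotemporal axis (1 = no end taper).
    end_asym : float
        Septal-over-temporal size asymmetry of the ends.
    w_gcl, w_ml : float
        Normal shell spacing per unit ``L`` inside the GCL and the ML
        (um).
    """

    # anatomical constants (fractions of pi, fixed)
    v_min: float = -0.23 * PI
    v_max: float = 1.425 * PI
    u_min_gcl: float = 0.01 * PI
    u_max_gcl: float = 0.98 * PI
    u_min_ml: float = -0.016 * PI
    u_max_ml: float = 1.01 * PI
    L_inner_gcl: float = -1.95
    L_outer_gcl: float = 0.0
    L_iml: float = 1.0
    L_mml: float = 2.0
    L_oml: float = 3.0

    # calibrated shape coefficients (um) -- defaults are the calibrated
    # values produced by scripts/calibrate_geometry.py
    rx: float = 3566.9158
    ry: float = 2469.4033
    defl_z: float = 1234.7016
    xsec_a: float = 713.3832
    q_septal: float = 1.25
    q_temporal: float = 0.80
    end_floor: float = 0.55
    end_asym: float = 0.12
    w_gcl: float = 80.7035
    w_ml: float = 86.2063

    # ------------------------------------------------------------------
    def end_scale(self, u):
        """Relative cross-section size along the septotemporal axis."""
        u = np.asarray(u, dtype=float)
        return (self.end_floor + (1.0 - self.end_floor) * np.sin(u)) * (
            1.0 + self.end_asym * np.cos(u)
        )

    def aspect(self, u):
        """Cross-section aspect ratio b/a as a function of ``u``."""
        u = np.asarray(u, dtype=float)
        return self.q_septal + (self.q_temporal - self.q_septal) * (1.0 - np.cos(u)) / 2.0

    def xsec_semiaxes(self, u):
        """Base (L=0) cross-section semi-axes ``(a, b)`` in um."""
        a = self.xsec_a * self.end_scale(u)
        return a, a * self.aspect(u)

    def center_radius(self, u):
        """Polar radius of the elliptical center curve at azimuth u."""
        u = np.asarray(u, dtype=float)
        return self.rx * self.ry / np.hypot(self.ry * np.cos(u), self.rx * np.sin(u))

    def center_z(self, u):
        """z-deflection of the center curve."""
        return self.defl_z * np.sin(np.asarray(u, dtype=float))

    def offset(self, L):
        """Normal shell offset (um) of layer coordinate ``L``."""
        L = np.asarray(L, dtype=float)
        return np.where(L < 0, self.w_gcl * L, self.w_ml * L)

    @property
    def offset_inner(self) -> float:
        return float(self.w_gcl * self.L_inner_gcl)

    @property
    def offset_outer(self) -> float:
        return float(self.w_ml * self.L_oml)

    @property
    def v_mid(self) -> float:
        """Midpoint of the v range: the supra/infrapyramidal split."""
        return 0.5 * (self.v_min + self.v_max)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DGSurfaceParams":
        return cls(**d)


# layer intervals in offset (um) units are derived per-instance; the
# label sequence from inside out is fixed:
_LAYER_SEQUENCE = (LayerLabel.GCL, LayerLabel.IML, LayerLabel.MML, LayerLabel.OML)


class DGVolume:
    """Evaluator for the layered dentate gyrus volume.

    Provides the forward surface map, the inverse map used for point
    classification, boundary point clouds, volume estimation helpers
    and local tangent frames.
    """

    def __init__(self, params: DGSurfaceParams | None = None):
        self.params = params or DGSurfaceParams()
        self._bbox: tuple[np.ndarray, np.ndarray] | None = None
        self._oml_cloud: np.ndarray | None = None
        self._oml_tree: cKDTree | None = None
        self._arc_grid: tuple[np.ndarray, np.ndarray] | None = None

    # -- forward map ----------------------------------------------------
    def _u_range(self, L) -> tuple[float, float]:
        p = self.params
        if np.any(np.asarray(L) > 0):
            return p.u_min_ml, p.u_max_ml
        return p.u_min_gcl, p.u_max_gcl

    def surface_point(self, u, v, L):
        """Forward parametric map ``(u, v, L) -> (x, y, z)`` in um.

        Raises
        ------
        ValueError
            If ``u``, ``v`` or ``L`` lie outside the printed parameter
            ranges for the requested layer shell.
        """
        p = self.params
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        L = np.asarray(L, dtype=float)
        umin, umax = self._u_range(L)
        if np.any(u < umin - 1e-12) or np.any(u > umax + 1e-12):
            raise ValueError(f"u outside [{umin}, {umax}]")
        if np.any(v < p.v_min - 1e-12) or np.any(v > p.v_max + 1e-12):
            raise ValueError(f"v outside [{p.v_min}, {p.v_max}]")
        if np.any(L < p.L_inner_gcl - 1e-12) or np.any(L > p.L_oml + 1e-12):
            raise ValueError(f"L outside [{p.L_inner_gcl}, {p.L_oml}]")
        return self._surface_point_unchecked(u, v, L)

    def _surface_point_unchecked(self, u, v, L):
        p = self.params
        a0, b0 = p.xsec_semiaxes(u)
        off = p.offset(L)
        A = a0 + off
        B = b0 + off
        r = p.center_radius(u) + A * np.cos(v)
        x = r * np.cos(u)
        y = r * np.sin(u)
        z = B * np.sin(v) + p.center_z(u)
        return np.stack(np.broadcast_arrays(x, y, z), axis=-1)

    # -- inverse map / classification ------------------------------------
    def invert_points(self, points: np.ndarray):
        """Map points to surface coordinates ``(u, v, off)``.

        Returns
        -------
        u, v, off : ndarray
            Surface coordinates; ``off`` is the normal shell offset in
            um (NaN where inversion fails).
        inside : ndarray of bool
            True where the point lies between the inner GCL and OML
            shells, within the angular ranges.
        """
        p = self.params
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = pts.shape[0]
        u = np.arctan2(pts[:, 1], pts[:, 0])
        a0, b0 = p.xsec_semiaxes(u)
        rr = np.hypot(pts[:, 0], pts[:, 1]) - p.center_radius(u)
        zz = pts[:, 2] - p.center_z(u)

        off_lo, off_hi = p.offset_inner, p.offset_outer
        v = np.full(n, np.nan)
        off = np.full(n, np.nan)
        inside = np.zeros(n, dtype=bool)

        # coarse rejection ring: |rr| and |zz| must fit inside the
        # outermost cross-section ellipse
        cand = (
            (np.abs(rr) <= a0 + off_hi)
            & (np.abs(zz) <= b0 + off_hi)
            & (u >= p.u_min_ml)
            & (u <= p.u_max_ml)
        )
        if not np.any(cand):
            return u, v, off, inside
        idx = np.nonzero(cand)[0]
        rr_c, zz_c = rr[idx], zz[idx]
        a_c, b_c = a0[idx], b0[idx]

        def g(o):
            return (rr_c / (a_c + o)) ** 2 + (zz_c / (b_c + o)) ** 2

        ok = (g(off_lo) >= 1.0) & (g(off_hi) <= 1.0)
        idx = idx[ok]
        if idx.size == 0:
            return u, v, off, inside
        rr_c, zz_c, a_c, b_c = rr_c[ok], zz_c[ok], a_c[ok], b_c[ok]

        lo = np.full(idx.size, off_lo)
        hi = np.full(idx.size, off_hi)
        for _ in range(40):  # bisection: g is strictly decreasing in off
            mid = 0.5 * (lo + hi)
            gm = (rr_c / (a_c + mid)) ** 2 + (zz_c / (b_c + mid)) ** 2
            too_far_out = gm < 1.0
            hi = np.where(too_far_out, mid, hi)
            lo = np.where(too_far_out, lo, mid)
        off_c = 0.5 * (lo + hi)
        v_c = np.arctan2(zz_c / (b_c + off_c), rr_c / (a_c + off_c))

        # v range covers (-0.23 pi, 1.425 pi); with atan2 in (-pi, pi]
        # the excluded arc maps to (-0.575 pi, -0.23 pi)
        v_ok = ~((v_c > p.v_max - 2 * PI) & (v_c < p.v_min))
        # GCL shells only exist over the (narrower) GCL u-range
        u_c = u[idx]
        u_ok = np.where(
            off_c < 0,
            (u_c >= p.u_min_gcl) & (u_c <= p.u_max_gcl),
            (u_c >= p.u_min_ml) & (u_c <= p.u_max_ml),
        )
        keep = v_ok & u_ok
        idx = idx[keep]
        v[idx] = v_c[keep]
        off[idx] = off_c[keep]
        inside[idx] = True
        return u, v, off, inside

    def classify_points(self, points: np.ndarray) -> np.ndarray:
        """Classify points into :class:`LayerLabel` values (vectorized).

        Total function: non-finite coordinates and points outside the
        shell stack map to ``OUTSIDE``.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        labels = np.full(pts.shape[0], int(LayerLabel.OUTSIDE), dtype=np.int8)
        finite = np.all(np.isfinite(pts), axis=1)
        if not np.any(finite):
            return labels
        sub = pts[finite]
        _, _, off, inside = self.invert_points(sub)
        lab = np.full(sub.shape[0], int(LayerLabel.OUTSIDE), dtype=np.int8)
        p = self.params
        # half-open intervals, ties resolved outward
        edges = [p.offset_inner, 0.0, p.w_ml, 2 * p.w_ml, 3 * p.w_ml]
        for lo, hi, label in zip(edges[:-1], edges[1:], _LAYER_SEQUENCE):
            m = inside & (off >= lo) & (off < hi)
            lab[m] = int(label)
        # the outermost shell itself belongs to the OML
        lab[inside & (off >= edges[-1])] = int(LayerLabel.OML)
        labels[finite] = lab
        return labels

    def classify_point(self, point) -> LayerLabel:
        """Classify a single point."""
        return LayerLabel(int(self.classify_points(np.asarray(point)[None, :])[0]))

    def confine_points(self, points: np.ndarray, margin: float = 1.0) -> np.ndarray:
        """Pull radially-escaped points back inside the shell stack.

        Points beyond the outer OML shell (or inside the inner GCL
        shell) along the cross-section are projected to ``margin`` um
        inside the violated boundary, the way granule-cell dendrites
        are physically confined by the hippocampal fissure and hilar
        border.  Points displaced outside the angular ranges are left
        unchanged.
        """
        p = self.params
        pts = np.array(np.atleast_2d(np.asarray(points, dtype=float)))
        inside = self.classify_points(pts) != int(LayerLabel.OUTSIDE)
        bad = np.nonzero(~inside)[0]
        if bad.size == 0:
            return pts
        sub = pts[bad]
        # clamp the septotemporal coordinate to the ML range
        u = np.clip(
            np.arctan2(sub[:, 1], sub[:, 0]),
            p.u_min_ml + 1e-4, p.u_max_ml - 1e-4,
        )
        a0, b0 = p.xsec_semiaxes(u)
        rr = np.hypot(sub[:, 0], sub[:, 1]) - p.center_radius(u)
        zz = sub[:, 2] - p.center_z(u)
        # solve the shell offset on an extended bracket, then clamp it
        lo, hi = p.offset_inner, p.offset_outer
        blo = np.full(bad.size, lo - 300.0)
        bhi = np.full(bad.size, hi + 300.0)
        for _ in range(45):
            mid = 0.5 * (blo + bhi)
            gm = (rr / np.maximum(a0 + mid, 1.0)) ** 2 + (
                zz / np.maximum(b0 + mid, 1.0)
            ) ** 2
            out_of = gm < 1.0
            bhi = np.where(out_of, mid, bhi)
            blo = np.where(out_of, blo, mid)
        off = np.clip(0.5 * (blo + bhi), lo + margin, hi - margin)
        # the GCL shells only exist over the narrower GCL u-range
        in_gcl_u = (u >= p.u_min_gcl) & (u <= p.u_max_gcl)
        off = np.where((off < 0) & ~in_gcl_u, margin, off)
        A, B = a0 + off, b0 + off
        v = np.arctan2(zz / B, rr / A)
        # fold the excluded arc of the open "C" onto its nearest end
        # (strictly inside the arc so reclassification is stable)
        eps = 1e-3
        wrapped_max = p.v_max - 2 * PI
        in_gap = (v > wrapped_max - eps) & (v < p.v_min + eps)
        v = np.where(
            in_gap,
            np.where(v - wrapped_max < p.v_min - v,
                     wrapped_max - eps, p.v_min + eps),
            v,
        )
        r_new = p.center_radius(u) + A * np.cos(v)
        pts[bad, 0] = r_new * np.cos(u)
        pts[bad, 1] = r_new * np.sin(u)
        pts[bad, 2] = B * np.sin(v) + p.center_z(u)
        return pts

    def contains_sphere_in_gcl(self, centers: np.ndarray, radius: float) -> np.ndarray:
        """True where a sphere of ``radius`` fits entirely in the GCL.

        The normal distance to the inner and outer GCL shells is
        evaluated from the shell-offset coordinate times the local
        offset-to-normal rate of the elliptical cross-section.
        """
        p = self.params
        u, v, off, inside = self.invert_points(centers)
        ok = inside & (off < 0)
        if not np.any(ok):
            return np.zeros(len(np.atleast_2d(centers)), dtype=bool)
        a0, b0 = p.xsec_semiaxes(u[ok])
        A = a0 + off[ok]
        B = b0 + off[ok]
        cv, sv = np.cos(v[ok]), np.sin(v[ok])
        # rate of change of normal distance per unit shell offset
        rate = (B * cv ** 2 + A * sv ** 2) / np.hypot(B * cv, A * sv)
        d_outer = (0.0 - off[ok]) * rate
        d_inner = (off[ok] - p.offset_inner) * rate
        fits = (d_outer >= radius) & (d_inner >= radius)
        out = np.zeros_like(ok)
        out[np.nonzero(ok)[0]] = fits
        return out

    def gcl_depth(self, points: np.ndarray) -> np.ndarray:
        """Normalized GCL depth in [0, 1]; 1 = adjacent to the ML."""
        p = self.params
        _, _, off, inside = self.invert_points(points)
        depth = (off - p.offset_inner) / (0.0 - p.offset_inner)
        depth[~inside] = np.nan
        return depth

    # -- bounding box ----------------------------------------------------
    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box ``(lo, hi)`` in um."""
        if self._bbox is None:
            p = self.params
            u = np.linspace(p.u_min_ml, p.u_max_ml, 400)
            v = np.linspace(p.v_min, p.v_max, 400)
            uu, vv = np.meshgrid(u, v, indexing="ij")
            lo = np.full(3, np.inf)
            hi = np.full(3, -np.inf)
            for L in (p.L_inner_gcl, p.L_oml):
                pts = self._surface_point_unchecked(uu, vv, L).reshape(-1, 3)
                lo = np.minimum(lo, pts.min(axis=0))
                hi = np.maximum(hi, pts.max(axis=0))
            pad = 2.0
            self._bbox = (lo - pad, hi + pad)
        return self._bbox

    @property
    def bounding_box_volume_mm3(self) -> float:
        lo, hi = self.bounding_box
        return float(np.prod(hi - lo)) * 1e-9

    # -- boundary clouds -------------------------------------------------
    def boundary_cloud(self, L: float, n: int, seed=0) -> np.ndarray:
        """Sample ``n`` points area-uniformly on the shell at ``L``."""
        p = self.params
        rng = np.random.default_rng(seed)
        umin, umax = (p.u_min_gcl, p.u_max_gcl) if L <= 0 else (p.u_min_ml, p.u_max_ml)
        # numeric area element on a coarse grid for the rejection bound
        gu = np.linspace(umin, umax, 120)
        gv = np.linspace(p.v_min, p.v_max, 120)
        uu, vv = np.meshgrid(gu, gv, indexing="ij")
        jmax = self._area_element(uu.ravel(), vv.ravel(), L).max() * 1.25
        out = []
        got = 0
        while got < n:
            m = max(int((n - got) * 2.2), 1024)
            cu = rng.uniform(umin, umax, m)
            cv = rng.uniform(p.v_min, p.v_max, m)
            jac = self._area_element(cu, cv, L)
            acc = rng.uniform(0.0, jmax, m) < jac
            pts = self._surface_point_unchecked(cu[acc], cv[acc], L)
            out.append(pts)
            got += pts.shape[0]
        return np.concatenate(out, axis=0)[:n]

    def _area_element(self, u, v, L):
        eps = 1e-4
        su1 = self._surface_point_unchecked(u + eps, v, L)
        su0 = self._surface_point_unchecked(u - eps, v, L)
        sv1 = self._surface_point_unchecked(u, v + eps, L)
        sv0 = self._surface_point_unchecked(u, v - eps, L)
        du = (su1 - su0) / (2 * eps)
        dv = (sv1 - sv0) / (2 * eps)
        return np.linalg.norm(np.cross(du, dv), axis=-1)

    def oml_cloud(self, n: int = 2_000_000, seed: int = 12345) -> np.ndarray:
        """Cached OML boundary cloud used for cone orientation."""
        if self._oml_cloud is None or self._oml_cloud.shape[0] < n:
            self._oml_cloud = self.boundary_cloud(self.params.L_oml, n, seed=seed)
            self._oml_tree = None
        return self._oml_cloud[:n]

    def oml_tree(self, n: int = 2_000_000, seed: int = 12345) -> cKDTree:
        if self._oml_tree is None or self._oml_cloud is None or self._oml_cloud.shape[0] != n:
            self._oml_tree = cKDTree(self.oml_cloud(n, seed))
        return self._oml_tree

    def set_oml_cloud_size(self, n: int, seed: int = 12345) -> None:
        """Pre-set the cached OML cloud (small clouds keep tests fast)."""
        self._oml_cloud = self.boundary_cloud(self.params.L_oml, n, seed=seed)
        self._oml_tree = None

    # -- local frames ----------------------------------------------------
    def tangent_frame(self, u, v, L=0.0):
        """Unit (longitudinal, transverse, normal) frame at ``(u, v, L)``.

        Longitudinal follows the septotemporal ``u`` direction,
        transverse the cross-sectional ``v`` direction.
        """
        eps = 1e-4
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        du = (
            self._surface_point_unchecked(u + eps, v, L)
            - self._surface_point_unchecked(u - eps, v, L)
        ) / (2 * eps)
        dv = (
            self._surface_point_unchecked(u, v + eps, L)
            - self._surface_point_unchecked(u, v - eps, L)
        ) / (2 * eps)
        lon = du / np.linalg.norm(du, axis=-1, keepdims=True)
        trans = dv / np.linalg.norm(dv, axis=-1, keepdims=True)
        nrm = np.cross(lon, trans)
        nrm /= np.linalg.norm(nrm, axis=-1, keepdims=True)
        return lon, trans, nrm

    # -- arc length along the septotemporal axis --------------------------
    def _arc_table(self):
        if self._arc_grid is None:
            p = self.params
            u = np.linspace(p.u_min_ml, p.u_max_ml, 2000)
            c = np.stack(
                [p.center_radius(u) * np.cos(u), p.center_radius(u) * np.sin(u), p.center_z(u)],
                axis=-1,
            )
            seg = np.linalg.norm(np.diff(c, axis=0), axis=1)
            s = np.concatenate([[0.0], np.cumsum(seg)])
            self._arc_grid = (u, s)
        return self._arc_grid

    def arc_position(self, u) -> np.ndarray:
        """Arc length (um) along the septotemporal center curve."""
        gu, gs = self._arc_table()
        return np.interp(np.asarray(u, dtype=float), gu, gs)

    # -- meshes -----------------------------------------------------------
    def surface_mesh(self, L: float, nu: int = 51, nv: int = 51):
        """Triangulated shell at ``L``: ``(vertices, faces)``.

        The default grid yields ``2 * (nu-1) * (nv-1) = 5000`` faces.
        """
        p = self.params
        umin, umax = (p.u_min_gcl, p.u_max_gcl) if L <= 0 else (p.u_min_ml, p.u_max_ml)
        u = np.linspace(umin, umax, nu)
        v = np.linspace(p.v_min, p.v_max, nv)
        uu, vv = np.meshgrid(u, v, indexing="ij")
        verts = self._surface_point_unchecked(uu, vv, L).reshape(-1, 3)
        faces = []
        for i in range(nu - 1):
            for j in range(nv - 1):
                k = i * nv + j
                faces.append((k, k + nv, k + 1))
                faces.append((k + 1, k + nv, k + nv + 1))
        return verts, np.asarray(faces, dtype=int)

    def export_off(self, path, L: float, nu: int = 51, nv: int = 51) -> None:
        """Write the shell triangulation as an OFF mesh file."""
        verts, faces = self.surface_mesh(L, nu, nv)
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{len(verts)} {len(faces)} 0\n")
            for x, y, z in verts:
                fh.write(f"{x:.3f} {y:.3f} {z:.3f}\n")
            for a, b, c in faces:
                fh.write(f"3 {a} {b} {c}\n")


# ----------------------------------------------------------------------
# volume and width estimators
# ----------------------------------------------------------------------

def estimate_volume(
    volume,
    layers: Iterable[LayerLabel] | LayerLabel,
    n_samples: int = 1_000_000,
    seed: int = 0,
    chunk: int = 1_000_000,
):
    """Monte-Carlo rejection estimate of the volume of a layer set.

    Parameters
    ----------
    volume
        Object with ``bounding_box`` (um) and ``classify_points``.
    layers
        A :class:`LayerLabel` or iterable thereof.

    Returns
    -------
    vol_mm3, se_mm3 : float
        Estimate and Monte-Carlo standard error, in mm^3.
    """
    if isinstance(layers, LayerLabel):
        layers = (layers,)
    wanted = np.array([int(l) for l in layers])
    lo, hi = volume.bounding_box
    extent = hi - lo
    if np.any(extent <= 0):
        raise ValueError("degenerate bounding box")
    box_mm3 = float(np.prod(extent)) * 1e-9
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        pts = lo + rng.random((m, 3)) * extent
        lab = volume.classify_points(pts)
        hits += int(np.isin(lab, wanted).sum())
        done += m
    p_hat = hits / n_samples
    se = np.sqrt(p_hat * (1 - p_hat) / n_samples)
    return p_hat * box_mm3, se * box_mm3


def ml_width(
    volume,
    n_boundary: int = 2_000_000,
    n_query: int = 10_000,
    seed: int = 0,
):
    """Molecular-layer width: nearest distance, outer GCL -> OML cloud.

    Distributes ``n_boundary`` points on each of the outer GCL and OML
    shells, samples ``n_query`` outer-GCL points and returns the mean
    and standard deviation (um) of their nearest distance to the OML
    cloud.
    """
    if n_boundary < 1 or n_query < 1:
        raise ValueError("empty boundary or query cloud")
    p = volume.params
    gcl = volume.boundary_cloud(p.L_outer_gcl, n_boundary, seed=seed)
    oml = volume.boundary_cloud(p.L_oml, n_boundary, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    q = gcl[rng.choice(n_boundary, size=min(n_query, n_boundary), replace=False)]
    d, _ = cKDTree(oml).query(q, workers=-1)
    return float(d.mean()), float(d.std())


@dataclass
class TransverseSlice:
    """Slab predicate selecting points near one septotemporal position.

    Either an arc position (``u0`` on the center curve, slab measured
    by arc distance) or an explicit plane (``point`` + ``normal``) may
    be given.  Thickness is in um; the selection is the open slab of
    the given thickness.
    """

    volume: DGVolume | None = None
    u0: float | None = None
    point: np.ndarray | None = None
    normal: np.ndarray | None = None
    thickness: float = 200.0

    def __post_init__(self):
        if self.thickness < 0:
            raise ValueError("thickness must be >= 0")
        if self.u0 is not None and self.volume is None:
            raise ValueError("arc-position slices need a volume")

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.u0 is not None:
            u = np.arctan2(pts[:, 1], pts[:, 0])
            s = self.volume.arc_position(u)
            s0 = self.volume.arc_position(self.u0)
            return np.abs(s - s0) < self.thickness / 2.0
        n = np.asarray(self.normal, dtype=float)
        n = n / np.linalg.norm(n)
        d = (pts - np.asarray(self.point, dtype=float)) @ n
        return np.abs(d) < self.thickness / 2.0
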