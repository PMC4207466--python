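"""Parametric volume: forward/inverse consistency, volumes, widths,
slices and the qualitative septal/temporal cross-section shapes."""

import numpy as np
import pytest

from dgforest import (
    DGSurfaceParams,
    DGVolume,
    LayerLabel,
    TransverseSlice,
    estimate_volume,
    ml_width,
)
from dgforest.fixtures import make_toy_volume
from dgforest.geometry import ML_LAYERS


@pytest.fixture(scope="module")
def params():
    return DGSurfaceParams()


def test_forward_inverse_roundtrip(volume, params):
    rng = np.random.default_rng(0)
    u = rng.uniform(params.u_min_gcl, params.u_max_gcl, 500)
    v = rng.uniform(params.v_min, params.v_max, 500)
    L = rng.uniform(params.L_inner_gcl, params.L_oml, 500)
    pts = volume.surface_point(u, v, L)
    uu, vv, off, inside = volume.invert_points(pts)
    assert inside.all()
    np.testing.assert_allclose(off, params.offset(L), atol=1e-6)
    np.testing.assert_allclose(uu, u, atol=1e-9)


def test_boundary_point_classifies_to_bracketing_layer(volume, params):
    """A point just inside the outer GCL shell is GCL; just outside, IML."""
    u, v = 0.5 * np.pi, 0.4 * np.pi
    on = volume.surface_point(u, v, 0.0)
    inward = volume.surface_point(u, v, -0.05)
    outward = volume.surface_point(u, v, 0.05)
    assert volume.classify_point(inward.ravel()) == LayerLabel.GCL
    assert volume.classify_point(outward.ravel()) == LayerLabel.IML
    # midpoint between the L=1 and L=2 shells is MML
    mid = 0.5 * (volume.surface_point(u, v, 1.0) + volume.surface_point(u, v, 2.0))
    assert volume.classify_point(mid.ravel()) == LayerLabel.MML


def test_far_point_is_outside(volume):
    lo, hi = volume.bounding_box
    far = hi + 1000.0
    assert volume.classify_point(far) == LayerLabel.OUTSIDE
    assert volume.classify_point(np.array([np.nan, 0, 0])) == LayerLabel.OUTSIDE


def test_surface_point_domain_errors(volume, params):
    with pytest.raises(ValueError):
        volume.surface_point(params.u_max_gcl + 0.5, 0.0, 0.0)
    with pytest.raises(ValueError):
        volume.surface_point(0.5 * np.pi, params.v_max + 0.5, 0.0)
    with pytest.raises(ValueError):
        volume.surface_point(0.5 * np.pi, 0.0, params.L_oml + 1.0)


def test_layer_ordering_along_outward_ray(volume, params):
    """Along increasing L the labels march GCL->IML->MML->OML->OUTSIDE."""
    u, v = 0.45 * np.pi, 0.3 * np.pi
    Ls = np.linspace(params.L_inner_gcl + 0.01, params.L_oml - 0.01, 60)
    pts = volume.surface_point(np.full_like(Ls, u), np.full_like(Ls, v), Ls)
    labels = volume.classify_points(pts)
    diffs = np.diff(labels.astype(int))
    assert np.all(diffs >= 0), "labels must be monotone along outward ray"
    assert set(labels) == {1, 2, 3, 4}
    beyond = pts[-1] + 500.0 * (pts[-1] - pts[-2]) / np.linalg.norm(pts[-1] - pts[-2])
    assert volume.classify_point(beyond) == LayerLabel.OUTSIDE


def test_monte_carlo_volume_against_closed_forms():
    sphere = make_toy_volume("sphere", radius=1000.0)
    v, se = estimate_volume(sphere, LayerLabel.GCL, n_samples=200_000, seed=1)
    assert v == pytest.approx(4.18879, abs=max(3 * se, 0.02))
    box = make_toy_volume("box", size=(100.0, 100.0, 100.0))
    v, se = estimate_volume(box, LayerLabel.GCL, n_samples=200_000, seed=2)
    assert v == pytest.approx(1e-3, abs=3 * se + 1e-5)


def test_volume_additivity(volume):
    parts = [
        estimate_volume(volume, l, n_samples=400_000, seed=int(l))
        for l in ML_LAYERS
    ]
    total, se_t = estimate_volume(volume, ML_LAYERS, n_samples=400_000, seed=9)
    s = sum(p[0] for p in parts)
    err = np.sqrt(sum(p[1] ** 2 for p in parts) + se_t ** 2)
    assert s == pytest.approx(total, abs=4 * err)


def test_ml_width_on_concentric_shells():
    shell = make_toy_volume("shell", radius=500.0, width=120.0)
    mean, sd = ml_width(shell, n_boundary=60_000, n_query=2_000, seed=3)
    assert mean == pytest.approx(120.0, abs=1.5)
    assert sd < 3.0


def test_ml_width_converges_with_cloud_size(volume):
    m1, _ = ml_width(volume, n_boundary=300_000, n_query=3_000, seed=4)
    m2, _ = ml_width(volume, n_boundary=600_000, n_query=3_000, seed=4)
    assert abs(m1 - m2) < 1.5


def _crest_curvature_ratio(volume, u0):
    """Curvature at the crest of the transverse C-curve over its mean."""
    p = volume.params
    v = np.linspace(p.v_min, p.v_max, 800)
    pts = volume.surface_point(np.full_like(v, u0), v, 0.0)
    d1 = np.gradient(pts, v, axis=0)
    d2 = np.gradient(d1, v, axis=0)
    cross = np.linalg.norm(np.cross(d1, d2), axis=1)
    kappa = cross / np.linalg.norm(d1, axis=1) ** 3
    crest = np.argmin(np.abs(v - p.v_mid))
    return kappa[crest] / kappa.mean()


def test_septal_sections_sharper_than_temporal(volume, params):
    """Septal transverse sections are V-like (sharper crest) while
    temporal sections are U-like."""
    septal = _crest_curvature_ratio(volume, params.u_min_gcl + 0.05)
    temporal = _crest_curvature_ratio(volume, params.u_max_gcl - 0.05)
    assert septal > temporal


def test_transverse_slice_selects_slab(volume, somata):
    zero = TransverseSlice(volume=volume, u0=0.5 * np.pi, thickness=0.0)
    assert not zero(somata.centers[:5000]).any()

    sl = TransverseSlice(volume=volume, u0=0.5 * np.pi, thickness=20.0)
    picked = sl(somata.centers)
    # count ~ slab volume x packing density: slab GCL volume =
    # GCL volume x (20 um / septotemporal arc length)
    arc = volume.arc_position(volume.params.u_max_gcl) - volume.arc_position(
        volume.params.u_min_gcl
    )
    expected = len(somata) * 20.0 / arc
    assert picked.sum() == pytest.approx(expected, rel=0.35)


def test_mesh_export_off(tmp_path, volume):
    path = tmp_path / "gcl.off"
    volume.export_off(path, L=0.0, nu=11, nv=11)
    lines = path.read_text().splitlines()
    assert lines[0] == "OFF"
    nv, nf, _ = map(int, lines[1].split())
    assert nv == 121 and nf == 200
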