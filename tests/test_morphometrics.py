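"""Morphometrics: closed-form fixture oracles and population
aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dgforest.fixtures import make_fixture_tree
from dgforest.morphometrics import (
    asymmetry,
    branch_stats,
    contraction,
    laminar_distribution,
    population_summary,
    se_to_sd,
    sholl,
    spreads,
)
from dgforest.tree import MorphTree


def test_sholl_straight_dendrite_is_one_everywhere():
    t = make_fixture_tree("straight", length=100.0).tree
    radii, counts = sholl(t, step=10.0)
    assert counts[0] == 1  # radius 0 -> stem count
    assert np.all(counts[1:10] == 1)


def test_sholl_y_tree_counts_two_past_branch():
    t = make_fixture_tree("y", stem=50.0, arm=50.0).tree
    radii, counts = sholl(t, step=25.0)
    assert counts[radii == 25.0] == 1
    assert counts[radii == 75.0] == 2


def test_sholl_zero_radius_equals_stems(population200):
    for t in population200[:10]:
        radii, counts = sholl(t)
        assert counts[0] == t.n_stems


def test_sholl_matches_dense_sampling_oracle(population200):
    """Crossing counts equal sign-change counts of (|p|-r) along a
    densely interpolated polyline."""
    for t in population200[:8]:
        radii, counts = sholl(t, step=40.0)
        d = np.linalg.norm(t.coords - t.coords[0], axis=1)
        for r, c in zip(radii[1:], counts[1:]):
            oracle = 0
            for i in range(1, t.n_nodes):
                a, b = d[t.parent[i]], d[i]
                # dense subdivision of the chord: |p(t)| is monotone
                # between endpoints in the straddle sense
                s = np.linspace(0, 1, 20)
                dd = np.linalg.norm(
                    t.coords[t.parent[i]][None, :] * (1 - s[:, None])
                    + t.coords[i][None, :] * s[:, None]
                    - t.coords[0],
                    axis=1,
                )
                oracle += int(np.sum(np.diff(np.sign(dd - r)) != 0) % 2 == 1)
            assert c == oracle


def test_contraction_straight_and_right_angle():
    t = make_fixture_tree("straight").tree
    assert contraction(t) == pytest.approx([1.0])
    coords = np.array([[0, 0, 0], [30.0, 0, 0], [30.0, 40.0, 0]])
    t2 = MorphTree(coords=coords, parent=np.array([-1, 0, 1]))
    assert contraction(t2) == pytest.approx([50.0 / 70.0])


def test_contraction_in_unit_interval(population200):
    for t in population200[:20]:
        c = contraction(t)
        assert np.all((c > 0) & (c <= 1 + 1e-12))


def test_branch_stats_full_binary_tree():
    fx = make_fixture_tree("binary", levels=3)
    bs = branch_stats(fx.tree)
    assert bs["n_branches"] == fx.expected["n_branches"] == 7
    assert bs["max_branch_order"] == fx.expected["max_branch_order"] == 2
    assert bs["n_tips"] == 4


def test_branch_stats_soma_only_degenerate():
    t = MorphTree(coords=np.zeros((1, 3)), parent=np.array([-1]))
    bs = branch_stats(t)
    assert bs["degenerate"] and bs["n_branches"] == 0


def test_branch_length_sum_equals_total_length(population200):
    for t in population200[:15]:
        branches = t.branches()
        s = sum(
            np.linalg.norm(np.diff(t.coords[br], axis=0), axis=1).sum()
            for br in branches
        )
        assert s == pytest.approx(t.total_length, rel=1e-9)


def test_asymmetry_closed_forms():
    assert asymmetry(make_fixture_tree("binary", levels=4).tree) == 0.0
    assert asymmetry(make_fixture_tree("comb", n_tips=8).tree) == pytest.approx(6.0 / 7.0)
    with pytest.raises(ValueError):
        asymmetry(make_fixture_tree("straight").tree)


def test_asymmetry_bounded(population200):
    vals = [asymmetry(t) for t in population200[:40]]
    assert np.all((np.array(vals) >= 0) & (np.array(vals) <= 1))


def test_spreads_rotation_swaps_axes(volume, population200):
    t = population200[0]
    s_t, s_l = spreads(t, volume)
    soma = t.coords[0]
    u, v, _, _ = volume.invert_points(soma[None, :])
    lon, trans, _ = volume.tangent_frame(u[0], v[0], 0.0)
    e1 = trans / np.linalg.norm(trans)
    e2 = lon - (lon @ e1) * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    # rotate the tree 90 degrees about the local normal
    w = t.coords - soma
    a, b, c = w @ e1, w @ e2, w @ e3
    rot = t.copy()
    rot.coords = soma + np.outer(-b, e1) + np.outer(a, e2) + np.outer(c, e3)
    r_t, r_l = spreads(rot, volume)
    assert r_t == pytest.approx(s_l, rel=0.05)
    assert r_l == pytest.approx(s_t, rel=0.05)


def test_laminar_distribution_single_layer():
    # a little tree tagged entirely MML
    coords = np.array([[0, 0, 0], [10.0, 0, 0], [20.0, 0, 0], [20.0, 10.0, 0]])
    t = MorphTree(coords=coords, parent=np.array([-1, 0, 1, 1]))
    t.layer = np.full(4, 3, dtype=np.int8)  # MML
    lam = laminar_distribution(t)
    assert lam.loc["MML", "pct_length"] == pytest.approx(100.0)
    assert lam["pct_length"].sum() == pytest.approx(100.0)


def test_laminar_percentages_sum_to_100(volume, population200):
    for t in population200[:10]:
        lam = laminar_distribution(t, volume=volume)
        assert lam["pct_length"].sum() == pytest.approx(100.0, abs=0.5)
        assert lam["pct_branch_points"].sum() == pytest.approx(100.0, abs=0.5)


def test_gcl_folds_into_iml(volume):
    coords = np.array([[0, 0, 0], [10.0, 0, 0]])
    t = MorphTree(coords=coords, parent=np.array([-1, 0]))
    t.layer = np.array([1, 1], dtype=np.int8)  # GCL
    lam = laminar_distribution(t)
    assert lam.loc["IML", "pct_length"] == pytest.approx(100.0)


def test_se_to_sd_conventions():
    assert se_to_sd(2.0, 25) == pytest.approx(10.0)
    assert se_to_sd(2.0, 25, convention="stated") == pytest.approx(50.0)
    with pytest.raises(ValueError):
        se_to_sd(1.0, 10, convention="bogus")


def test_population_summary_degenerate_duplicates(volume, population200):
    dup = [population200[0]] * 3 + [population200[1]] * 3
    for k, t in enumerate(dup):
        t = t.copy()
        t.subgroup = 0 if k < 3 else 2  # supra vs infra blades
        dup[k] = t
    s = population_summary(dup, volume)
    sub = s.per_cell[s.per_cell.subgroup == 0]
    assert sub["total_length"].std() == pytest.approx(0.0)


def test_ttest_matches_textbook_formula(volume, population200):
    s = population_summary(population200, volume)
    df = s.per_cell
    a = df[df.blade == "supra"]["total_length"].to_numpy()
    b = df[df.blade == "infra"]["total_length"].to_numpy()
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    t_pkg = s.ttests.loc["total_length:supra-vs-infra", "t"]
    assert t_pkg == pytest.approx(t_hand, rel=1e-9)
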