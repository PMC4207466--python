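"""Single-cell and population morphometrics for validation.

Implements the statistics used to compare synthetic granule cells with
experimental reconstructions: Sholl intersection profiles, branch
counts and orders, branch-length statistics, contraction, partition
(topological) asymmetry, transverse/longitudinal spreads, laminar
distributions of branch points and dendritic length, and population
aggregation with subgroup contrasts (Student's t-test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import LayerLabel
from .packing import Subgroup
from .tree import MorphTree

__all__ = [
    "sholl",
    "contraction",
    "branch_stats",
    "asymmetry",
    "spreads",
    "laminar_distribution",
    "cell_metrics",
    "population_summary",
    "se_to_sd",
]


def sholl(tree: MorphTree, step: float = 20.0) -> tuple[np.ndarray, np.ndarray]:
    """Sholl profile: dendrite crossings of concentric spheres.

    Spheres are centered on the root with radii ``0, step, 2*step, ...``
    up to the outermost node.  A segment is counted at radius ``r``
    when its two endpoint distances from the root straddle ``r``
    (``min < r <= max``).  At radius 0 the count is the stem number.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    d = np.linalg.norm(tree.coords - tree.coords[0], axis=1)
    d0 = d[tree.parent[1:]]
    d1 = d[1:]
    lo = np.minimum(d0, d1)
    hi = np.maximum(d0, d1)
    rmax = d.max()
    radii = step * np.arange(0, int(np.floor(rmax / step)) + 1)
    counts = np.array([(lo < r) & (r <= hi) for r in radii]).sum(axis=1)
    if len(counts):
        counts[0] = tree.n_stems
    return radii, counts


def contraction(tree: MorphTree) -> np.ndarray:
    """Per-branch ratio of Euclidean to path distance, in (0, 1]."""
    out = []
    for br in tree.branches():
        pts = tree.coords[br]
        path = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        if path <= 0:
            continue
        out.append(float(np.linalg.norm(pts[-1] - pts[0])) / path)
    return np.asarray(out)


def branch_stats(tree: MorphTree) -> dict:
    """Branch bookkeeping: counts, orders and branch lengths.

    Branches are paths between topological points (root, branch
    points, tips); a branch is *terminal* when it ends in a tip and
    *intermediate* otherwise.  Branch order counts the branch points
    on the path from the root.  A soma-only tree returns zeros with
    ``degenerate=True``.
    """
    if tree.n_nodes == 1:
        return {
            "n_stems": 0, "n_branches": 0, "max_branch_order": 0,
            "n_branch_points": 0, "n_tips": 0,
            "mean_intermediate_branch_length": 0.0,
            "mean_terminal_branch_length": 0.0,
            "total_length": 0.0, "mean_path_to_tips": 0.0,
            "degenerate": True,
        }
    nc = tree.n_children
    branches = tree.branches()
    lengths = np.array(
        [np.linalg.norm(np.diff(tree.coords[br], axis=0), axis=1).sum() for br in branches]
    )
    terminal = np.array([nc[br[-1]] == 0 for br in branches])
    order = tree.branch_order()
    pl = tree.path_length
    tips = tree.tips
    return {
        "n_stems": tree.n_stems,
        "n_branches": len(branches),
        "max_branch_order": int(order.max()),
        "n_branch_points": len(tree.branch_point_nodes),
        "n_tips": len(tips),
        "mean_intermediate_branch_length": float(lengths[~terminal].mean())
        if np.any(~terminal) else 0.0,
        "mean_terminal_branch_length": float(lengths[terminal].mean())
        if np.any(terminal) else 0.0,
        "total_length": float(lengths.sum()),
        "mean_path_to_tips": float(pl[tips].mean()),
        "degenerate": False,
    }


def asymmetry(tree: MorphTree) -> float:
    """Mean partition asymmetry over bifurcation points.

    For a bifurcation splitting the terminal tips into subtrees of
    ``l`` and ``r`` tips, the partition asymmetry is
    ``|l - r| / (l + r - 2)`` (0 for the degree-2 partition
    ``l = r = 1``); the tree value is the mean over bifurcations.
    Degree-2 partitions (``l = r = 1``) contribute 0, so a finite comb
    with ``n`` tips scores ``(n-2)/(n-1)`` (approaching 1).  The
    measure is defined for binary partitions; higher-order branch
    points (rare in wired trees) are excluded, with a mean over child
    pairs as a fallback for trees that have only multifurcations.
    """
    bps = tree.branch_point_nodes
    if len(bps) == 0:
        raise ValueError("asymmetry requires at least one branch point")
    tipc = tree.subtree_tip_counts()
    kids: dict[int, list[int]] = {}
    for i in range(1, tree.n_nodes):
        kids.setdefault(int(tree.parent[i]), []).append(i)

    def partition(l, r):
        return abs(l - r) / (l + r - 2) if l + r > 2 else 0.0

    vals = []
    fallback = []
    for b in bps:
        c = [tipc[k] for k in kids[int(b)]]
        if len(c) == 2:
            vals.append(partition(*c))
        else:
            fallback.append(
                np.mean([partition(c[i], c[j])
                         for i in range(len(c)) for j in range(i + 1, len(c))])
            )
    if vals:
        return float(np.mean(vals))
    return float(np.mean(fallback))


def spreads(tree: MorphTree, volume) -> tuple[float, float]:
    """Transverse and longitudinal dendritic spread (um).

    Terminal tips are projected into the local surface-tangent plane
    at the soma; the mean transverse axis is the principal direction
    of the projected tips, and each spread is the extent of the tip
    cloud along that axis / the in-plane orthogonal (septotemporal)
    axis.
    """
    soma = tree.coords[0]
    u, v, _, inside = volume.invert_points(soma[None, :])
    if not inside[0]:
        raise ValueError("soma outside the volume")
    lon, trans, _ = volume.tangent_frame(u[0], v[0], 0.0)
    # orthonormal in-plane basis (u and v tangents are oblique)
    e1 = trans / np.linalg.norm(trans)
    e2 = lon - (lon @ e1) * e1
    e2 = e2 / np.linalg.norm(e2)
    tips = tree.coords[tree.tips]
    if len(tips) < 2:
        return 0.0, 0.0
    w = tips - soma
    xy = np.stack([w @ e1, w @ e2], axis=1)
    xy_c = xy - xy.mean(axis=0)
    _, _, vt = np.linalg.svd(xy_c, full_matrices=False)
    pc1, pc2 = vt[0], vt[1]
    # keep "transverse" the axis closer to the v tangent
    if abs(pc1[0]) < abs(pc2[0]):
        pc1, pc2 = pc2, pc1
    s_t = float(np.ptp(xy @ pc1))
    s_l = float(np.ptp(xy @ pc2))
    return s_t, s_l


def laminar_distribution(tree: MorphTree, volume=None) -> pd.DataFrame:
    """Per-layer percentages of branch points and dendritic length.

    Segment length is attributed to the layer of the segment midpoint;
    GCL branch points and length are folded into the IML, matching the
    convention of the experimental reference.  Percentages are over
    in-structure segments (IML + MML + OML = 100).
    """
    if tree.layer is None and volume is None:
        raise ValueError("tree has no layer tags and no volume was given")
    mids = 0.5 * (tree.coords[1:] + tree.coords[tree.parent[1:]])
    if volume is not None:
        seg_lab = volume.classify_points(mids)
        node_lab = volume.classify_points(tree.coords)
    else:
        node_lab = tree.layer
        seg_lab = np.maximum(node_lab[1:], node_lab[tree.parent[1:]])
    seg_len = tree.edge_lengths[1:]
    bp_lab = np.asarray(node_lab)[tree.branch_point_nodes]

    def fold(lab):
        lab = np.asarray(lab, dtype=int).copy()
        lab[lab == int(LayerLabel.GCL)] = int(LayerLabel.IML)
        return lab

    seg_lab = fold(seg_lab)
    bp_lab = fold(bp_lab)
    rows = {}
    lsum = sum(seg_len[seg_lab == int(l)].sum() for l in (LayerLabel.IML, LayerLabel.MML, LayerLabel.OML))
    bsum = sum((bp_lab == int(l)).sum() for l in (LayerLabel.IML, LayerLabel.MML, LayerLabel.OML))
    for l in (LayerLabel.IML, LayerLabel.MML, LayerLabel.OML):
        pl = 100.0 * seg_len[seg_lab == int(l)].sum() / lsum if lsum > 0 else np.nan
        pb = 100.0 * (bp_lab == int(l)).sum() / bsum if bsum > 0 else np.nan
        rows[l.name] = {"pct_branch_points": pb, "pct_length": pl}
    return pd.DataFrame(rows).T


def cell_metrics(tree: MorphTree, volume) -> dict:
    """All per-cell scalar morphometrics used in the population tables."""
    bs = branch_stats(tree)
    out = {k: v for k, v in bs.items() if k != "degenerate"}
    out["asymmetry"] = asymmetry(tree) if bs["n_branch_points"] else np.nan
    s_t, s_l = spreads(tree, volume)
    out["transverse_spread"] = s_t
    out["longitudinal_spread"] = s_l
    lam = laminar_distribution(tree, volume=volume)
    for layer in lam.index:
        out[f"pct_bp_{layer}"] = lam.loc[layer, "pct_branch_points"]
        out[f"pct_len_{layer}"] = lam.loc[layer, "pct_length"]
    out["mean_contraction"] = float(np.mean(contraction(tree)))
    out["subgroup"] = tree.subgroup
    out["cell_id"] = tree.cell_id
    return out


@dataclass
class PopulationSummary:
    per_cell: pd.DataFrame
    overall: pd.DataFrame          # mean/sd per metric
    by_subgroup: pd.DataFrame      # mean/sd per metric and subgroup
    by_blade: pd.DataFrame
    ttests: pd.DataFrame           # supra-vs-infra contrasts


# named subgroup contrasts: (metric, group A mask name, group B mask name)
_CONTRASTS = (
    ("n_branches", "supra", "infra"),
    ("total_length", "supra", "infra"),
    ("transverse_spread", "supra", "infra"),
    ("n_stems", "supra_superficial", "supra_deep"),
    ("max_branch_order", "supra_superficial", "supra_deep"),
)


def population_summary(trees, volume) -> PopulationSummary:
    """Aggregate per-cell metrics into population tables.

    Means and population standard deviations are reported overall, per
    subgroup and per blade; suprapyramidal-vs-infrapyramidal contrasts
    use the two-sample Student t-test.  Degenerate contrasts (zero
    variance or an empty group) are flagged with NaN statistics.
    """
    rows = [cell_metrics(t, volume) for t in trees]
    df = pd.DataFrame(rows)
    df["blade"] = [
        Subgroup(int(s)).blade if s is not None and not np.isnan(s) else "?"
        for s in df["subgroup"]
    ]
    num = df.select_dtypes("number").drop(columns=["cell_id", "subgroup"], errors="ignore")
    overall = pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=0)})
    by_subgroup = df.groupby("subgroup")[num.columns].agg(["mean", "std"])
    by_blade = df.groupby("blade")[num.columns].agg(["mean", "std"])
    groups = {
        "supra": df[df.blade == "supra"],
        "infra": df[df.blade == "infra"],
        "supra_superficial": df[df.subgroup == int(Subgroup.SUPRA_SUPERFICIAL)],
        "supra_deep": df[df.subgroup == int(Subgroup.SUPRA_DEEP)],
    }
    t_rows = {}
    for m, ga, gb in _CONTRASTS:
        a, b = groups[ga][m], groups[gb][m]
        key = f"{m}:{ga}-vs-{gb}"
        if len(a) < 2 or len(b) < 2 or (a.std() == 0 and b.std() == 0):
            t_rows[key] = {"t": np.nan, "p": np.nan, "degenerate": True}
        else:
            t, p = stats.ttest_ind(a, b)
            t_rows[key] = {"t": float(t), "p": float(p), "degenerate": False}
    return PopulationSummary(
        per_cell=df,
        overall=overall,
        by_subgroup=by_subgroup,
        by_blade=by_blade,
        ttests=pd.DataFrame(t_rows).T,
    )


def se_to_sd(se: float, n: int, convention: str = "sqrt") -> float:
    """Convert a reported standard error to a standard deviation.

    ``convention="sqrt"`` (default) applies the conventional
    ``sd = se * sqrt(n)``.  ``convention="stated"`` multiplies by the
    sample size itself, reproducing verbatim the conversion described
    with the literature reference values; both are provided because
    the stated procedure differs from the conventional one.
    """
    if convention == "sqrt":
        return float(se) * float(np.sqrt(n))
    if convention == "stated":
        return float(se) * float(n)
    raise ValueError("convention must be 'sqrt' or 'stated'")
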