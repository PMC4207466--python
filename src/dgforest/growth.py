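"""Dendritic tree growth by greedy optimal wiring.

Trees are grown by sequentially connecting target points so as to
minimize a combined wiring cost: the total dendritic length plus a
balancing factor ``bf`` times the path length from the root.  At every
step the unconnected target ``t`` with the smallest attachment cost

    cost(t) = min over tree nodes n of  ||t - n|| + bf * (plen(n) + ||t - n||)

is attached to its minimizing node, where ``plen(n)`` is the path
length from the root to ``n``; the second term is the path length the
new point would acquire, so the greedy step minimizes the increment of
``total length + bf * sum of path lengths``.  ``bf = 0`` reduces
exactly to Prim's minimum spanning tree; large ``bf`` drives trees
toward star-like, short-path topologies.  Balancing factors above 1
remain meaningful in this parameterization (the printed granule-cell
values reach 1.35).

After wiring, trees are resampled to a 5 um segment interval, roughed
up with smooth spatial noise at two length constants (10 and 50 um) to
reproduce the tortuosity of real dendrites, and given a quadratic
diameter taper toward the tips with an ``expm1`` ramp suppressing the
taper right at the soma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import factorial

from .targets import EllipticalCone, draw_quota, orient_cone, sample_in_cone, sample_targets
from .tree import MorphTree

__all__ = [
    "GrowthParams",
    "grow_tree",
    "init_stems",
    "resample_tree",
    "apply_jitter",
    "apply_taper",
    "generate_cell",
    "truncated_poisson_pmf",
    "sample_truncated_poisson",
    "poisson_lambda_for_mean",
]


# ----------------------------------------------------------------------
# truncated-Poisson stem sampler
# ----------------------------------------------------------------------

def truncated_poisson_pmf(lam: float, lo: int = 1, hi: int = 4) -> np.ndarray:
    """Pmf of a Poisson(lam) conditioned on the support [lo, hi]."""
    k = np.arange(lo, hi + 1)
    w = lam ** k / factorial(k)
    return w / w.sum()


def sample_truncated_poisson(lam: float, size, rng, lo: int = 1, hi: int = 4):
    pmf = truncated_poisson_pmf(lam, lo, hi)
    return rng.choice(np.arange(lo, hi + 1), size=size, p=pmf)


def poisson_lambda_for_mean(target_mean: float, lo: int = 1, hi: int = 4) -> float:
    """Rate of the truncated Poisson whose mean equals ``target_mean``."""
    k = np.arange(lo, hi + 1)

    def mean(lam):
        pmf = truncated_poisson_pmf(lam, lo, hi)
        return float(pmf @ k)

    if not (lo < target_mean < hi):
        raise ValueError(f"target mean must lie in ({lo}, {hi})")
    return brentq(lambda l: mean(l) - target_mean, 1e-6, 200.0)


# ----------------------------------------------------------------------
# greedy optimal wiring
# ----------------------------------------------------------------------

def grow_tree(
    root: np.ndarray,
    targets: np.ndarray,
    bf: float,
    n_lock_stems: int = 0,
) -> MorphTree:
    """Grow a tree over ``targets`` from ``root`` (topology only).

    With ``n_lock_stems > 0`` the first ``n_lock_stems`` targets are
    attached directly to the root, after which the root accepts no
    further children, so the root degree equals the stem count.  Ties
    in the attachment cost resolve to the lowest target index.
    """
    if bf < 0:
        raise ValueError("bf must be >= 0")
    root = np.asarray(root, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    m = targets.shape[0]
    if m == 0 or targets.size == 0:
        warnings.warn("no targets: returning soma-only tree")
        return MorphTree(coords=root[None, :], parent=np.array([-1]))

    coords = np.empty((m + 1, 3))
    parent = np.empty(m + 1, dtype=int)
    plen = np.empty(m + 1)
    coords[0] = root
    parent[0] = -1
    plen[0] = 0.0
    n_nodes = 1

    n_lock = min(n_lock_stems, m)
    for k in range(n_lock):
        d = float(np.linalg.norm(targets[k] - root))
        coords[n_nodes] = targets[k]
        parent[n_nodes] = 0
        plen[n_nodes] = d
        n_nodes += 1

    rem = np.arange(n_lock, m)
    if rem.size:
        # initialize best attachment over currently allowed nodes
        best_cost = np.full(rem.size, np.inf)
        best_par = np.full(rem.size, -1, dtype=int)
        allowed = range(1, n_nodes) if n_lock else range(0, n_nodes)
        for j in allowed:
            d = np.linalg.norm(targets[rem] - coords[j], axis=1)
            c = (1.0 + bf) * d + bf * plen[j]
            better = c < best_cost
            best_cost[better] = c[better]
            best_par[better] = j

        alive = np.ones(rem.size, dtype=bool)
        for _ in range(rem.size):
            masked = np.where(alive, best_cost, np.inf)
            i = int(np.argmin(masked))  # first minimum -> lowest index
            t = rem[i]
            j = best_par[i]
            d = float(np.linalg.norm(targets[t] - coords[j]))
            coords[n_nodes] = targets[t]
            parent[n_nodes] = j
            plen[n_nodes] = plen[j] + d
            alive[i] = False
            # relax remaining targets against the new node
            if alive.any():
                da = np.linalg.norm(targets[rem[alive]] - coords[n_nodes], axis=1)
                ca = (1.0 + bf) * da + bf * plen[n_nodes]
                sub = np.nonzero(alive)[0]
                better = ca < best_cost[sub]
                best_cost[sub[better]] = ca[better]
                best_par[sub[better]] = n_nodes
            n_nodes += 1

    return MorphTree(coords=coords[:n_nodes], parent=parent[:n_nodes])


def init_stems(cone: EllipticalCone, n_stems: int, rng, stem_length: float = 10.0):
    """Seed points for the primary dendrites, inside the cone opening.

    Returns ``n_stems`` points sampled uniformly in the cone
    cross-section at height ``stem_length``; prepended to the target
    list and force-attached to the root, they realize the drawn stem
    count exactly.
    """
    if not 1 <= n_stems <= 4:
        raise ValueError("stem count must be in [1, 4]")
    scale = stem_length / cone.height
    r = np.sqrt(rng.random(n_stems))
    th = rng.uniform(0, 2 * np.pi, n_stems)
    x = r * np.cos(th) * cone.radius_t * scale
    y = r * np.sin(th) * cone.radius_l * scale
    return (
        cone.apex
        + stem_length * cone.axis
        + np.outer(x, cone.t_hat)
        + np.outer(y, cone.l_hat)
    )


# ----------------------------------------------------------------------
# resampling, jitter, taper
# ----------------------------------------------------------------------

def resample_tree(tree: MorphTree, spacing: float = 5.0) -> MorphTree:
    """Resample every branch to a fixed ~``spacing`` segment interval.

    Branch and termination points are preserved exactly; interior
    nodes are re-spaced evenly along each branch polyline (segment
    count ``max(1, round(length / spacing))``), so total length can
    only decrease, by less than the tortuosity between old nodes.
    """
    if tree.n_nodes == 1:
        return tree.copy()
    branches = tree.branches()
    diam = tree.diam
    new_coords = [tree.coords[0]]
    new_parent = [-1]
    new_diam = [diam[0]]
    topo_map = {0: 0}
    for br in branches:
        pts = tree.coords[br]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        length = arc[-1]
        n_seg = max(1, int(round(length / spacing))) if length > 0 else 1
        s_new = np.linspace(0.0, length, n_seg + 1)[1:]
        prev = topo_map[int(br[0])]
        d_br = diam[br]
        for si, s in enumerate(s_new):
            idx = len(new_coords)
            if si == len(s_new) - 1:
                c = pts[-1]
                dd = d_br[-1]
            else:
                c = np.array([np.interp(s, arc, pts[:, k]) for k in range(3)])
                dd = np.interp(s, arc, d_br)
            new_coords.append(c)
            new_parent.append(prev)
            new_diam.append(dd)
            prev = idx
        topo_map[int(br[-1])] = prev
    return MorphTree(
        coords=np.asarray(new_coords),
        parent=np.asarray(new_parent),
        diam=np.asarray(new_diam),
        cell_id=tree.cell_id,
        subgroup=tree.subgroup,
    )


def apply_jitter(
    tree: MorphTree,
    amplitudes=(1.6, 6.0),
    length_constants=(10.0, 50.0),
    seed=0,
    n_features: int = 64,
) -> MorphTree:
    """Displace nodes with smooth homogeneous spatial noise.

    For each length constant a stationary Gaussian random displacement
    field with squared-exponential correlation is realized by random
    Fourier features and evaluated at the node positions, so connected
    nodes move coherently and branch points stay attached to their
    branches.  The root is pinned (the field value at the root is
    subtracted); topology and diameters are unchanged.  Amplitudes are
    the per-axis displacement standard deviations in um.
    """
    out = tree.copy()
    if all(a == 0 for a in amplitudes):
        return out
    rng = np.random.default_rng(seed)
    disp = np.zeros_like(out.coords)
    for amp, ell in zip(amplitudes, length_constants):
        if amp == 0:
            continue
        for comp in range(3):
            omega = rng.normal(0.0, 1.0 / ell, size=(n_features, 3))
            phi = rng.uniform(0, 2 * np.pi, n_features)
            f = np.cos(out.coords @ omega.T + phi).sum(axis=1)
            disp[:, comp] += amp * np.sqrt(2.0 / n_features) * f
    disp -= disp[0]
    out.coords = out.coords + disp
    return out


def apply_taper(
    tree: MorphTree,
    d_max: float = 2.2,
    d_tip: float = 0.65,
    lambda_soma: float = 4.0,
    soma_diameter: float = 12.54,
    min_diam: float = 0.3,
) -> MorphTree:
    """Map diameters onto a finished topology.

    The dendritic diameter follows a quadratic taper in path distance
    ``x`` from the soma, ``d(x) = d_tip + (d_max - d_tip) (1 - x/X)^2``
    with ``X`` the maximal path length, multiplied by the near-soma
    ramp ``min(1, expm1(x / lambda_soma))``.  With the default
    ``lambda_soma`` the ramp saturates within the first segment, so
    diameters are non-increasing along every root-to-tip path.  The
    root keeps the soma diameter; diameters never fall below
    ``min_diam`` (clamped with a warning).
    """
    out = tree.copy()
    pl = out.path_length
    X = pl.max()
    if X <= 0:
        out.diam = np.full(out.n_nodes, soma_diameter)
        return out
    base = d_tip + (d_max - d_tip) * (1.0 - pl / X) ** 2
    ramp = np.minimum(1.0, np.expm1(pl / lambda_soma))
    d = base * ramp
    if np.any(d[1:] < min_diam):
        warnings.warn("taper produced sub-minimum diameters; clamping")
        d = np.maximum(d, min_diam)
    # the near-soma ramp can undercut a node's descendants when jitter
    # shortens the first arc; lift such nodes to their subtree maximum
    # so diameters are non-increasing along every root-to-tip path
    for i in range(out.n_nodes - 1, 0, -1):
        p = out.parent[i]
        if p > 0 and d[p] < d[i]:
            d[p] = d[i]
    d[0] = soma_diameter
    out.diam = d
    return out


# ----------------------------------------------------------------------
# per-cell parameters and full pipeline
# ----------------------------------------------------------------------

@dataclass
class GrowthParams:
    """Per-subgroup generation parameters (units um unless noted).

    The defaults are placeholders; the calibrated per-subgroup tables
    live in :mod:`dgforest.config`.
    """

    bf: float = 1.0                     # balancing factor, dimensionless
    stem_mean: float = 1.8              # mean of the truncated-Poisson stem count
    stem_length: float = 10.0
    quota_means: dict = field(
        default_factory=lambda: {1: 2.0, 2: 25.0, 3: 18.0, 4: 14.0}
    )                                   # LayerLabel code -> mean target count
    radius_t_mean: float = 160.0        # transverse cone semi-axis
    radius_t_sd: float = 25.0
    radius_ratio: float = 0.55          # longitudinal / transverse
    # radial bias of target placement per layer (0.5 = area-uniform;
    # smaller = rim-biased): proximal targets hug the trunks, distal
    # targets spread to the periphery of the fan
    radial_exp: dict | float = field(
        default_factory=lambda: {1: 0.6, 2: 0.6, 3: 0.3, 4: 0.2}
    )
    oml_band: tuple = (0.85, 1.0)        # normalized OML depth band for targets
    jitter_amplitudes: tuple = (1.6, 6.0)
    jitter_length_constants: tuple = (10.0, 50.0)
    taper_dmax_mean: float = 2.2
    taper_dmax_sd: float = 0.35
    taper_dtip: float = 0.65
    taper_lambda: float = 4.0

    @property
    def stem_lambda(self) -> float:
        return poisson_lambda_for_mean(self.stem_mean)


def generate_cell(
    soma: np.ndarray,
    subgroup: int,
    volume,
    params: GrowthParams,
    cell_id: int = 0,
    master_seed: int = 0,
    oml_tree=None,
    resample_spacing: float = 5.0,
) -> MorphTree:
    """Run the full single-cell pipeline.

    cone orientation -> laminar quota -> target sampling -> optimal
    wiring -> 5 um resampling -> spatial jitter -> diameter taper ->
    per-node layer tags.  Deterministic given ``(master_seed,
    cell_id)``; every cell uses an independent substream so population
    results do not depend on generation order.
    """
    rng = np.random.default_rng([int(master_seed), int(cell_id)])
    radius_t = -1.0
    while radius_t <= 0:
        radius_t = rng.normal(params.radius_t_mean, params.radius_t_sd)
    radius_l = radius_t * params.radius_ratio
    cone = orient_cone(volume, soma, radius_t, radius_l, oml_tree=oml_tree)
    n_stems = int(sample_truncated_poisson(params.stem_lambda, None, rng))
    stems = init_stems(cone, n_stems, rng, params.stem_length)
    quota = draw_quota(params.quota_means, rng)
    pts, _ = sample_targets(
        volume, cone, quota, rng,
        radial_exp=params.radial_exp, oml_band=params.oml_band,
    )
    targets = np.concatenate([stems, pts], axis=0)
    tree = grow_tree(soma, targets, params.bf, n_lock_stems=n_stems)
    tree = resample_tree(tree, resample_spacing)
    tree = apply_jitter(
        tree,
        params.jitter_amplitudes,
        params.jitter_length_constants,
        seed=rng.integers(2 ** 31),
    )
    if hasattr(volume, "confine_points"):
        # the fissure and hilar border physically bound the dendrites
        tree.coords = volume.confine_points(tree.coords)
    d_max = max(1.0, rng.normal(params.taper_dmax_mean, params.taper_dmax_sd))
    tree = apply_taper(tree, d_max, params.taper_dtip, params.taper_lambda)
    tree.layer = volume.classify_points(tree.coords).astype(np.int8)
    tree.cell_id = int(cell_id)
    tree.subgroup = int(subgroup)
    return tree
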