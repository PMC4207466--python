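"""End-to-end generation pipeline: volume -> somata -> trees -> reports.

A run is a pure function of a :class:`~dgforest.config.RunConfig`: the
master seed spawns named substreams for packing, per-cell generation
and analysis, so any stage (and any single cell) is independently
reproducible and results do not depend on generation order.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from .config import RunConfig
from .geometry import DGVolume, estimate_volume, ml_width
from .geometry import ML_LAYERS, LayerLabel
from .growth import generate_cell
from .morphometrics import population_summary
from .packing import assign_subgroups, pack_somata
from .swcio import write_swc

log = logging.getLogger("dgforest")

__all__ = ["run_pipeline", "build_volume", "select_somata", "generate_population"]


def build_volume(config: RunConfig) -> DGVolume:
    vol = DGVolume(config.surface)
    vol.set_oml_cloud_size(config.oml_cloud_size, seed=config.master_seed + 12345)
    return vol


def select_somata(config: RunConfig, vol: DGVolume):
    """Pack the GCL and pick the cells to generate.

    Returns the full annotated soma set and the indices of the somata
    selected for growth (all, a seeded random subset of ``n_cells``,
    or a septotemporal region restriction).
    """
    somata = assign_subgroups(pack_somata(vol, seed=config.master_seed), vol)
    idx = np.arange(len(somata))
    if config.region_u is not None:
        lo, hi = config.region_u
        idx = idx[(somata.u[idx] >= lo) & (somata.u[idx] <= hi)]
    if config.n_cells is not None and config.n_cells < len(idx):
        rng = np.random.default_rng([config.master_seed, 7])
        idx = rng.choice(idx, size=config.n_cells, replace=False)
        idx.sort()
    return somata, idx


def generate_population(config: RunConfig, vol: DGVolume, somata, indices):
    """Generate trees for the selected somata (generator)."""
    oml = vol.oml_tree(config.oml_cloud_size)
    for i in indices:
        sg = int(somata.subgroup[i])
        yield generate_cell(
            somata.centers[i], sg, vol, config.subgroups[sg],
            cell_id=int(i), master_seed=config.master_seed,
            oml_tree=oml, resample_spacing=config.resample_spacing,
        )


def run_pipeline(config: RunConfig, out_dir, write_trees: bool = True) -> dict:
    """Run all stages and write artifacts under ``out_dir``.

    Artifacts: ``volume.json`` (calibration check), ``somata.tsv``
    (x, y, z, subgroup, depth), ``swc/cell_<id>.swc`` per generated
    cell and ``report.json`` with the population summary.  Returns the
    report dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"master_seed": config.master_seed}

    t0 = time.time()
    vol = build_volume(config)
    gcl_vol, _ = estimate_volume(vol, LayerLabel.GCL, n_samples=1_000_000,
                                 seed=config.master_seed + 1)
    ml_vol, _ = estimate_volume(vol, ML_LAYERS, n_samples=1_000_000,
                                seed=config.master_seed + 2)
    w_mean, w_sd = ml_width(vol, n_boundary=min(config.oml_cloud_size, 500_000),
                            n_query=5_000, seed=config.master_seed + 3)
    report["volume"] = {
        "gcl_mm3": gcl_vol, "ml_mm3": ml_vol,
        "ml_width_um": w_mean, "ml_width_sd_um": w_sd,
    }
    log.info("volume stage: %.1fs (GCL %.2f mm3, ML %.2f mm3, width %.0f um)",
             time.time() - t0, gcl_vol, ml_vol, w_mean)

    t0 = time.time()
    somata, idx = select_somata(config, vol)
    report["somata"] = {"n_packed": len(somata), "n_selected": int(len(idx))}
    np.savetxt(
        out / "somata.tsv",
        somata.subset(idx).to_table(),
        fmt="%.3f", delimiter="\t",
        header="x\ty\tz\tsubgroup\tdepth", comments="",
    )
    log.info("packing stage: %.1fs (%d somata, %d selected)",
             time.time() - t0, len(somata), len(idx))

    t0 = time.time()
    swc_dir = out / "swc"
    if write_trees:
        swc_dir.mkdir(exist_ok=True)
    trees = []
    for tree in generate_population(config, vol, somata, idx):
        trees.append(tree)
        if write_trees:
            write_swc(tree, swc_dir / f"cell_{tree.cell_id:07d}.swc")
    dt = time.time() - t0
    report["generation"] = {
        "n_cells": len(trees),
        "seconds_per_cell": dt / max(len(trees), 1),
    }
    log.info("growth stage: %.1fs (%.3f s/cell)", dt, dt / max(len(trees), 1))

    t0 = time.time()
    summary = population_summary(trees, vol)
    report["population"] = {
        m: {"mean": float(summary.overall.loc[m, "mean"]),
            "sd": float(summary.overall.loc[m, "sd"])}
        for m in summary.overall.index
    }
    report["ttests"] = {
        k: {"t": (None if np.isnan(v["t"]) else float(v["t"])),
            "p": (None if np.isnan(v["p"]) else float(v["p"]))}
        for k, v in summary.ttests.to_dict("index").items()
    }
    summary.per_cell.to_csv(out / "per_cell.csv", index=False)
    log.info("analysis stage: %.1fs", time.time() - t0)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
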