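"""Run configuration and the calibrated per-subgroup parameter table.

A :class:`RunConfig` fully determines a run: the surface coefficients,
the per-subgroup growth parameters and one master seed.  Configs
round-trip through YAML so any run is reproducible from the config
file alone.

The subgroup table below is the calibrated operating point produced by
``scripts/calibrate_growth.py``: balancing factors follow the printed
per-subgroup values (supra-deep 0.9, supra-superficial 1.35,
infrapyramidal 1.22), stem-count means follow the printed subgroup
stem statistics, and cone radii / laminar quotas are fitted so the
generated population reproduces the reference morphometric tables.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from .geometry import DGSurfaceParams
from .growth import GrowthParams
from .packing import Subgroup

__all__ = ["RunConfig", "default_subgroup_table", "load_config", "save_config"]


def default_subgroup_table() -> dict[int, GrowthParams]:
    """Calibrated growth parameters for the four anatomical subgroups."""
    common = dict(
        jitter_amplitudes=(3.5, 15.0),
        jitter_length_constants=(10.0, 50.0),
        taper_dmax_mean=2.2,
        taper_dmax_sd=0.35,
        taper_dtip=0.65,
        taper_lambda=4.0,
        stem_length=10.0,
    )
    return {
        int(Subgroup.SUPRA_SUPERFICIAL): GrowthParams(
            bf=1.35, stem_mean=2.4,
            quota_means={1: 1.3, 2: 23.5, 3: 7.0, 4: 17.0},
            radius_t_mean=327.0, radius_t_sd=52.3, radius_ratio=0.59,
            radial_exp={1: 1.5, 2: 1.5, 3: 0.3, 4: 0.2}, **common,
        ),
        int(Subgroup.SUPRA_DEEP): GrowthParams(
            bf=0.9, stem_mean=1.5,
            quota_means={1: 1.4, 2: 23.0, 3: 6.5, 4: 17.5},
            radius_t_mean=257.0, radius_t_sd=41.1, radius_ratio=0.62,
            radial_exp={1: 2.0, 2: 2.0, 3: 0.3, 4: 0.2}, **common,
        ),
        int(Subgroup.INFRA_SUPERFICIAL): GrowthParams(
            bf=1.22, stem_mean=1.9,
            quota_means={1: 1.3, 2: 20.5, 3: 6.5, 4: 15.5},
            radius_t_mean=262.0, radius_t_sd=41.9, radius_ratio=0.54,
            radial_exp={1: 1.5, 2: 1.5, 3: 0.3, 4: 0.2}, **common,
        ),
        int(Subgroup.INFRA_DEEP): GrowthParams(
            bf=1.22, stem_mean=1.5,
            quota_means={1: 1.3, 2: 19.5, 3: 6.0, 4: 16.0},
            radius_t_mean=214.0, radius_t_sd=34.2, radius_ratio=0.56,
            radial_exp={1: 2.0, 2: 2.0, 3: 0.3, 4: 0.2}, **common,
        ),
    }


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    master_seed: int = 0
    surface: DGSurfaceParams = field(default_factory=DGSurfaceParams)
    subgroups: dict = field(default_factory=default_subgroup_table)
    n_cells: int | None = None        # None = all packed somata
    oml_cloud_size: int = 2_000_000
    resample_spacing: float = 5.0
    region_u: tuple | None = None     # optional (u_lo, u_hi) restriction

    def to_dict(self) -> dict:
        d = {
            "master_seed": self.master_seed,
            "surface": self.surface.to_dict(),
            "subgroups": {
                str(k): {
                    **{kk: vv for kk, vv in asdict(v).items() if kk != "quota_means"},
                    "quota_means": {str(lk): lv for lk, lv in v.quota_means.items()},
                }
                for k, v in self.subgroups.items()
            },
            "n_cells": self.n_cells,
            "oml_cloud_size": self.oml_cloud_size,
            "resample_spacing": self.resample_spacing,
            "region_u": list(self.region_u) if self.region_u else None,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sub = {}
        for k, v in d.get("subgroups", {}).items():
            v = dict(v)
            v["quota_means"] = {int(lk): float(lv) for lk, lv in v["quota_means"].items()}
            for key in ("jitter_amplitudes", "jitter_length_constants"):
                if key in v:
                    v[key] = tuple(v[key])
            sub[int(k)] = GrowthParams(**v)
        return cls(
            master_seed=int(d.get("master_seed", 0)),
            surface=DGSurfaceParams.from_dict(d["surface"])
            if "surface" in d else DGSurfaceParams(),
            subgroups=sub or default_subgroup_table(),
            n_cells=d.get("n_cells"),
            oml_cloud_size=int(d.get("oml_cloud_size", 2_000_000)),
            resample_spacing=float(d.get("resample_spacing", 5.0)),
            region_u=tuple(d["region_u"]) if d.get("region_u") else None,
        )


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))
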