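"""Calibrate the parametric DG surface coefficients.

Fits the free micrometre-valued coefficients of
:class:`dgforest.DGSurfaceParams` to the three anatomical reference
values: GCL volume 3.78 mm^3, ML volume 9.02 mm^3 and mean ML width
247 um.  The fixed-point loop exploits the near-triangular structure of
the problem: the ML shell spacing controls the width, a global in-plane
scale controls the ML volume at fixed width, and the GCL shell spacing
controls the GCL volume.

Run from the repository root:

    python scripts/calibrate_geometry.py [--fast]

and copy the printed coefficients into the DGSurfaceParams defaults.
"""

import argparse
import numpy as np

from dgforest import DGSurfaceParams, DGVolume, LayerLabel, estimate_volume, ml_width
from dgforest.geometry import ML_LAYERS

TARGET_GCL = 3.78  # mm^3
TARGET_ML = 9.02   # mm^3
TARGET_W = 247.0   # um


def measure(params, n_mc, n_bnd, n_q, seed=0):
    vol = DGVolume(params)
    g, _ = estimate_volume(vol, LayerLabel.GCL, n_samples=n_mc, seed=seed)
    m, _ = estimate_volume(vol, ML_LAYERS, n_samples=n_mc, seed=seed + 1)
    w, wsd = ml_width(vol, n_boundary=n_bnd, n_query=n_q, seed=seed + 2)
    return g, m, w, wsd


def calibrate(params, rounds=5, n_mc=2_000_000, n_bnd=300_000, n_q=4000):
    for it in range(rounds):
        g, m, w, wsd = measure(params, n_mc, n_bnd, n_q, seed=10 * it)
        print(
            f"round {it}: GCL {g:.3f}  ML {m:.3f}  width {w:.1f}+-{wsd:.1f}  "
            f"(w_gcl {params.w_gcl:.2f} w_ml {params.w_ml:.2f} "
            f"rx {params.rx:.0f} a {params.xsec_a:.1f})"
        )
        # width -> ML shell spacing
        params.w_ml *= TARGET_W / w
        # ML volume at fixed width -> in-plane scale
        k = np.sqrt(TARGET_ML / (m * (TARGET_W / w)))
        params.rx *= k
        params.ry *= k
        params.defl_z *= k
        params.xsec_a *= k
        # GCL volume -> GCL shell spacing
        params.w_gcl *= TARGET_GCL / (g * k ** 2)
    return params


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--fast", action="store_true", help="fewer samples (exploration)")
    args = ap.parse_args()
    scale = 0.2 if args.fast else 1.0
    params = DGSurfaceParams()
    params = calibrate(
        params,
        rounds=5,
        n_mc=int(2e6 * scale) if args.fast else 2_000_000,
        n_bnd=int(3e5 * scale) if args.fast else 300_000,
        n_q=2000 if args.fast else 5000,
    )
    g, m, w, wsd = measure(params, 4_000_000, 500_000, 8000, seed=999)
    print(f"final: GCL {g:.3f}  ML {m:.3f}  width {w:.1f}+-{wsd:.1f}")
    print("calibrated coefficients:")
    for k in ("rx", "ry", "defl_z", "xsec_a", "w_gcl", "w_ml"):
        print(f"    {k}: float = {getattr(params, k):.4f}")


if __name__ == "__main__":
    main()
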