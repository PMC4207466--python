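"""Build the parametric dentate gyrus volume and check its calibration.

The layered shell model is calibrated so the granule cell layer (GCL)
holds 3.78 mm^3, the molecular layer (ML) 9.02 mm^3, and the ML is on
average 247 um wide.
"""

from dgforest import DGVolume, LayerLabel, estimate_volume, ml_width
from dgforest.geometry import ML_LAYERS

vol = DGVolume()

gcl, gcl_se = estimate_volume(vol, LayerLabel.GCL, n_samples=1_000_000, seed=0)
ml, ml_se = estimate_volume(vol, ML_LAYERS, n_samples=1_000_000, seed=1)
width, width_sd = ml_width(vol, n_boundary=300_000, n_query=5_000, seed=2)

print(f"GCL volume : {gcl:.3f} +- {gcl_se:.3f} mm^3   (reference 3.78)")
print(f"ML volume  : {ml:.3f} +- {ml_se:.3f} mm^3   (reference 9.02)")
print(f"ML width   : {width:.1f} +- {width_sd:.1f} um    (reference 247)")

for layer in ML_LAYERS:
    v, _ = estimate_volume(vol, layer, n_samples=500_000, seed=int(layer))
    print(f"  {layer.name}: {v:.2f} mm^3")

# The three sublayer volumes grow from the IML outward because each
# shell sits farther out on the convex side of the granule cell layer.
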