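"""Pack the ~1.2 million granule-cell somata into the GCL.

Somata are 12.54 um spheres on a close-packed lattice with a 3.5 um
gap; spheres protruding from the GCL are discarded.  Each soma is
labelled by blade (supra/infrapyramidal) and depth (deep/superficial).
"""

from dgforest import DGVolume
from dgforest.packing import Subgroup, assign_subgroups, pack_somata

vol = DGVolume()
somata = assign_subgroups(pack_somata(vol, seed=0), vol)

print(f"packed somata: {len(somata):,}  (reference population 1,185,178)")
for sg, frac in somata.subgroup_fractions().items():
    print(f"  {Subgroup(sg).name:18s} {100 * frac:5.1f} %")
# The suprapyramidal blade holds the larger share of cells, and the
# deep/superficial split is close to even within each blade.
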