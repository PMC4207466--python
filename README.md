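# dgforest

Context-driven synthesis of the complete rat dentate gyrus granule-cell
dendritic forest.

Granule cells (GCs) are the most numerous neurons of the hippocampus:
about 1.2 million of them pack the thin granule cell layer (GCL) of the
rat dentate gyrus (DG), and each extends a cone-shaped dendritic tree
across the overlying molecular layer (ML, subdivided into inner, middle
and outer sublayers — IML/MML/OML). `dgforest` turns that macroscopic
anatomy into single-cell morphology: a parametric layered volume drives
soma placement, dendritic-field orientation and tree growth, so that
whole-population statistics (laminar distributions, branch counts,
spatial occupancy) emerge from the tissue context rather than being
copied from individual reconstructions. It is intended for computational
neuroanatomists and network modellers who need full-scale, anatomically
embedded morphology populations, or who want to study how macroscopic
structure shapes dendritic statistics.

## The model

* **Volume** — the GCL and ML boundaries are offset shells of a cut
  elliptical torus: a "C"-shaped elliptical cross-section (parameter
  *v* ∈ (−0.23π, 1.425π)) swept along a curved septotemporal axis
  (parameter *u*), with layer coordinate *L* ∈ {−1.95, 0, 1, 2, 3}
  indexing the inner GCL, outer GCL, IML, MML and OML shells. The free
  coefficients are calibrated to the anatomical reference values: GCL
  volume 3.78 mm³, ML volume 9.02 mm³, mean ML width 247 µm.
* **Somata** — 12.54 µm spheres on a close-packed lattice with 3.5 µm
  gaps, keeping the ~1.19 million that fit inside the GCL, each labelled
  supra/infrapyramidal (blade) × deep/superficial (GCL depth).
* **Growth** — each cell wires target points inside an elliptical cone
  (apex at the soma, axis toward the nearest OML boundary point) by
  greedy optimal wiring: the unconnected target *t* minimizing

      cost(t) = min over tree nodes n of ‖t−n‖ + bf · (plen(n) + ‖t−n‖)

  is attached next, where plen(n) is the path length from the soma and
  *bf* is the balancing factor weighing conduction-path cost against
  total cable (bf = 0 is exactly a minimum spanning tree). Per-subgroup
  balancing factors (supra-deep 0.9, supra-superficial 1.35,
  infrapyramidal 1.22), truncated-Poisson stem counts (1–4) and
  calibrated laminar target quotas reproduce the published subgroup
  morphometrics. Trees are resampled at 5 µm, roughened with smooth
  spatial noise (length constants 10 and 50 µm) and given a quadratic
  diameter taper.
* **Analysis** — Sholl profiles, contraction, branch statistics,
  partition asymmetry, laminar distributions, transverse/longitudinal
  spreads, population tables with Student's t-tests, 25 µm voxel
  occupancy grids (unique cells, cable density, volumetric occupancy),
  wiring-based axon complexity and GCL surface maps. Morphologies are
  read and written as standard SWC.

## Worked example

```python
from dgforest import DGVolume
from dgforest.config import default_subgroup_table
from dgforest.growth import generate_cell
from dgforest.morphometrics import branch_stats
from dgforest.packing import assign_subgroups, pack_somata

vol = DGVolume()                       # calibrated layered DG volume
somata = assign_subgroups(pack_somata(vol, seed=0), vol)
print(len(somata))                     # 1195789 packed somata

params = default_subgroup_table()[int(somata.subgroup[50_000])]
tree = generate_cell(somata.centers[50_000], int(somata.subgroup[50_000]),
                     vol, params, cell_id=0, master_seed=42)
print(branch_stats(tree)["n_branches"])  # e.g. 36 dendritic branches
print(round(tree.total_length))          # e.g. 3626 um of dendrite
```

Running `python examples/01_build_volume.py` prints the calibration
check:

```
GCL volume : 3.781 +- 0.019 mm^3   (reference 3.78)
ML volume  : 9.052 +- 0.028 mm^3   (reference 9.02)
ML width   : 247.1 +- 13.6 um    (reference 247)
```

i.e. the Monte-Carlo layer volumes and the nearest-neighbour ML width
of the calibrated surface match the anatomical reference values. The
other scripts in `examples/` walk through soma packing, single-cell
growth, population morphometrics and voxel occupancy, each printing the
quantities it computes next to the corresponding reference value.

A thin command-line interface wraps the same library calls:

```bash
dgforest build-volume --check
dgforest grow --cells 50 --seed 1 --out run/
dgforest analyze --in run/swc --report run/report.json
dgforest occupancy --in run/swc --out run/grid.tsv
```

## Scope

The package covers mature granule-cell dendrites. Newborn GCs, basal
dendrites, axon generation, dendro-dendritic avoidance, spines and
export to electrophysiological simulators are out of scope; see
`docs/methods.md` for the model's assumptions and limitations.
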