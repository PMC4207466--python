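"""Shared fixtures: the calibrated volume, packed somata and a
reference generated population.

Heavy objects are session-scoped; all randomness is fixed (the
package-default master seed 0 for the reference population)."""

import numpy as np
import pytest

from dgforest import DGVolume
from dgforest.config import default_subgroup_table
from dgforest.growth import generate_cell
from dgforest.packing import assign_subgroups, pack_somata

OML_CLOUD_TEST = 200_000  # boundary cloud size used in tests (speed)


@pytest.fixture(scope="session")
def volume():
    vol = DGVolume()
    vol.set_oml_cloud_size(OML_CLOUD_TEST)
    return vol


@pytest.fixture(scope="session")
def somata(volume):
    """Full-GCL packed and subgroup-annotated soma set."""
    return assign_subgroups(pack_somata(volume, seed=0), volume)


@pytest.fixture(scope="session")
def subgroup_table():
    return default_subgroup_table()


@pytest.fixture(scope="session")
def population200(volume, somata, subgroup_table):
    """Reference mixed population: 200 cells, master seed 0."""
    rng = np.random.default_rng(0)
    idx = rng.choice(len(somata), 200, replace=False)
    oml = volume.oml_tree(OML_CLOUD_TEST)
    trees = []
    for k, i in enumerate(idx):
        sg = int(somata.subgroup[i])
        trees.append(
            generate_cell(
                somata.centers[i], sg, volume, subgroup_table[sg],
                cell_id=k, master_seed=0, oml_tree=oml,
            )
        )
    return trees


@pytest.fixture(scope="session")
def slab_population(volume, somata, subgroup_table):
    """Cells from a thin central septotemporal window, for overlap
    analyses (dendrites of neighbouring cells genuinely intersect)."""
    p = volume.params
    lo, hi = 0.49 * np.pi, 0.51 * np.pi
    pool = np.nonzero((somata.u >= lo) & (somata.u <= hi))[0]
    rng = np.random.default_rng(1)
    idx = rng.choice(pool, 150, replace=False)
    oml = volume.oml_tree(OML_CLOUD_TEST)
    trees = []
    for k, i in enumerate(idx):
        sg = int(somata.subgroup[i])
        trees.append(
            generate_cell(
                somata.centers[i], sg, volume, subgroup_table[sg],
                cell_id=k, master_seed=1, oml_tree=oml,
            )
        )
    return trees
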