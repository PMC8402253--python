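"""Shared fixtures.

The expensive Monte Carlo runs are session-scoped and shared across test
modules; their photon counts are the package's desk-scale study conditions
(noise small against the tolerances being checked, runtimes in minutes).
"""

import numpy as np
import pytest

from srsoxi import (
    DetectorAnnuli,
    ExtinctionTable,
    RunConfig,
    make_preset_model,
    run_simulation,
)
from srsoxi.phantom import PhantomSpec, phantom_base_run
from srsoxi.sensitivity import fine_annuli_for

#: Photon counts of the shared runs, sized so far-ring Monte Carlo error
#: stays small against the tolerances checked (smaller map runs visibly
#: bias the plateau-peak and regression estimates).
N_HOMOG = 2_500_000
N_MAP = 5_000_000


@pytest.fixture(scope="session")
def eps_table():
    return ExtinctionTable.from_csv()


@pytest.fixture(scope="session")
def homog_tallies():
    """Homogeneous skin-like medium, 0.2 mm slabs, fine annuli to 31 mm."""
    model = make_preset_model("homogeneous_skin", 770)
    cfg = RunConfig(n_photons=N_HOMOG, seed=20210819, voxel_size=0.2)
    return run_simulation(model, cfg, DetectorAnnuli.uniform(0.5, 31.0))


@pytest.fixture(scope="session")
def skin_map_tallies():
    """Skin/fat/muscle layered model, 0.5 mm slabs (depth-map protocol)."""
    model = make_preset_model("skin_subcutaneous", 770)
    cfg = RunConfig(n_photons=N_MAP, seed=20210820, voxel_size=0.5)
    return model, run_simulation(model, cfg, fine_annuli_for(30.0))


@pytest.fixture(scope="session")
def gastric_map_tallies():
    """Gastric 7 mm slab, 0.5 mm slabs (depth-map protocol)."""
    model = make_preset_model("gastric", 770)
    cfg = RunConfig(n_photons=N_MAP, seed=20210821, voxel_size=0.5)
    return model, run_simulation(model, cfg, fine_annuli_for(30.0))


@pytest.fixture(scope="session")
def phantom_base():
    """Recorded blood-free phantom background run for reweighted sweeps."""
    spec = PhantomSpec()
    cfg = RunConfig(n_photons=1_000_000, seed=20210822, voxel_size=0.5)
    return spec, phantom_base_run(spec, cfg, rec_depth=16.0)
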