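from pathlib import Path

import numpy as np
import pytest

from pmfkit.landscape import (LangevinSettings, ModelPotential,
                              build_cycle_potential)

DATA_DIR = Path(__file__).resolve().parent.parent / "data" / "pdb"


@pytest.fixture(scope="session")
def cycle_potential():
    return build_cycle_potential("cycle")


@pytest.fixture(scope="session")
def apo_potential():
    return build_cycle_potential("apo-flat")


@pytest.fixture(scope="session")
def ion_bound_potential():
    return build_cycle_potential("ion-bound")


@pytest.fixture(scope="session")
def three_well_potential():
    return build_cycle_potential("three-well")


@pytest.fixture
def flat_potential():
    # constant surface on a generous rectangle
    return ModelPotential(np.array([[-8.0, -8.0], [8.0, 8.0]]))


@pytest.fixture
def fast_settings():
    return LangevinSettings(n_steps=2000, diffusion_coefficient=0.01, seed=11)


def pdb_path(accession: str) -> Path:
    return DATA_DIR / f"{accession.upper()}.pdb"
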