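"""Shared fixtures: phantoms and meshes are expensive, so the canonical ones
are built once per session."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from ossimetry import phantoms as ph
from ossimetry.config import RunConfig
from ossimetry.parameterization import measure_chain
from ossimetry.volume_io import extract_label_mask
from ossimetry import surface_reconstruction as sr


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def chain_phantom():
    """Default chain phantom at the canonical study conditions (0.1 mm)."""
    vol, truth = ph.generate_chain_phantom()
    return vol, truth


@pytest.fixture(scope="session")
def chain_measurement(chain_phantom, default_config):
    vol, truth = chain_phantom
    meas, qc = measure_chain(vol, default_config.label_map, default_config)
    return meas, qc, truth


@pytest.fixture(scope="session")
def malleus_phantom():
    return ph.generate_malleus_phantom()


@pytest.fixture(scope="session")
def incus_phantom():
    return ph.generate_incus_phantom()


@pytest.fixture(scope="session")
def stapes_phantom():
    return ph.generate_stapes_phantom()


def _mesh_of(vol, label=1):
    return sr.mask_to_mesh(extract_label_mask(vol, label))


@pytest.fixture(scope="session")
def malleus_mesh(malleus_phantom):
    return _mesh_of(malleus_phantom[0])


@pytest.fixture(scope="session")
def incus_mesh(incus_phantom):
    return _mesh_of(incus_phantom[0])


@pytest.fixture(scope="session")
def stapes_mesh(stapes_phantom):
    return _mesh_of(stapes_phantom[0])


@pytest.fixture(scope="session")
def icosphere():
    return trimesh.creation.icosphere(subdivisions=4, radius=1.0)


@pytest.fixture(scope="session")
def capsule_mesh():
    return trimesh.creation.capsule(height=2.0, radius=0.5)
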