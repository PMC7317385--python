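"""Shared fixtures: small geometries and planted scenes used across modules."""

import numpy as np
import pytest

import arboretum as ab
from arboretum.synthetic_fixtures import SlaterAtom, SlaterSceneSpec, make_slater_scene


@pytest.fixture(scope="session")
def water() -> ab.Geometry:
    return ab.Geometry(
        ["O", "H", "H"],
        np.array([8, 1, 1]),
        np.array([[0.0, 0.0, 0.0], [0.0, 1.43, 1.11], [0.0, -1.43, 1.11]]),
        total_charge=0,
        label="water",
    )


@pytest.fixture(scope="session")
def transfer_scene():
    """Two N-like Slater atoms 12 Bohr apart with 0.3 e transferred."""
    return make_slater_scene(
        SlaterSceneSpec(
            atoms=[
                SlaterAtom("N", np.zeros(3), 7.3, 1.92),
                SlaterAtom("N", np.array([0.0, 0.0, 12.0]), 6.7, 1.92),
            ],
            spacing=0.25,
        )
    )


@pytest.fixture(scope="session")
def transfer_grid(transfer_scene):
    return ab.build_becke_grid(transfer_scene.geometry)


@pytest.fixture(scope="session")
def symmetric_scene():
    """Homonuclear diatomic of identical Slater atoms (neutral)."""
    return make_slater_scene(
        SlaterSceneSpec(
            atoms=[
                SlaterAtom("N", np.zeros(3), 7.0, 1.92),
                SlaterAtom("N", np.array([0.0, 0.0, 2.1]), 7.0, 1.92),
            ],
            # 0.1 keeps both nuclei on lattice planes, the bond midplane
            # between voxel centers (2.1/0.1 = 21, odd), and the cusp
            # Riemann defect below ~2e-3 e
            spacing=0.1,
        )
    )


@pytest.fixture(scope="session")
def symmetric_grid(symmetric_scene):
    return ab.build_becke_grid(symmetric_scene.geometry)
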