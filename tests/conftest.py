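"""Shared fixtures: coarse meshes, solvers and cached expensive pipelines."""

from __future__ import annotations

import numpy as np
import pytest

from oxisense.detector import run_detection_experiment
from oxisense.electrode_opt import build_surrogate_dataset
from oxisense.fixtures import make_fixture, select_reference_pattern
from oxisense.forward import ForwardSolver
from oxisense.geometry import (
    ConductivityField,
    OxygenatorGeometry,
    build_mesh,
    edge_array,
    symmetric_array,
)
from oxisense.thrombus_sampler import make_training_sets


@pytest.fixture(scope="session")
def geom() -> OxygenatorGeometry:
    return OxygenatorGeometry()


@pytest.fixture(scope="session")
def tiny_mesh(geom):
    """~2e3-element mesh (1 cm cells); odd in-plane cell counts."""
    return build_mesh(geom, 0.01)


@pytest.fixture(scope="session")
def even_mesh(geom):
    """Mesh with even in-plane cell counts: exactly 90-degree-rotation
    symmetric, used by the symmetry tests."""
    return build_mesh(geom, 0.009)


@pytest.fixture(scope="session")
def fd_mesh(geom):
    """<= 2,000-element mesh for finite-difference Jacobian verification."""
    mesh = build_mesh(geom, 0.0115)
    assert mesh.n_elements <= 2000
    return mesh


@pytest.fixture(scope="session")
def tiny_hom_solution(tiny_mesh, geom):
    solver = ForwardSolver(tiny_mesh, edge_array(geom), geom)
    return solver, solver.factorize(ConductivityField.homogeneous(tiny_mesh))


@pytest.fixture(scope="session")
def tiny_bundle():
    """Tiny end-to-end fixture: mesh, 8-measurement frame, 20-sample dataset."""
    return make_fixture("tiny", seed=1)


@pytest.fixture(scope="session")
def surrogate_study(tiny_mesh, geom):
    """50 random arrays scored with the full 208-measurement frame on the
    coarse mesh (shared by the surrogate and correlation tests)."""
    pattern = select_reference_pattern(
        geom, {"volume": 144, "l1": 32, "l2": 32}
    )
    scenarios = make_training_sets(diameter=0.016, seed=7)
    return build_surrogate_dataset(
        tiny_mesh,
        pattern,
        scenarios,
        n_random=50,
        geom=geom,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment():
    """The desk-scale detection replication (5 mm mesh, 800 + 800 samples)."""
    return run_detection_experiment(seed=1)
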