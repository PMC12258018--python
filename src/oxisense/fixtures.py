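"""Deterministic coarse-scale fixture bundles for fast end-to-end runs.

``tiny``  -- 1 cm mesh (~2e3 elements), an 8-measurement frame and a
             20-sample detection dataset: the whole pipeline in seconds.
``small`` -- 5 mm mesh (~1.6e4 elements), the full 208-measurement frame and
             a 1,600-sample dataset: the desk-scale replication surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detector import (
    DetectionDataset,
    DetectionSimulator,
    NoiseSpec,
    OPTIMIZED_ARRAY_RADIUS,
    build_detection_dataset,
)
from .forward import ForwardSolver, IMPattern
from .geometry import (
    ConductivityField,
    ElectrodeArray,
    Mesh,
    OxygenatorGeometry,
    build_mesh,
    edge_array,
    symmetric_array,
)
from .patterns import enumerate_candidates, select_pattern
from .thrombus_sampler import make_target_grid

SCALES = {
    "tiny": dict(max_h=0.01, counts={"volume": 4, "l1": 2, "l2": 2},
                 n_positive=10, n_negative=10, grid_spacing=0.012,
                 target_diameter=0.016),
    "small": dict(max_h=0.005, counts={"volume": 144, "l1": 32, "l2": 32},
                  n_positive=800, n_negative=800, grid_spacing=0.0042,
                  target_diameter=0.01),
}


@dataclass
class FixtureBundle:
    scale: str
    geom: OxygenatorGeometry
    mesh: Mesh
    array: ElectrodeArray
    pattern: IMPattern
    dataset: DetectionDataset
    seed: int


def select_reference_pattern(
    geom: OxygenatorGeometry,
    counts: dict[str, int],
    pattern_max_h: float = 0.009,
) -> IMPattern:
    """Frame selected on a coarse mesh with the edge reference array."""
    mesh = build_mesh(geom, pattern_max_h)
    solver = ForwardSolver(mesh, edge_array(geom), geom)
    sol = solver.factorize(ConductivityField.homogeneous(mesh))
    cands = enumerate_candidates()
    cand_pattern = IMPattern(list(cands.measurements))
    J_all = sol.jacobian(cand_pattern)
    v_ref = sol.measure(cand_pattern).v
    pattern, _ = select_pattern(J_all, cands, counts=counts, v_ref=v_ref)
    return pattern


def make_fixture(scale: str = "tiny", seed: int = 0,
                 noise: NoiseSpec | None = None) -> FixtureBundle:
    """Build a deterministic fixture bundle at the requested scale."""
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; choose from {sorted(SCALES)}")
    cfg = SCALES[scale]
    geom = OxygenatorGeometry()
    pattern = select_reference_pattern(geom, cfg["counts"])
    mesh = build_mesh(geom, cfg["max_h"])
    array = symmetric_array(OPTIMIZED_ARRAY_RADIUS, geom)
    simulator = DetectionSimulator(
        ForwardSolver(mesh, array, geom), pattern, noise
    )
    grid = make_target_grid(geom, diameter=cfg["target_diameter"],
                            spacing=cfg["grid_spacing"])
    dataset = build_detection_dataset(
        simulator, grid, cfg["n_positive"], cfg["n_negative"], seed=seed
    )
    return FixtureBundle(scale=scale, geom=geom, mesh=mesh, array=array,
                         pattern=pattern, dataset=dataset, seed=seed)
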