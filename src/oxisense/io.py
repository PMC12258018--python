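"""Serialization: meshes (VTK / Gmsh MSH), patterns, frames, scenarios, reports.

Meshes are written in legacy-ASCII VTK unstructured-grid format and in Gmsh
MSH 2.2 ASCII, with region labels carried as element data; tabular artifacts
(patterns, frames, scenarios, selection reports) are plain CSV; evaluation
reports are JSON.  Every writer has a matching reader where round-tripping
is meaningful.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .detector import EvalReport
from .forward import IMPattern, Measurement, MeasurementFrame
from .geometry import Mesh
from .thrombus_sampler import Target, ThrombusScenario

VTK_TETRA = 10
MSH_TETRA = 4


# -- meshes -----------------------------------------------------------------

def write_vtk(mesh: Mesh, path: str | Path,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Legacy-ASCII VTK unstructured grid with region (+ extra) cell data."""
    cell_data = {"region": mesh.region, **(cell_data or {})}
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\noxygenator mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        fh.write(f"CELLS {mesh.n_elements} {mesh.n_elements * 5}\n")
        for e in mesh.elements:
            fh.write(f"4 {e[0]} {e[1]} {e[2]} {e[3]}\n")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        fh.write("\n".join([str(VTK_TETRA)] * mesh.n_elements) + "\n")
        fh.write(f"CELL_DATA {mesh.n_elements}\n")
        for name, data in cell_data.items():
            kind = "int" if np.issubdtype(np.asarray(data).dtype, np.integer) \
                else "double"
            fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(f"{v:.12g}" if kind == "double" else str(int(v))
                               for v in data) + "\n")


def write_msh(mesh: Mesh, path: str | Path) -> None:
    """Gmsh MSH 2.2 ASCII; the element's physical tag is its region label."""
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{mesh.n_nodes}\n")
        for i, p in enumerate(mesh.nodes, start=1):
            fh.write(f"{i} {p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        fh.write("$EndNodes\n")
        fh.write(f"$Elements\n{mesh.n_elements}\n")
        for i, (e, r) in enumerate(zip(mesh.elements, mesh.region), start=1):
            fh.write(f"{i} {MSH_TETRA} 2 {int(r)} {int(r)} "
                     f"{e[0]+1} {e[1]+1} {e[2]+1} {e[3]+1}\n")
        fh.write("$EndElements\n")


def read_msh(path: str | Path, max_h: float = float("nan")) -> Mesh:
    """Read a tetrahedral MSH 2.2 file written by :func:`write_msh`."""
    lines = Path(path).read_text().splitlines()
    it = iter(lines)
    nodes, elements, region = [], [], []
    for line in it:
        if line.strip() == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                nodes.append([float(x) for x in parts[1:4]])
        elif line.strip() == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                if int(parts[1]) != MSH_TETRA:
                    continue
                ntags = int(parts[2])
                region.append(int(parts[3]))
                elements.append([int(x) - 1 for x in parts[3 + ntags:7 + ntags]])
    nodes_arr = np.array(nodes)
    elems_arr = np.array(elements, dtype=np.int64)
    p = nodes_arr[elems_arr]
    v6 = np.einsum("ei,ei->e",
                   np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                   p[:, 3] - p[:, 0])
    return Mesh(nodes=nodes_arr, elements=elems_arr,
                region=np.array(region, dtype=np.int8),
                volumes=np.abs(v6) / 6.0, max_h=max_h)


# -- patterns and frames ----------------------------------------------------

def write_pattern_csv(pattern: IMPattern, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"inject_a": m.inject[0], "inject_b": m.inject[1],
             "meas_c": m.measure[0], "meas_d": m.measure[1]}
            for m in pattern
        ]
    ).to_csv(path, index=False)


def read_pattern_csv(path: str | Path) -> IMPattern:
    df = pd.read_csv(path)
    return IMPattern(
        [
            Measurement(inject=(int(r.inject_a), int(r.inject_b)),
                        measure=(int(r.meas_c), int(r.meas_d)))
            for r in df.itertuples()
        ]
    )


def write_frame_csv(frame: MeasurementFrame, path: str | Path) -> None:
    data = {"v": frame.v}
    if frame.delta_vr is not None:
        data["delta_vr"] = frame.delta_vr
    pd.DataFrame(data).to_csv(path, index=False)


def read_frame_csv(path: str | Path) -> MeasurementFrame:
    df = pd.read_csv(path)
    return MeasurementFrame(
        v=df["v"].to_numpy(),
        delta_vr=df["delta_vr"].to_numpy() if "delta_vr" in df else None,
    )


# -- scenarios --------------------------------------------------------------

def write_scenarios_csv(scenarios: list[ThrombusScenario],
                        path: str | Path) -> None:
    rows = []
    for s_idx, sc in enumerate(scenarios):
        for t in sc.targets:
            rows.append(
                {"scenario": s_idx, "x": t.center[0], "y": t.center[1],
                 "z": t.center[2], "diameter": t.diameter, "sigma": t.sigma}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_scenarios_csv(path: str | Path) -> list[ThrombusScenario]:
    df = pd.read_csv(path)
    scenarios = []
    for _, group in df.groupby("scenario", sort=True):
        targets = [
            Target(center=np.array([r.x, r.y, r.z]), diameter=r.diameter,
                   sigma=r.sigma)
            for r in group.itertuples()
        ]
        scenarios.append(ThrombusScenario(targets=targets))
    return scenarios


# -- model checkpoints ------------------------------------------------------

def save_mlp(net, path: str | Path, sidecar: dict | None = None) -> None:
    """Weights as a portable .npz plus a JSON sidecar describing the model."""
    path = Path(path)
    arrays = {f"W{i}": W for i, W in enumerate(net.W)}
    arrays.update({f"b{i}": b for i, b in enumerate(net.b)})
    np.savez(path, **arrays)
    desc = {"sizes": list(net.sizes), "task": net.task, "leak": net.leak}
    desc.update(sidecar or {})
    path.with_suffix(".json").write_text(json.dumps(desc, indent=2) + "\n")


def load_mlp(path: str | Path):
    from .nn import MLP

    path = Path(path)
    desc = json.loads(path.with_suffix(".json").read_text())
    net = MLP(tuple(desc["sizes"]), task=desc["task"], leak=desc["leak"])
    with np.load(path if path.suffix else path.with_suffix(".npz")) as data:
        net.W = [data[f"W{i}"] for i in range(len(net.W))]
        net.b = [data[f"b{i}"] for i in range(len(net.b))]
    return net, desc


# -- reports and logging ----------------------------------------------------

def write_report_json(report: EvalReport, path: str | Path,
                      extra: dict | None = None) -> None:
    payload = report.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping (for log provenance)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def setup_run_logging(out_dir: str | Path, name: str = "oxisense") -> Path:
    """File + console logging with ISO timestamps; returns the log path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = datetime.now(timezone.utc).strftime("%Y%m%dT%H%M%SZ")
    log_path = out_dir / f"{name}-{stamp}.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s")
    )
    root = logging.getLogger()
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    return log_path
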