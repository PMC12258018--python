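"""Electrode-array optimization via a neural surrogate.

Random electrode arrays are scored by three figures of merit that summarise
measurement quality for a fixed 208-measurement frame:

* ``j_homogeneity``   -- median / min of the L1 row norms of the sensitivity
  matrix J (how evenly the measurements sense the volume);
* ``j_condition``     -- max / min singular value of J;
* ``dv_homogeneity``  -- median / min of |dVr| entries pooled over the
  thrombus scenario sets (how evenly target responses spread over the frame).

All three are scale-free ratios with an ideal value of 1.  A shallow
regression network learns the inverse map features -> electrode coordinates
on thousands of random arrays; querying it at the ideal feature vector
[1, 1, 1] and snapping the output to the admissible slots proposes an
optimized array.  An optional deterministic symmetrization averages the
proposal over the eight spokes of each plane (the admissible arrays are
rotationally interchangeable, so a symmetric array is the natural
representative); it is never applied silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forward import FieldSolution, ForwardSolver, IMPattern, delta_vr
from .geometry import (
    N_SPOKES,
    ConductivityField,
    ElectrodeArray,
    Mesh,
    OxygenatorGeometry,
    generate_random_array,
    insert_spherical_target,
    snap_to_slots,
)
from .nn import MLP, TrainingHistory
from .thrombus_sampler import ThrombusScenario

logger = logging.getLogger(__name__)

SURROGATE_WIDTHS = (254, 203)
IDEAL_FEATURES = (1.0, 1.0, 1.0)


@dataclass(frozen=True)
class FeatureVector:
    """The three figures of merit fed to the surrogate network."""

    j_homogeneity: float
    j_condition: float
    dv_homogeneity: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.j_homogeneity, self.j_condition, self.dv_homogeneity]
        )


def extract_features(J: np.ndarray, dvr_pool: np.ndarray) -> FeatureVector:
    """Figures of merit from a sensitivity matrix and pooled |dVr| entries."""
    row_l1 = np.abs(J).sum(axis=1)
    if row_l1.min() <= 0:
        raise ValueError("degenerate array: a sensitivity row is exactly zero")
    sv = np.linalg.svd(J, compute_uv=False)
    adv = np.abs(np.asarray(dvr_pool, dtype=float).ravel())
    if adv.min() <= 0:
        raise ValueError("degenerate array: a pooled |dVr| entry is zero")
    return FeatureVector(
        j_homogeneity=float(np.median(row_l1) / row_l1.min()),
        j_condition=float(sv.max() / sv.min()),
        dv_homogeneity=float(np.median(adv) / adv.min()),
    )


def candidate_figures(J: np.ndarray, dvr_pool: np.ndarray) -> dict[str, float]:
    """The wider screen of figures of merit used for correlation analysis."""
    row_l1 = np.abs(J).sum(axis=1)
    adv = np.abs(np.asarray(dvr_pool, dtype=float).ravel())
    sv = np.linalg.svd(J, compute_uv=False)
    tol = sv.max() * max(J.shape) * np.finfo(float).eps
    figures = {
        "mean_J": float(row_l1.mean()),
        "median_J": float(np.median(row_l1)),
        "max_J": float(row_l1.max()),
        "min_J": float(row_l1.min()),
        "rank_J": float((sv > tol).sum()),
        "cond_J": float(sv.max() / sv.min()),
        "mean_dV": float(adv.mean()),
        "median_dV": float(np.median(adv)),
        "max_dV": float(adv.max()),
        "min_dV": float(adv.min()),
    }
    figures["median_over_min_J"] = figures["median_J"] / figures["min_J"]
    figures["median_over_min_dV"] = figures["median_dV"] / figures["min_dV"]
    return figures


@dataclass
class SurrogateDataset:
    """Per-array features (n, 3) mapped to flattened coordinates (n, 48)."""

    features: np.ndarray
    coords: np.ndarray
    figures: pd.DataFrame | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.features)

    def split(self, fractions=(0.8, 0.1, 0.1), seed: int = 0):
        """Shuffled train/validation/test index triples."""
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        idx = np.random.default_rng(seed).permutation(len(self))
        n_tr = int(round(fractions[0] * len(self)))
        n_va = int(round(fractions[1] * len(self)))
        return idx[:n_tr], idx[n_tr:n_tr + n_va], idx[n_tr + n_va:]


def _arrays_distinct(a: np.ndarray, b: np.ndarray, tol: float,
                     min_differing: int = 2) -> bool:
    """Uniqueness rule: at least ``min_differing`` electrodes moved."""
    moved = np.linalg.norm(a - b, axis=1) > tol
    return int(moved.sum()) >= min_differing


def scenario_field(
    mesh: Mesh, scenario: ThrombusScenario,
    base: ConductivityField | None = None,
) -> ConductivityField:
    """Conductivity field with all targets of one scenario inserted."""
    fld = (base or ConductivityField.homogeneous(mesh)).copy()
    for t in scenario.targets:
        fld = insert_spherical_target(fld, mesh, t.center, t.diameter, t.sigma)
    return fld


def pooled_delta_vr(
    solution_hom: FieldSolution,
    solver: ForwardSolver,
    scenarios: list[ThrombusScenario],
    pattern: IMPattern,
) -> np.ndarray:
    """|dVr| entries of all scenarios stacked into one pool."""
    v_hom = solution_hom.measure(pattern)
    base = ConductivityField.homogeneous(solver.mesh)
    pool = []
    for sc in scenarios:
        fld = scenario_field(solver.mesh, sc, base)
        v_inh = solver.factorize(fld).measure(pattern)
        pool.append(delta_vr(v_inh, v_hom))
    return np.concatenate(pool)


def build_surrogate_dataset(
    mesh: Mesh,
    pattern: IMPattern,
    scenarios: list[ThrombusScenario],
    n_random: int = 8000,
    mu_elpos: float = 0.030,
    sigma_elpos: float = 0.012,
    geom: OxygenatorGeometry | None = None,
    seed: int = 0,
    uniqueness_tol: float = 1e-4,
) -> SurrogateDataset:
    """Simulate random arrays and extract (features, coordinates) pairs.

    For each array that passes the uniqueness rule (at least two electrodes
    differing from every retained array) the sensitivity matrix for the
    shared measurement frame and the dVr pool over all scenario sets are
    computed; degenerate arrays (zero sensitivity row or zero |dVr| entry)
    are dropped with a log entry.
    """
    geom = geom or OxygenatorGeometry()
    rng = np.random.default_rng(seed)
    kept_pos: list[np.ndarray] = []
    feats, coords, rows = [], [], []
    for _ in range(n_random):
        arr = generate_random_array(mu_elpos, sigma_elpos, rng, geom=geom)
        pos = arr.positions()
        if any(not _arrays_distinct(pos, other, uniqueness_tol)
               for other in kept_pos):
            continue
        solver = ForwardSolver(mesh, arr, geom)
        hom = ConductivityField.homogeneous(mesh)
        sol = solver.factorize(hom)
        J = sol.jacobian(pattern)
        try:
            pool = pooled_delta_vr(sol, solver, scenarios, pattern)
            fv = extract_features(J, pool)
        except ValueError as exc:
            logger.info("dropping degenerate array: %s", exc)
            continue
        kept_pos.append(pos)
        feats.append(fv.as_array())
        coords.append(pos.ravel())
        rows.append(candidate_figures(J, pool))
    return SurrogateDataset(
        features=np.array(feats),
        coords=np.array(coords),
        figures=pd.DataFrame(rows),
        seed=seed,
    )


def correlation_screen(figures: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix over all candidate figures of merit.

    Zero-variance columns produce undefined correlations and are reported
    as NaN.  This is a report only; the surrogate's input set is fixed.
    """
    if len(figures) < 3:
        raise ValueError("need at least 3 arrays for a correlation screen")
    return figures.corr(method="pearson")


@dataclass
class SurrogateModel:
    """Trained surrogate plus the feature/target scalings recorded with it.

    Features are min-max scaled and the coordinate targets standardised on
    the training split; both transforms are stored so predictions (and the
    ideal-feature query) pass through the identical pipeline.
    """

    net: MLP
    feat_min: np.ndarray
    feat_range: np.ndarray
    coord_mean: np.ndarray
    coord_scale: np.ndarray
    history: TrainingHistory = field(repr=False, default=None)

    def scale(self, features: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(features) - self.feat_min) / self.feat_range

    def predict_coords(self, features: np.ndarray) -> np.ndarray:
        out = self.net.predict(self.scale(features))
        return out * self.coord_scale + self.coord_mean


def train_surrogate(
    dataset: SurrogateDataset,
    widths: tuple[int, int] = SURROGATE_WIDTHS,
    epochs: int = 200,
    lr0: float = 1e-3,
    l2: float = 1e-6,
    momentum: float = 0.9,
    leak: float = 0.01,
    batch_size: int = 32,
    seed: int = 0,
    split_seed: int = 0,
    scaling: str = "minmax",
) -> SurrogateModel:
    """Train the features -> coordinates regression network (80/10/10 split).

    Features are min-max scaled on the training split by default (``scaling
    = "identity"`` disables this); the scaling is stored with the model so
    ideal feature queries pass through the same transform.
    """
    tr, va, _ = dataset.split(seed=split_seed)
    X, Y = dataset.features, dataset.coords
    if scaling == "minmax":
        fmin = X[tr].min(axis=0)
        frange = X[tr].max(axis=0) - fmin
        frange[frange <= 0] = 1.0
    elif scaling == "identity":
        fmin, frange = np.zeros(X.shape[1]), np.ones(X.shape[1])
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    cmean = Y[tr].mean(axis=0)
    cscale = np.full(Y.shape[1], max(Y[tr].std(), 1e-12))
    net = MLP((3, *widths, Y.shape[1]), task="regression", leak=leak,
              seed=seed)
    model = SurrogateModel(net=net, feat_min=fmin, feat_range=frange,
                           coord_mean=cmean, coord_scale=cscale)
    yt = (Y - cmean) / cscale
    model.history = net.fit(
        model.scale(X[tr]), yt[tr],
        X_val=model.scale(X[va]) if len(va) else None,
        y_val=yt[va] if len(va) else None,
        epochs=epochs, lr0=lr0, momentum=momentum, l2=l2,
        batch_size=batch_size, seed=seed,
    )
    return model


def symmetrize_array(array: ElectrodeArray) -> ElectrodeArray:
    """Equalise the radial distance over the 8 spokes of each plane (mean),
    clamped to each spoke's admissible range."""
    radial = array.radial.reshape(2, N_SPOKES)
    means = radial.mean(axis=1)
    out = np.empty_like(radial)
    for plane in range(2):
        for spoke in range(N_SPOKES):
            out[plane, spoke] = min(means[plane], array.geom.r_max(spoke))
    return ElectrodeArray(radial=out.ravel(), patch_radius=array.patch_radius,
                          contact_impedance=array.contact_impedance,
                          geom=array.geom)


def propose_array(
    model: SurrogateModel,
    ideal_features: tuple[float, float, float] = IDEAL_FEATURES,
    geom: OxygenatorGeometry | None = None,
    symmetrize: bool = False,
    patch_radius: float = 0.004,
    contact_impedance: float = 0.01,
) -> ElectrodeArray:
    """Optimized array: forward pass at the ideal features, snapped to slots."""
    geom = geom or OxygenatorGeometry()
    coords = model.predict_coords(np.asarray(ideal_features)).reshape(16, 3)
    arr = snap_to_slots(coords, geom, patch_radius=patch_radius,
                        contact_impedance=contact_impedance)
    return symmetrize_array(arr) if symmetrize else arr
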