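"""Thrombus-presence classification from simulated voltage frames.

The detector study mirrors the intended deployment: the first frame recorded
on a freshly primed oxygenator serves as the clean homogeneous reference;
later frames are normalised against it to relative voltage differences
(dVr).  Labelled samples are simulated on a fixed optimized array and
208-measurement frame:

* positives -- one spherical clot from a regular target grid, clot
  conductivity jittered N(0, sigma_target / 10);
* negatives -- the clot-free background with per-element conductivity jitter
  N(0, sigma_back / 100).

Both are augmented with white Gaussian frame noise at a configurable power
SNR (default 15 dB, i.e. noise power ~3.2% of signal power per frame).  A
shallow ReLU network (208-200-100-2, softmax) classifies frames into
thrombus present / absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split

from .forward import ForwardSolver, IMPattern, delta_vr
from .geometry import (
    SIGMA_BLOOD,
    SIGMA_CLOT,
    BG,
    ConductivityField,
    ElectrodeArray,
    Mesh,
    OxygenatorGeometry,
    build_mesh,
    insert_spherical_target,
    symmetric_array,
)
from .nn import MLP, TrainingHistory
from .thrombus_sampler import Target, make_target_grid

DETECTOR_WIDTHS = (200, 100)
#: symmetric near-wall radius used as the canonical optimized array
OPTIMIZED_ARRAY_RADIUS = 0.04


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model of the simulated measurement chain."""

    target_jitter_sd: float = SIGMA_CLOT / 10.0     # S/m, clot conductivity
    background_jitter_sd: float = SIGMA_BLOOD / 100.0  # S/m, per element
    snr_db: float = 15.0                            # frame power SNR
    sigma_min: float = 1e-4                         # S/m, truncation floor

    def __post_init__(self) -> None:
        if self.target_jitter_sd <= 0 or self.background_jitter_sd <= 0:
            raise ValueError("jitter standard deviations must be > 0")
        if not np.isfinite(self.snr_db):
            raise ValueError("SNR must be finite")


def add_frame_noise(
    frame: np.ndarray, snr_db: float, rng: np.random.Generator
) -> np.ndarray:
    """Add white Gaussian noise at an exact per-frame power SNR.

    The noise vector is scaled so that ||signal||^2 / ||noise||^2 equals
    10^(snr_db / 10) for this frame; an identically-zero frame stays zero.
    """
    norm = np.linalg.norm(frame)
    if norm == 0:
        return frame.copy()
    g = rng.standard_normal(frame.shape)
    g *= norm * 10.0 ** (-snr_db / 20.0) / np.linalg.norm(g)
    return frame + g


class DetectionSimulator:
    """Generates labelled dVr samples against one clean reference frame."""

    def __init__(
        self,
        solver: ForwardSolver,
        pattern: IMPattern,
        noise: NoiseSpec | None = None,
    ) -> None:
        self.solver = solver
        self.pattern = pattern
        self.noise = noise or NoiseSpec()
        self.hom_field = ConductivityField.homogeneous(solver.mesh)
        self.v_hom = solver.factorize(self.hom_field).measure(pattern)

    def _truncated_normal(self, mean: float, sd: float,
                          rng: np.random.Generator) -> float:
        for _ in range(1000):
            draw = rng.normal(mean, sd)
            if draw >= self.noise.sigma_min:
                return draw
        raise RuntimeError("conductivity draw persistently below floor")

    def positive(self, target: Target, rng: np.random.Generator) -> np.ndarray:
        """dVr frame for a single jittered clot; label = present."""
        sigma_t = self._truncated_normal(
            target.sigma, self.noise.target_jitter_sd, rng
        )
        fld = insert_spherical_target(
            self.hom_field, self.solver.mesh, target.center, target.diameter,
            sigma_t,
        )
        v = self.solver.factorize(fld).measure(self.pattern)
        return add_frame_noise(delta_vr(v, self.v_hom), self.noise.snr_db, rng)

    def negative(self, rng: np.random.Generator) -> np.ndarray:
        """dVr frame for jittered clot-free background; label = absent."""
        fld = self.hom_field.copy()
        bg = fld.region == BG
        jitter = rng.normal(0.0, self.noise.background_jitter_sd, bg.sum())
        fld.sigma[bg] = np.maximum(
            fld.sigma[bg] + jitter, self.noise.sigma_min
        )
        v = self.solver.factorize(fld).measure(self.pattern)
        return add_frame_noise(delta_vr(v, self.v_hom), self.noise.snr_db, rng)


@dataclass
class DetectionDataset:
    """Labelled dVr frames; label 1 = thrombus present."""

    X: np.ndarray
    y: np.ndarray
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.y)

    def split(self, fractions=(0.8, 0.1, 0.1), seed: int = 0):
        """Stratified, disjoint train/validation/test index triples."""
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        idx = np.arange(len(self))
        tr, rest = train_test_split(
            idx, train_size=fractions[0], random_state=seed, stratify=self.y
        )
        va, te = train_test_split(
            rest,
            train_size=fractions[1] / (fractions[1] + fractions[2]),
            random_state=seed,
            stratify=self.y[rest],
        )
        return tr, va, te


def build_detection_dataset(
    simulator: DetectionSimulator,
    grid: list,
    n_positive: int,
    n_negative: int,
    seed: int = 0,
) -> DetectionDataset:
    """Balanced dataset: clots drawn from the target grid + noise-only frames."""
    rng = np.random.default_rng(seed)
    replace = n_positive > len(grid)
    picks = rng.choice(len(grid), size=n_positive, replace=replace)
    X = np.empty((n_positive + n_negative, simulator.pattern.n_v))
    y = np.empty(n_positive + n_negative, dtype=int)
    for i, g in enumerate(picks):
        X[i] = simulator.positive(grid[g].targets[0], rng)
        y[i] = 1
    for i in range(n_negative):
        X[n_positive + i] = simulator.negative(rng)
        y[n_positive + i] = 0
    return DetectionDataset(X=X, y=y, seed=seed)


@dataclass
class DetectorModel:
    """Classifier plus the input standardisation fitted on its training split."""

    net: MLP
    mean: np.ndarray
    std: np.ndarray
    history: TrainingHistory = field(repr=False, default=None)

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean) / self.std

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict(self._scale(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self._scale(X))


def train_detector(
    dataset: DetectionDataset,
    splits: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    widths: tuple[int, int] = DETECTOR_WIDTHS,
    epochs: int = 200,
    lr0: float = 1e-3,
    momentum: float = 0.9,
    l2: float = 1e-6,
    batch_size: int = 32,
    seed: int = 0,
) -> tuple[DetectorModel, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Train the presence classifier on an 80/10/10 stratified split."""
    if splits is None:
        splits = dataset.split(seed=seed)
    tr, va, _ = splits
    for part, name in zip(splits, ("training", "validation", "test")):
        if len(np.unique(dataset.y[part])) < 2:
            raise ValueError(f"{name} split does not contain both classes")
    mean = dataset.X[tr].mean(axis=0)
    std = dataset.X[tr].std(axis=0)
    std[std <= 0] = 1.0
    net = MLP((dataset.X.shape[1], *widths, 2), task="classification",
              seed=seed)
    model = DetectorModel(net=net, mean=mean, std=std)
    model.history = net.fit(
        model._scale(dataset.X[tr]), dataset.y[tr],
        X_val=model._scale(dataset.X[va]), y_val=dataset.y[va],
        epochs=epochs, lr0=lr0, momentum=momentum, l2=l2,
        batch_size=batch_size, seed=seed,
    )
    return model, splits


@dataclass
class EvalReport:
    """Test-split metrics with thrombus-present as the positive class."""

    confusion: np.ndarray     # rows: true absent/present; cols: predicted
    sensitivity: float
    precision: float
    f1: float
    accuracy: float
    fp_fraction: float        # false positives / all test cases

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "fp_fraction": self.fp_fraction,
        }


def evaluate(model: DetectorModel, X_test: np.ndarray,
             y_test: np.ndarray) -> EvalReport:
    """Confusion matrix and derived metrics on a held-out test split."""
    y_test = np.asarray(y_test)
    if len(np.unique(y_test)) < 2:
        raise ValueError("test split must contain both classes")
    pred = model.predict(X_test)
    cm = confusion_matrix(y_test, pred, labels=[0, 1])
    tn, fp, fn, tp = cm.ravel()
    sensitivity = tp / (tp + fn)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if (precision + sensitivity) else 0.0)
    return EvalReport(
        confusion=cm,
        sensitivity=float(sensitivity),
        precision=float(precision),
        f1=float(f1),
        accuracy=float((tp + tn) / cm.sum()),
        fp_fraction=float(fp / cm.sum()),
    )


def run_detection_experiment(
    seed: int = 0,
    max_h: float = 0.005,
    n_positive: int = 800,
    n_negative: int = 800,
    pattern_max_h: float = 0.009,
    counts: dict[str, int] | None = None,
    grid_spacing: float = 0.0042,
    target_diameter: float = 0.01,
    noise: NoiseSpec | None = None,
    epochs: int = 200,
    geom: OxygenatorGeometry | None = None,
    array: ElectrodeArray | None = None,
    pattern: IMPattern | None = None,
) -> dict:
    """End-to-end scaled replication of the detection study.

    Selects the 208-measurement frame on a coarse mesh with the edge
    reference array, simulates a balanced dataset on the detection mesh with
    the symmetric optimized array, trains the classifier and evaluates it on
    the held-out 10% split.  Every stochastic stage is seeded from ``seed``.
    """
    from .patterns import enumerate_candidates, select_pattern
    from .geometry import edge_array

    geom = geom or OxygenatorGeometry()
    if pattern is None:
        coarse = build_mesh(geom, pattern_max_h)
        ref_array = edge_array(geom)
        solver = ForwardSolver(coarse, ref_array, geom)
        sol = solver.factorize(ConductivityField.homogeneous(coarse))
        cands = enumerate_candidates()
        cand_pattern = IMPattern(list(cands.measurements))
        J_all = sol.jacobian(cand_pattern)
        v_ref = sol.measure(cand_pattern).v
        pattern, _ = select_pattern(J_all, cands, counts=counts, v_ref=v_ref)

    mesh = build_mesh(geom, max_h)
    array = array or symmetric_array(OPTIMIZED_ARRAY_RADIUS, geom)
    simulator = DetectionSimulator(
        ForwardSolver(mesh, array, geom), pattern, noise
    )
    grid = make_target_grid(geom, diameter=target_diameter,
                            spacing=grid_spacing)
    dataset = build_detection_dataset(
        simulator, grid, n_positive, n_negative, seed=seed
    )
    model, (tr, va, te) = train_detector(dataset, epochs=epochs, seed=seed)
    report = evaluate(model, dataset.X[te], dataset.y[te])
    return {
        "report": report,
        "model": model,
        "dataset": dataset,
        "splits": (tr, va, te),
        "pattern": pattern,
        "array": array,
        "n_grid_targets": len(grid),
        "mesh_elements": mesh.n_elements,
    }
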