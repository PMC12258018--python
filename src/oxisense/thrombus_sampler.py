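"""Flow-informed thrombus placement: likelihood field, CDF sampling, grids.

Clots preferentially form where blood flow stagnates -- near the walls and
corners of the oxygenator -- while the well-perfused core stays largely
clot-free.  The flow field is approximated empirically by a centred
trivariate Gaussian (sd 0.045 m in-plane, 0.025 m vertically, i.e. half the
box dimensions), and the thrombus likelihood is its exact reciprocal:

    L(x, y, z) = sigma_x sigma_y sigma_z (2 pi)^{3/2}
                 * exp( sum_d (d - mu_d)^2 / (2 sigma_d^2) ),

smallest at the centre and increasing monotonically toward every corner.
Scenarios are drawn by percentile of the voxelised likelihood CDF: because
the isosurfaces are ellipsoidal, many voxels share one CDF value, and the
sampler picks uniformly at random among the voxels on that isoline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SIGMA_CLOT, OxygenatorGeometry

DEFAULT_SIGMAS = (0.045, 0.045, 0.025)  # m; half the default box dimensions


def likelihood(
    x: float | np.ndarray,
    y: float | np.ndarray,
    z: float | np.ndarray,
    sigmas: tuple[float, float, float] = DEFAULT_SIGMAS,
) -> float | np.ndarray:
    """Reciprocal-Gaussian thrombus likelihood at a point (zero-mean)."""
    sx, sy, sz = sigmas
    pref = sx * sy * sz * (2.0 * np.pi) ** 1.5
    expo = (np.asarray(x) ** 2 / (2 * sx**2)
            + np.asarray(y) ** 2 / (2 * sy**2)
            + np.asarray(z) ** 2 / (2 * sz**2))
    out = pref * np.exp(expo)
    return float(out) if np.isscalar(x) else out


@dataclass
class Target:
    """One spherical conductivity target (a clot surrogate)."""

    center: np.ndarray        # (3,) m
    diameter: float           # m
    sigma: float = SIGMA_CLOT  # S/m

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.diameter <= 0:
            raise ValueError("target diameter must be > 0")


@dataclass
class ThrombusScenario:
    """A set of targets with the provenance of their draw."""

    targets: list[Target]
    percentiles: list[float] = field(default_factory=list)
    seed: int | None = None


class LikelihoodField:
    """Voxelised thrombus-likelihood field over the box interior."""

    def __init__(
        self,
        geom: OxygenatorGeometry | None = None,
        voxel_size: float = 0.002,
        sigmas: tuple[float, float, float] = DEFAULT_SIGMAS,
    ) -> None:
        self.geom = geom or OxygenatorGeometry()
        self.voxel_size = float(voxel_size)
        self.sigmas = sigmas
        nx = int(round(self.geom.size_x / voxel_size))
        ny = int(round(self.geom.size_y / voxel_size))
        nz = int(round(self.geom.size_z / voxel_size))
        self.shape = (nx, ny, nz)
        axes = [
            (np.arange(n) + 0.5) * voxel_size - extent / 2.0
            for n, extent in zip(
                (nx, ny, nz), (self.geom.size_x, self.geom.size_y, self.geom.size_z)
            )
        ]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        self.centers = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        self.L = likelihood(
            self.centers[:, 0], self.centers[:, 1], self.centers[:, 2], sigmas
        )
        self.p = self.L / self.L.sum()

    @property
    def n_voxels(self) -> int:
        return len(self.L)

    def percentile_value(self, percentile: float) -> float:
        """Likelihood value at a percentile of the voxel-value distribution."""
        if not 0.0 <= percentile <= 100.0:
            raise ValueError("percentile must lie in [0, 100]")
        return float(np.percentile(self.L, percentile))

    def sample_by_percentile(
        self,
        percentile: float,
        seed: int | np.random.Generator,
        band: float = 0.005,
    ) -> np.ndarray:
        """Voxel centre drawn uniformly from the isoline at a CDF percentile.

        All voxels whose likelihood lies within a relative ``band`` of the
        percentile's value are candidates; if the band is empty it is widened
        once (x10) before giving up.
        """
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        value = self.percentile_value(percentile)
        for width in (band, band * 10.0):
            sel = np.flatnonzero(np.abs(self.L - value) <= width * value)
            if len(sel):
                return self.centers[rng.choice(sel)].copy()
        raise RuntimeError(
            f"no voxels within {band * 10:.3%} of the percentile "
            f"{percentile} likelihood value"
        )

    def sample_unconstrained(
        self, seed: int | np.random.Generator, n: int = 1
    ) -> np.ndarray:
        """Draw voxel centres from the normalized likelihood directly."""
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        idx = rng.choice(self.n_voxels, size=n, p=self.p)
        return self.centers[idx]


def make_training_sets(
    field_: LikelihoodField | None = None,
    n_sets: int = 12,
    targets_per_set: int = 6,
    percentile_range: tuple[float, float] = (5.0, 98.0),
    diameter: float = 0.01,
    sigma_t: float = SIGMA_CLOT,
    seed: int = 0,
) -> list[ThrombusScenario]:
    """Scenario sets for electrode-array evaluation.

    Every set shares one equidistant percentile schedule (default 5..98, so
    the targets of each set cover the whole oxygenator from core to corner);
    the voxel choice on each isoline is seeded per set.
    """
    if n_sets <= 0 or targets_per_set <= 0:
        raise ValueError("set counts must be positive")
    field_ = field_ or LikelihoodField()
    percentiles = np.linspace(*percentile_range, targets_per_set)
    scenarios = []
    for s in range(n_sets):
        rng = np.random.default_rng(seed + s)
        targets = [
            Target(center=field_.sample_by_percentile(p, rng),
                   diameter=diameter, sigma=sigma_t)
            for p in percentiles
        ]
        scenarios.append(
            ThrombusScenario(targets=targets, percentiles=list(percentiles),
                             seed=seed + s)
        )
    return scenarios


def make_target_grid(
    geom: OxygenatorGeometry | None = None,
    diameter: float = 0.01,
    spacing: float = 0.0042,
    sigma_t: float = SIGMA_CLOT,
) -> list[ThrombusScenario]:
    """Regular lattice of single-target scenarios for detector training.

    Sphere centres form a lattice symmetric about the box centre with every
    sphere surface strictly inside the box.  The default spacing yields a
    grid on the order of 4e3 targets for the default geometry.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    geom = geom or OxygenatorGeometry()
    half = geom.half - diameter / 2.0
    if np.any(half < 0):
        raise ValueError("sphere diameter exceeds the box")
    axes = []
    for h in half:
        n = int(np.floor(2 * h / spacing)) + 1
        axes.append((np.arange(n) - (n - 1) / 2.0) * spacing)
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    return [
        ThrombusScenario(
            targets=[Target(center=c, diameter=diameter, sigma=sigma_t)]
        )
        for c in centers
    ]
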