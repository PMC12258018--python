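"""Parametric oxygenator geometry, tetrahedral meshing and electrode arrays.

The oxygenator interior is modelled as a rectangular box (default
9 x 9 x 5 cm) with the coordinate origin at the box centre and z vertical,
so the top and bottom planes sit at z = +/- size_z/2.  A non-conductive
separation grid -- an orthogonal lattice of cylindrical rods -- spans the
mid-height plane.  Electrodes live on the top and bottom planes only, one
per angular spoke (8 spokes per plane, 45 degrees apart), which reduces the
placement search to one radial distance per spoke.

The mesh is a structured tetrahedral subdivision of the box: each hexahedral
cell is split into five tetrahedra with checkerboard parity so that faces of
neighbouring cells match.  This subdivision conserves the box volume exactly
and, for odd cell counts, is invariant under 90-degree rotation about the
vertical axis -- a property the forward solver's symmetry tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

# element region labels
BG = 0      # background (blood)
SG = 1      # separation grid (polycarbonate rods)
TARGET = 2  # inserted spherical target (clot)

# single-frequency conductivities, S/m
SIGMA_BLOOD = 0.662
SIGMA_CLOT = 0.0662
SIGMA_GRID = 1e-6

N_SPOKES = 8
SPOKE_ANGLES = np.arange(N_SPOKES) * (2.0 * np.pi / N_SPOKES)

TOP = 0
BOTTOM = 1


class MeshingError(RuntimeError):
    """Raised when a geometry cannot be meshed at the requested resolution."""


@dataclass(frozen=True)
class OxygenatorGeometry:
    """Box interior of the oxygenator with a mid-height separation grid.

    Lengths are in meters.  The separation grid is an orthogonal lattice of
    ``grid_n_rods`` rods per in-plane direction, spaced ``grid_rod_spacing``
    apart and centred on the vertical axis at height ``grid_plane_z``.
    """

    size_x: float = 0.09
    size_y: float = 0.09
    size_z: float = 0.05
    grid_rod_diameter: float = 0.004
    grid_plane_z: float = 0.0
    grid_rod_spacing: float = 0.018
    grid_n_rods: int = 5

    def __post_init__(self) -> None:
        if min(self.size_x, self.size_y, self.size_z) <= 0:
            raise ValueError("box sizes must be strictly positive")
        if self.grid_rod_diameter < 0:
            raise ValueError("grid_rod_diameter must be >= 0")
        if self.grid_rod_diameter >= min(self.size_x, self.size_y, self.size_z):
            raise ValueError("grid_rod_diameter must be smaller than the box")
        r = self.grid_rod_diameter / 2.0
        span = self._rod_offsets().max(initial=0.0) if self.grid_n_rods else 0.0
        if span + r > min(self.size_x, self.size_y) / 2.0:
            raise ValueError("separation-grid rods extend outside the box")
        if abs(self.grid_plane_z) + r > self.size_z / 2.0:
            raise ValueError("separation-grid plane too close to top/bottom")

    # -- derived quantities -------------------------------------------------

    @property
    def half(self) -> np.ndarray:
        return np.array([self.size_x, self.size_y, self.size_z]) / 2.0

    @property
    def z_top(self) -> float:
        return self.size_z / 2.0

    @property
    def z_bottom(self) -> float:
        return -self.size_z / 2.0

    def _rod_offsets(self) -> np.ndarray:
        n = self.grid_n_rods
        return (np.arange(n) - (n - 1) / 2.0) * self.grid_rod_spacing

    def rod_axes(self) -> list[tuple[str, float, float]]:
        """Rod axes as (direction, in-plane offset, z) triples.

        Direction 'x' means the rod runs along x at y = offset; 'y' the
        perpendicular set.  The two sets are orthogonal by construction.
        """
        if self.grid_rod_diameter == 0 or self.grid_n_rods == 0:
            return []
        axes: list[tuple[str, float, float]] = []
        for off in self._rod_offsets():
            axes.append(("x", float(off), self.grid_plane_z))
        for off in self._rod_offsets():
            axes.append(("y", float(off), self.grid_plane_z))
        return axes

    def r_max(self, spoke: int) -> float:
        """Largest radial distance keeping an electrode centre on the plane."""
        c, s = np.cos(SPOKE_ANGLES[spoke]), np.sin(SPOKE_ANGLES[spoke])
        lim = np.inf
        if abs(c) > 1e-12:
            lim = min(lim, (self.size_x / 2.0) / abs(c))
        if abs(s) > 1e-12:
            lim = min(lim, (self.size_y / 2.0) / abs(s))
        return float(lim)


@dataclass
class Mesh:
    """Conforming tetrahedral mesh with per-element region labels."""

    nodes: np.ndarray          # (n_nodes, 3) float
    elements: np.ndarray       # (n_elems, 4) int, positively oriented
    region: np.ndarray         # (n_elems,) int in {BG, SG}
    volumes: np.ndarray        # (n_elems,) float, > 0
    max_h: float
    _centroids: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def centroids(self) -> np.ndarray:
        if self._centroids is None:
            self._centroids = self.nodes[self.elements].mean(axis=1)
        return self._centroids


# five-tet subdivision of a unit cube; vertex index = dx + 2*dy + 4*dz
_TETS_EVEN = np.array(
    [[1, 0, 3, 5], [2, 0, 3, 6], [4, 0, 5, 6], [7, 3, 5, 6], [0, 3, 5, 6]]
)
_TETS_ODD = np.array(
    [[0, 1, 2, 4], [3, 1, 2, 7], [5, 1, 4, 7], [6, 2, 4, 7], [1, 2, 4, 7]]
)


def build_mesh(geom: OxygenatorGeometry, max_h: float) -> Mesh:
    """Mesh the box with tetrahedra of characteristic size <= ``max_h``.

    The box is divided into ``ceil(size/max_h)`` cells per direction and each
    cell into five tetrahedra (checkerboard parity, so the subdivision is
    conforming).  Elements whose centroid lies within a rod radius of a
    separation-grid rod axis are labelled ``SG``; the rest ``BG``.
    Deterministic for fixed inputs.
    """
    if max_h <= 0:
        raise ValueError("max_h must be > 0")
    nx = int(np.ceil(geom.size_x / max_h))
    ny = int(np.ceil(geom.size_y / max_h))
    nz = int(np.ceil(geom.size_z / max_h))
    if min(nx, ny, nz) < 2 and geom.grid_rod_diameter > 0:
        raise MeshingError(
            f"rod layout not resolvable at max_h={max_h}: "
            f"cells=({nx},{ny},{nz}), geometry={geom}"
        )
    xs = np.linspace(-geom.size_x / 2, geom.size_x / 2, nx + 1)
    ys = np.linspace(-geom.size_y / 2, geom.size_y / 2, ny + 1)
    zs = np.linspace(-geom.size_z / 2, geom.size_z / 2, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(ix, iy, iz):
        return (ix * (ny + 1) + iy) * (nz + 1) + iz

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    ii, jj, kk = ii.ravel(), jj.ravel(), kk.ravel()
    # node ids of the 8 cell corners, ordered dx + 2*dy + 4*dz
    corners = np.stack(
        [nid(ii + dx, jj + dy, kk + dz)
         for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)],
        axis=1,
    )[:, [0, 1, 2, 3, 4, 5, 6, 7]]
    parity = (ii + jj + kk) % 2
    elems = np.empty((len(ii), 5, 4), dtype=np.int64)
    elems[parity == 0] = corners[parity == 0][:, _TETS_EVEN]
    elems[parity == 1] = corners[parity == 1][:, _TETS_ODD]
    elements = elems.reshape(-1, 4)

    # orient positively
    p = nodes[elements]
    v6 = np.einsum(
        "ei,ei->e",
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
        p[:, 3] - p[:, 0],
    )
    flip = v6 < 0
    elements[flip] = elements[flip][:, [0, 2, 1, 3]]
    volumes = np.abs(v6) / 6.0
    if np.any(volumes <= 0):
        raise MeshingError(f"degenerate elements produced; geometry={geom}")

    mesh = Mesh(nodes=nodes, elements=elements,
                region=np.zeros(len(elements), dtype=np.int8),
                volumes=volumes, max_h=float(max_h))
    c = mesh.centroids
    r = geom.grid_rod_diameter / 2.0
    sg = np.zeros(len(elements), dtype=bool)
    for direction, off, z0 in geom.rod_axes():
        if direction == "x":
            d2 = (c[:, 1] - off) ** 2 + (c[:, 2] - z0) ** 2
        else:
            d2 = (c[:, 0] - off) ** 2 + (c[:, 2] - z0) ** 2
        sg |= d2 <= r * r
    mesh.region[sg] = SG
    return mesh


@dataclass
class ElectrodeArray:
    """16 electrodes: one per spoke on each of the top and bottom planes.

    Electrode index convention: ``plane * 8 + spoke`` with plane 0 = top.
    ``radial`` holds the distance of each electrode centre from the plane
    centre along its spoke.
    """

    radial: np.ndarray                 # (16,) distances in m
    patch_radius: float = 0.004        # contact patch radius, m
    contact_impedance: float = 0.01    # Ohm * m^2
    geom: OxygenatorGeometry = field(default_factory=OxygenatorGeometry)

    def __post_init__(self) -> None:
        self.radial = np.asarray(self.radial, dtype=float)
        if self.radial.shape != (16,):
            raise ValueError("radial must have 16 entries (2 planes x 8 spokes)")
        for idx in range(16):
            r = self.radial[idx]
            if r < 0 or r > self.geom.r_max(idx % N_SPOKES) + 1e-12:
                raise ValueError(
                    f"electrode {idx}: radial distance {r} outside the plane"
                )

    @property
    def planes(self) -> np.ndarray:
        return np.repeat([TOP, BOTTOM], N_SPOKES)

    @property
    def spokes(self) -> np.ndarray:
        return np.tile(np.arange(N_SPOKES), 2)

    def positions(self) -> np.ndarray:
        """Electrode centre coordinates, shape (16, 3)."""
        ang = SPOKE_ANGLES[self.spokes]
        z = np.where(self.planes == TOP, self.geom.z_top, self.geom.z_bottom)
        return np.column_stack(
            [self.radial * np.cos(ang), self.radial * np.sin(ang), z]
        )

    def rotated(self, quarter_turns: int = 1) -> "ElectrodeArray":
        """Array rotated by multiples of 90 degrees about the vertical axis."""
        shift = 2 * quarter_turns
        radial = self.radial.reshape(2, N_SPOKES)
        radial = np.roll(radial, shift, axis=1).ravel()
        return replace(self, radial=radial)


def generate_random_array(
    mu_elpos: float,
    sigma_elpos: float,
    seed: int | np.random.Generator,
    geom: OxygenatorGeometry | None = None,
    patch_radius: float = 0.004,
    contact_impedance: float = 0.01,
    max_attempts: int = 10_000,
) -> ElectrodeArray:
    """Draw one electrode array with N(mu, sigma) radial distances per spoke.

    Out-of-bounds draws are rejected and re-sampled (preserving the
    distributional shape near the plane edges) up to ``max_attempts`` per
    electrode.  Reproducible for a fixed seed.
    """
    if mu_elpos < 0 or sigma_elpos < 0:
        raise ValueError("mu_elpos and sigma_elpos must be >= 0")
    geom = geom or OxygenatorGeometry()
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    radial = np.empty(16)
    for idx in range(16):
        rmax = geom.r_max(idx % N_SPOKES)
        for attempt in range(max_attempts):
            r = rng.normal(mu_elpos, sigma_elpos)
            if 0.0 <= r <= rmax:
                radial[idx] = r
                break
        else:
            raise RuntimeError(
                f"no valid radial draw for electrode {idx} after "
                f"{max_attempts} attempts (mu={mu_elpos}, sigma={sigma_elpos}, "
                f"r_max={rmax})"
            )
    return ElectrodeArray(radial=radial, patch_radius=patch_radius,
                          contact_impedance=contact_impedance, geom=geom)


def symmetric_array(
    radial_distance: float,
    geom: OxygenatorGeometry | None = None,
    **kwargs,
) -> ElectrodeArray:
    """Fully symmetric array: every spoke on both planes at the same radius."""
    geom = geom or OxygenatorGeometry()
    return ElectrodeArray(radial=np.full(16, radial_distance), geom=geom,
                          **kwargs)


def edge_array(
    geom: OxygenatorGeometry | None = None,
    fraction: float = 0.9,
    **kwargs,
) -> ElectrodeArray:
    """Reference array with electrodes near the plane edges.

    Each electrode sits at ``fraction`` of its spoke's maximal radius, which
    places the diagonal spokes close to the corners.  Used as the fixed
    array for measurement-pattern design.
    """
    geom = geom or OxygenatorGeometry()
    radial = np.array([fraction * geom.r_max(k % N_SPOKES) for k in range(16)])
    return ElectrodeArray(radial=radial, geom=geom, **kwargs)


@dataclass
class ConductivityField:
    """Per-element conductivity with region labels (incl. inserted targets)."""

    sigma: np.ndarray      # (n_elems,) S/m, > 0
    region: np.ndarray     # (n_elems,) int in {BG, SG, TARGET}

    def __post_init__(self) -> None:
        if np.any(self.sigma <= 0):
            raise ValueError("conductivities must be strictly positive")

    @classmethod
    def homogeneous(
        cls,
        mesh: Mesh,
        sigma_blood: float = SIGMA_BLOOD,
        sigma_grid: float = SIGMA_GRID,
    ) -> "ConductivityField":
        sigma = np.where(mesh.region == SG, sigma_grid, sigma_blood)
        return cls(sigma=sigma.astype(float), region=mesh.region.astype(np.int8).copy())

    def copy(self) -> "ConductivityField":
        return ConductivityField(self.sigma.copy(), self.region.copy())


def insert_spherical_target(
    field: ConductivityField,
    mesh: Mesh,
    center: Sequence[float],
    diameter: float,
    sigma_t: float = SIGMA_CLOT,
) -> ConductivityField:
    """Return a new field with a spherical target of conductivity ``sigma_t``.

    Every element whose centroid lies within ``diameter / 2`` of ``center``
    is reassigned; raises if the sphere is below the mesh resolution (no
    centroid captured).
    """
    center = np.asarray(center, dtype=float)
    half = mesh.nodes.max(axis=0)  # box is origin-centred
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    if np.any(np.abs(center) > half + 1e-12):
        raise ValueError(f"target centre {center} outside the box")
    d2 = ((mesh.centroids - center) ** 2).sum(axis=1)
    inside = d2 <= (diameter / 2.0) ** 2
    if not inside.any():
        raise ValueError(
            f"target (d={diameter} m) captures no element centroid: "
            f"smaller than the mesh resolution (max_h={mesh.max_h} m)"
        )
    out = field.copy()
    out.sigma[inside] = sigma_t
    out.region[inside] = TARGET
    return out


def _slot_point(geom: OxygenatorGeometry, plane: int, spoke: int,
                xyz: np.ndarray) -> tuple[float, np.ndarray]:
    """Clamped radial coordinate and 3D point of the nearest slot position."""
    ang = SPOKE_ANGLES[spoke]
    d = np.array([np.cos(ang), np.sin(ang)])
    r = float(np.clip(xyz[:2] @ d, 0.0, geom.r_max(spoke)))
    z = geom.z_top if plane == TOP else geom.z_bottom
    return r, np.array([r * d[0], r * d[1], z])


def snap_to_slots(
    coords: np.ndarray,
    geom: OxygenatorGeometry | None = None,
    patch_radius: float = 0.004,
    contact_impedance: float = 0.01,
) -> ElectrodeArray:
    """Map 16 free-space points to the nearest valid electrode slots.

    Each point is assigned the (plane, spoke) slot minimising the Euclidean
    distance to its clamped on-spoke position.  When two points map to the
    same slot, the nearer one keeps it and the farther one moves to its
    nearest free slot (repeatedly, until conflict-free); ties break on the
    lower electrode index.  Idempotent on already-snapped arrays.
    """
    geom = geom or OxygenatorGeometry()
    coords = np.asarray(coords, dtype=float).reshape(16, 3)

    # distance of every point to every slot (2 planes x 8 spokes = 16 slots)
    dist = np.empty((16, 16))
    radii = np.empty((16, 16))
    for slot in range(16):
        plane, spoke = divmod(slot, N_SPOKES)
        for i in range(16):
            r, p = _slot_point(geom, plane, spoke, coords[i])
            dist[i, slot] = np.linalg.norm(coords[i] - p)
            radii[i, slot] = r

    assignment = np.full(16, -1, dtype=int)
    taken = np.zeros(16, dtype=bool)
    # assign in order of best achievable distance (nearest point wins a slot;
    # the displaced point falls back to its nearest free slot)
    remaining = list(range(16))
    while remaining:
        best_i, best_slot, best_d = -1, -1, np.inf
        for i in remaining:
            free = np.flatnonzero(~taken)
            slot = free[np.argmin(dist[i, free])]
            d = dist[i, slot]
            if d < best_d - 1e-15 or (abs(d - best_d) <= 1e-15 and i < best_i):
                best_i, best_slot, best_d = i, slot, d
        assignment[best_i] = best_slot
        taken[best_slot] = True
        remaining.remove(best_i)

    radial = np.empty(16)
    for i in range(16):
        radial[assignment[i]] = radii[i, assignment[i]]
    return ElectrodeArray(radial=radial, patch_radius=patch_radius,
                          contact_impedance=contact_impedance, geom=geom)
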