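"""Bioimpedance forward problem: CEM finite-element solver and sensitivities.

Solves the quasi-static conduction problem div(sigma grad u) = 0 on the
oxygenator mesh with the complete electrode model (CEM): finite contact
patches on the top/bottom planes, a contact impedance z_c per electrode, and
current conservation per electrode.  The discrete system couples nodal
potentials u with electrode voltages U:

    [ A(sigma) + M/z_c   -B/z_c ] [u]   [0]
    [    -B^T/z_c       |E|/z_c ] [U] = [I],

grounded by a zero-mean nodal-potential constraint (Lagrange multiplier).
Four-point measurements read voltage differences between two electrodes that
carry no net current, which suppresses the contact-impedance drop.

Sensitivities use the adjoint formulation: the derivative of a four-point
voltage with respect to one element's conductivity is

    J[i, j] = - integral_elem_j  grad(u_inject) . grad(u_measure) dV,

with ``u_measure`` the potential field obtained by driving unit current
through the measuring pair.  One sparse factorization per conductivity field
is reused across all injection and adjoint solves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import (
    TOP,
    ConductivityField,
    ElectrodeArray,
    Mesh,
    OxygenatorGeometry,
)

N_ELECTRODES = 16
VHOM_FLOOR = 1e-12  # V; below this a reference measurement is degenerate


class DegenerateMeasurementError(ValueError):
    """A reference voltage is too small to normalise against."""


@dataclass(frozen=True)
class Measurement:
    """One four-point measurement: inject through (a, b), measure (c, d)."""

    inject: tuple[int, int]
    measure: tuple[int, int]

    def __post_init__(self) -> None:
        a, b = self.inject
        c, d = self.measure
        if a == b or c == d:
            raise ValueError("injection/measurement pairs need distinct electrodes")
        if {a, b} & {c, d}:
            raise ValueError("four-point measurement requires disjoint pairs")
        for e in (a, b, c, d):
            if not 0 <= e < N_ELECTRODES:
                raise ValueError(f"electrode index {e} out of range")

    @property
    def reciprocal_key(self) -> tuple:
        """Key identical for a measurement and its reciprocity twin."""
        p = tuple(sorted(self.inject))
        q = tuple(sorted(self.measure))
        return (min(p, q), max(p, q))

    def swapped(self) -> "Measurement":
        return Measurement(inject=self.measure, measure=self.inject)


@dataclass
class IMPattern:
    """Ordered list of four-point measurements forming one frame."""

    measurements: list[Measurement]

    def __post_init__(self) -> None:
        keys = [m.reciprocal_key for m in self.measurements]
        if len(set(keys)) != len(keys):
            raise ValueError("pattern contains reciprocity duplicates")

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    @property
    def n_v(self) -> int:
        return len(self.measurements)

    def inject_pairs(self) -> list[tuple[int, int]]:
        seen: dict[tuple[int, int], None] = {}
        for m in self.measurements:
            seen.setdefault(m.inject, None)
        return list(seen)


@dataclass
class MeasurementFrame:
    """Voltages of one frame, optionally with relative differences."""

    v: np.ndarray
    pattern: IMPattern | None = None
    delta_vr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if not np.all(np.isfinite(self.v)):
            raise ValueError("frame contains non-finite voltages")


def delta_vr(
    v_inh: MeasurementFrame | np.ndarray,
    v_hom: MeasurementFrame | np.ndarray,
    floor: float = VHOM_FLOOR,
) -> np.ndarray:
    """Relative voltage differences (v_inh - v_hom) / v_hom, per measurement."""
    vi = v_inh.v if isinstance(v_inh, MeasurementFrame) else np.asarray(v_inh)
    vh = v_hom.v if isinstance(v_hom, MeasurementFrame) else np.asarray(v_hom)
    if vi.shape != vh.shape:
        raise ValueError("frames have different lengths")
    bad = np.abs(vh) < floor
    if bad.any():
        raise DegenerateMeasurementError(
            f"reference voltage below {floor} V for measurements "
            f"{np.flatnonzero(bad).tolist()}"
        )
    return (vi - vh) / vh


class ForwardSolver:
    """Assembles the CEM system for a fixed mesh + electrode array.

    Geometry-dependent quantities (element gradients, stiffness sparsity,
    electrode patches, contact-layer matrices) are precomputed once; each
    conductivity field then costs one sparse LU factorization via
    :meth:`factorize`.
    """

    def __init__(
        self,
        mesh: Mesh,
        array: ElectrodeArray,
        geom: OxygenatorGeometry | None = None,
        amplitude: float = 1.0,
    ) -> None:
        self.mesh = mesh
        self.array = array
        self.geom = geom or array.geom
        self.amplitude = float(amplitude)
        self._precompute_elements()
        self._precompute_electrodes()

    # -- geometric precomputation ------------------------------------------

    def _precompute_elements(self) -> None:
        nodes, elems = self.mesh.nodes, self.mesh.elements
        p = nodes[elems]                       # (m, 4, 3)
        T = p[:, 1:] - p[:, :1]                # (m, 3, 3)
        Tinv = np.linalg.inv(T)                # rows of Tinv.T are grad lambdas
        grads = np.empty((len(elems), 4, 3))
        grads[:, 1:, :] = np.transpose(Tinv, (0, 2, 1))
        grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
        self.grads = grads
        vols = self.mesh.volumes
        # per-element 4x4 stiffness (without sigma), flattened
        ke = np.einsum("eai,ebi->eab", grads, grads) * vols[:, None, None]
        self._ke_flat = ke.reshape(len(elems), 16)
        self._rows = np.repeat(elems, 4, axis=1).ravel()
        self._cols = np.tile(elems, (1, 4)).ravel()

    def _boundary_faces(self, z_plane: float) -> np.ndarray:
        """Triangles of element faces lying on a horizontal boundary plane."""
        elems = self.mesh.elements
        onplane = np.isclose(self.mesh.nodes[elems][:, :, 2], z_plane,
                             atol=1e-12)
        faces = []
        rows = np.flatnonzero(onplane.sum(axis=1) == 3)
        for e in rows:
            faces.append(elems[e][onplane[e]])
        return (np.array(faces, dtype=np.int64) if faces
                else np.empty((0, 3), dtype=np.int64))

    def _precompute_electrodes(self) -> None:
        geom = self.geom
        faces_by_plane = {
            TOP: self._boundary_faces(geom.z_top),
            1: self._boundary_faces(geom.z_bottom),
        }
        positions = self.array.positions()
        planes = self.array.planes
        n_nodes = self.mesh.n_nodes
        self.patches: list[np.ndarray] = []
        rows, cols, vals = [], [], []
        b_rows, b_cols, b_vals = [], [], []
        areas = np.zeros(N_ELECTRODES)
        for l in range(N_ELECTRODES):
            faces = faces_by_plane[planes[l]]
            if len(faces) == 0:
                raise RuntimeError(f"electrode {l}: no boundary faces on plane")
            cent = self.mesh.nodes[faces].mean(axis=1)
            d = np.linalg.norm(cent[:, :2] - positions[l, :2], axis=1)
            sel = np.flatnonzero(d <= self.array.patch_radius)
            if len(sel) == 0:
                # coarse mesh: all co-minimal faces (keeps mirror-related
                # electrodes' patches related by the same mesh symmetry)
                sel = np.flatnonzero(d <= d.min() + 1e-12)
            patch = faces[sel]
            self.patches.append(patch)
            pts = self.mesh.nodes[patch]
            a = 0.5 * np.linalg.norm(
                np.cross(pts[:, 1] - pts[:, 0], pts[:, 2] - pts[:, 0]), axis=1
            )
            areas[l] = a.sum()
            # contact-layer mass matrix on the patch: (A/12) * (1 + delta_ij)
            for f, af in zip(patch, a):
                for i in range(3):
                    for j in range(3):
                        rows.append(f[i])
                        cols.append(f[j])
                        vals.append(af / 12.0 * (2.0 if i == j else 1.0))
                    b_rows.append(f[i])
                    b_cols.append(l)
                    b_vals.append(af / 3.0)
        self.patch_areas = areas
        zc = self.array.contact_impedance
        self._M = sp.coo_matrix((np.array(vals) / zc, (rows, cols)),
                                shape=(n_nodes, n_nodes)).tocsr()
        self._B = sp.coo_matrix((np.array(b_vals) / zc, (b_rows, b_cols)),
                                shape=(n_nodes, N_ELECTRODES)).tocsr()
        self._D = sp.diags(areas / zc)

    # -- per-field factorization -------------------------------------------

    def factorize(self, cond: ConductivityField) -> "FieldSolution":
        """LU-factorize the CEM system for one conductivity field.

        The singular constant mode is removed by pinning one node's
        potential with a diagonal penalty -- exact here, because every
        right-hand side carries zero total current (orthogonal to the
        constant nullspace) -- and solutions are afterwards shifted to the
        zero-mean nodal gauge.
        """
        sigma = np.asarray(cond.sigma, dtype=float)
        if sigma.shape != (self.mesh.n_elements,):
            raise ValueError("conductivity field does not match the mesh")
        n = self.mesh.n_nodes
        data = (self._ke_flat * sigma[:, None]).ravel()
        A = sp.coo_matrix((data, (self._rows, self._cols)),
                          shape=(n, n)).tocsr() + self._M
        pin = sp.coo_matrix(([A.diagonal().mean()], ([0], [0])), shape=(n, n))
        system = sp.bmat(
            [[A + pin, -self._B], [-self._B.T, self._D]], format="csc"
        )
        try:
            lu = splu(system, permc_spec="MMD_AT_PLUS_A")
        except RuntimeError as exc:  # pragma: no cover - pathological meshes
            raise RuntimeError(f"singular CEM system: {exc}") from exc
        return FieldSolution(self, lu)


class FieldSolution:
    """Factorized forward operator for one conductivity field."""

    def __init__(self, solver: ForwardSolver, lu) -> None:
        self.solver = solver
        self._lu = lu
        self._cache: dict[tuple[int, int], np.ndarray] = {}
        self._n_nodes = solver.mesh.n_nodes

    def prime(self, pairs: list[tuple[int, int]]) -> None:
        """Batch-solve all not-yet-cached drive pairs in one LU pass."""
        todo = [p for p in dict.fromkeys(pairs)
                if p not in self._cache and (p[1], p[0]) not in self._cache]
        if not todo:
            return
        rhs = np.zeros((self._n_nodes + N_ELECTRODES, len(todo)))
        for k, (a, b) in enumerate(todo):
            rhs[self._n_nodes + a, k] = self.solver.amplitude
            rhs[self._n_nodes + b, k] = -self.solver.amplitude
        sols = self._lu.solve(rhs)
        if not np.all(np.isfinite(sols)):
            raise RuntimeError(
                "forward solve diverged; an electrode may be disconnected"
            )
        # shift each solution to the zero-mean nodal gauge
        sols -= sols[:self._n_nodes].mean(axis=0, keepdims=True)
        for k, pair in enumerate(todo):
            self._cache[pair] = sols[:, k]

    def drive(self, pair: tuple[int, int]) -> np.ndarray:
        """Full solution vector for unit current driven through ``pair``."""
        a, b = pair
        if (a, b) in self._cache:
            return self._cache[(a, b)]
        if (b, a) in self._cache:
            sol = -self._cache[(b, a)]
            self._cache[(a, b)] = sol
            return sol
        self.prime([pair])
        return self._cache[(a, b)]

    def electrode_voltages(self, pair: tuple[int, int]) -> np.ndarray:
        return self.drive(pair)[self._n_nodes:self._n_nodes + N_ELECTRODES]

    def electrode_currents(self, pair: tuple[int, int]) -> np.ndarray:
        """Net current through each electrode for one injection (checks KCL)."""
        sol = self.drive(pair)
        u, U = sol[:self._n_nodes], sol[self._n_nodes:self._n_nodes + N_ELECTRODES]
        s = self.solver
        # I_l = (|E_l| U_l - integral_patch u dS) / z_c
        return s._D @ U - s._B.T @ u

    def measure(self, pattern: IMPattern) -> MeasurementFrame:
        """Four-point voltages for every measurement of the pattern."""
        self.prime(pattern.inject_pairs())
        v = np.empty(pattern.n_v)
        for i, m in enumerate(pattern):
            U = self.electrode_voltages(m.inject)
            c, d = m.measure
            v[i] = U[c] - U[d]
        return MeasurementFrame(v=v, pattern=pattern)

    def _element_gradient(self, pair: tuple[int, int]) -> np.ndarray:
        u = self.drive(pair)[:self._n_nodes]
        s = self.solver
        return np.einsum("ea,eaj->ej", u[s.mesh.elements], s.grads)

    def jacobian(self, pattern: IMPattern) -> np.ndarray:
        """Adjoint sensitivity matrix, one row per measurement, one column
        per element, in V per (S/m) per unit current."""
        s = self.solver
        vols = s.mesh.volumes
        keys = sorted(
            {tuple(sorted(m.inject)) for m in pattern}
            | {tuple(sorted(m.measure)) for m in pattern}
        )
        self.prime(keys)
        G = np.stack([self._element_gradient(k) for k in keys])
        index = {k: i for i, k in enumerate(keys)}

        def row_of(pair):
            key = tuple(sorted(pair))
            return index[key], 1.0 if pair == key else -1.0

        ii, mm, sign = [], [], []
        for m in pattern:
            i, si = row_of(m.inject)
            j, sj = row_of(m.measure)
            ii.append(i)
            mm.append(j)
            sign.append(si * sj)
        ii, mm = np.array(ii), np.array(mm)
        sign = np.array(sign)
        J = np.empty((pattern.n_v, s.mesh.n_elements))
        chunk = max(1, int(4e7 // (s.mesh.n_elements * 3)))
        for start in range(0, pattern.n_v, chunk):
            sl = slice(start, start + chunk)
            J[sl] = np.einsum("cej,cej->ce", G[ii[sl]], G[mm[sl]])
            J[sl] *= -sign[sl, None] * vols[None, :]
        return J


def solve_forward(
    mesh: Mesh,
    cond: ConductivityField,
    pattern: IMPattern,
    array: ElectrodeArray,
    geom: OxygenatorGeometry | None = None,
) -> MeasurementFrame:
    """One-shot convenience wrapper: build solver, factorize, measure."""
    return ForwardSolver(mesh, array, geom).factorize(cond).measure(pattern)


def compute_jacobian(
    mesh: Mesh,
    cond: ConductivityField,
    pattern: IMPattern,
    array: ElectrodeArray,
    geom: OxygenatorGeometry | None = None,
) -> np.ndarray:
    """One-shot convenience wrapper for the adjoint sensitivity matrix."""
    return ForwardSolver(mesh, array, geom).factorize(cond).jacobian(pattern)
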