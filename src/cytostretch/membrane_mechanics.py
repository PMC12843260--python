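"""Incompressible Mooney-Rivlin model of the PDMS stretch-chamber membrane.

The membrane is idealized as a 2-D plane-stress sheet (out-of-plane bending is
neglected; the ~1 mm thickness enters only through force integration).
Incompressibility is enforced exactly through the thickness stretch
``lambda3 = 1 / det F``; substituting it into the strain-energy density

    W = C10 (I1 - 3) + C01 (I2 - 3)

eliminates the pressure, since the transverse normal Cauchy stress then
vanishes identically.  The solver is a total-Lagrangian quadrilateral FEM
(2x2 Gauss quadrature) with incremental loading and Newton iteration; the
residual is the analytic gradient of the total strain energy, and the
iteration matrix is assembled from batched central finite differences of the
element internal forces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "MooneyRivlinMaterial",
    "DeformationState",
    "MembraneMesh",
    "BoundaryCondition",
    "StrainField",
    "UniformityReport",
    "ConvergenceError",
    "strain_energy",
    "uniaxial_stress",
    "build_membrane_mesh",
    "uniaxial_stretch_bc",
    "solve_plane_stress",
    "evaluate_field",
    "total_strain_energy",
    "internal_force",
    "von_mises",
    "central_region_uniformity",
    "write_vtk",
]

_I2 = np.eye(2)


class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries load-step and residual diagnostics."""


@dataclass(frozen=True)
class MooneyRivlinMaterial:
    """Mooney-Rivlin coefficients in MPa (defaults: Sylgard-184 PDMS, 10:1)."""

    C10: float = 0.12
    C01: float = 0.03

    def __post_init__(self):
        if self.C10 <= 0 or self.C01 < 0:
            raise ValueError("require C10 > 0 and C01 >= 0")


@dataclass(frozen=True)
class DeformationState:
    """In-plane deformation gradient with incompressible thickness stretch.

    I1, I2 are the invariants of the full 3-D right Cauchy-Green tensor built
    from the in-plane part and lambda3^2, with det(F)*lambda3 = 1.
    """

    F: np.ndarray
    lambda3: float
    I1: float
    I2: float

    @classmethod
    def from_F(cls, F) -> "DeformationState":
        F = np.asarray(F, dtype=float).reshape(2, 2)
        J = float(np.linalg.det(F))
        if J <= 0:
            raise ValueError("in-plane deformation gradient must have det > 0")
        lam3 = 1.0 / J
        C = F.T @ F
        a = float(np.trace(C))
        d = float(np.linalg.det(C))
        i1 = a + lam3**2
        i2 = d + lam3**2 * a
        return cls(F=F, lambda3=lam3, I1=i1, I2=i2)


def strain_energy(state: DeformationState, mat: MooneyRivlinMaterial) -> float:
    """Strain-energy density W = C10 (I1 - 3) + C01 (I2 - 3) in MPa."""
    if state.I1 < 3.0 - 1e-9 or state.I2 < 3.0 - 1e-9:
        raise ValueError("invalid deformation state: invariants below 3")
    return mat.C10 * (state.I1 - 3.0) + mat.C01 * (state.I2 - 3.0)


def uniaxial_stress(lam: float, mat: MooneyRivlinMaterial) -> float:
    """Closed-form incompressible uniaxial Cauchy stress in MPa.

    sigma = 2 (lam^2 - 1/lam) (C10 + C01/lam); the small-strain slope at
    lam = 1 is 6 (C10 + C01), the Young's-modulus analogue.
    """
    if lam <= 0:
        raise ValueError("stretch must be positive")
    return 2.0 * (lam**2 - 1.0 / lam) * (mat.C10 + mat.C01 / lam)


# --------------------------------------------------------------------------- #
# mesh and boundary conditions
# --------------------------------------------------------------------------- #

@dataclass
class MembraneMesh:
    """Structured quad mesh of a rectangular membrane (coordinates in mm)."""

    node_coordinates: np.ndarray  # (n_nodes, 2)
    quad_elements: np.ndarray  # (n_elements, 4), counterclockwise
    thickness: float
    length: float
    width: float
    nx: int
    ny: int


def build_membrane_mesh(
    length_mm: float, width_mm: float, thickness_mm: float, nx: int, ny: int
) -> MembraneMesh:
    """Structured quad grid over [0, length] x [0, width]."""
    if min(length_mm, width_mm, thickness_mm) <= 0:
        raise ValueError("membrane dimensions must be positive")
    if nx < 2 or ny < 2:
        raise ValueError("nx and ny must be >= 2")
    dx, dy = length_mm / nx, width_mm / ny
    if max(dx / dy, dy / dx) > 5:
        warnings.warn(f"element aspect ratio {max(dx / dy, dy / dx):.1f} exceeds 5",
                      stacklevel=2)
    xs = np.linspace(0.0, length_mm, nx + 1)
    ys = np.linspace(0.0, width_mm, ny + 1)
    gx, gy = np.meshgrid(xs, ys)  # row-major: node = iy * (nx+1) + ix
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    elems = []
    for iy in range(ny):
        for ix in range(nx):
            n0 = iy * (nx + 1) + ix
            elems.append([n0, n0 + 1, n0 + nx + 2, n0 + nx + 1])
    return MembraneMesh(nodes, np.asarray(elems, dtype=int), thickness_mm,
                        length_mm, width_mm, nx, ny)


@dataclass
class BoundaryCondition:
    """Prescribed displacement dofs: ``dofs[i]`` (node*2 + component) -> value."""

    dofs: np.ndarray
    values: np.ndarray
    fixed_edge_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    displaced_edge_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __post_init__(self):
        if self.dofs.size != self.values.size:
            raise ValueError("dofs and values must align")
        if np.intersect1d(self.fixed_edge_nodes, self.displaced_edge_nodes).size:
            raise ValueError("fixed and displaced edges must be disjoint")


def uniaxial_stretch_bc(
    mesh: MembraneMesh, displacement_mm: float, grip: bool = True
) -> BoundaryCondition:
    """Stretch BC: x=0 edge fixed, x=L edge displaced axially; lateral edges free.

    With ``grip=True`` both short edges are clamped laterally as by the device
    grips.  With ``grip=False`` a roller (axial-only) condition is used, with
    one corner pinned laterally — this admits the homogeneous uniaxial
    solution used to check the closed form.
    """
    x = mesh.node_coordinates[:, 0]
    fixed = np.flatnonzero(np.isclose(x, 0.0))
    moved = np.flatnonzero(np.isclose(x, mesh.length))
    if fixed.size == 0 or moved.size == 0:
        raise ValueError("edge node sets are empty")
    dofs, vals = [], []
    for n in fixed:
        dofs.append(2 * n)
        vals.append(0.0)
        if grip:
            dofs.append(2 * n + 1)
            vals.append(0.0)
    for n in moved:
        dofs.append(2 * n)
        vals.append(displacement_mm)
        if grip:
            dofs.append(2 * n + 1)
            vals.append(0.0)
    if not grip:  # pin one lateral dof to remove rigid translation
        dofs.append(2 * int(fixed[0]) + 1)
        vals.append(0.0)
    return BoundaryCondition(np.asarray(dofs, int), np.asarray(vals, float),
                             fixed, moved)


# --------------------------------------------------------------------------- #
# element kinematics (batched over elements and Gauss points)
# --------------------------------------------------------------------------- #

_GP = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float) / np.sqrt(3.0)


def _shape_gradients(mesh: MembraneMesh):
    """dN/dX (E, G, 4, 2) and integration weights w*detJ (E, G)."""
    X = mesh.node_coordinates[mesh.quad_elements]  # (E, 4, 2)
    n_e = X.shape[0]
    dndx = np.empty((n_e, 4, 4, 2))
    wdet = np.empty((n_e, 4))
    for g, (xi, eta) in enumerate(_GP):
        dn = 0.25 * np.array([
            [-(1 - eta), -(1 - xi)],
            [(1 - eta), -(1 + xi)],
            [(1 + eta), (1 + xi)],
            [-(1 + eta), (1 - xi)],
        ])  # (4, 2) wrt (xi, eta)
        jac = np.einsum("eak,al->ekl", X, dn)  # (E, 2, 2)
        det = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
        if np.any(det <= 0):
            raise ValueError("degenerate element (non-positive Jacobian)")
        inv = np.empty_like(jac)
        inv[:, 0, 0] = jac[:, 1, 1]
        inv[:, 1, 1] = jac[:, 0, 0]
        inv[:, 0, 1] = -jac[:, 0, 1]
        inv[:, 1, 0] = -jac[:, 1, 0]
        inv /= det[:, None, None]
        dndx[:, g] = np.einsum("al,elk->eak", dn, inv)
        wdet[:, g] = det  # unit Gauss weights for 2x2 rule
    return dndx, wdet


def _pk2_stress(C: np.ndarray, mat: MooneyRivlinMaterial) -> np.ndarray:
    """Second Piola-Kirchhoff stress (in-plane, pressure eliminated).

    C is the in-plane right Cauchy-Green tensor, shape (..., 2, 2).
    """
    a = C[..., 0, 0] + C[..., 1, 1]
    d = C[..., 0, 0] * C[..., 1, 1] - C[..., 0, 1] * C[..., 1, 0]
    cinv = np.empty_like(C)
    cinv[..., 0, 0] = C[..., 1, 1]
    cinv[..., 1, 1] = C[..., 0, 0]
    cinv[..., 0, 1] = -C[..., 0, 1]
    cinv[..., 1, 0] = -C[..., 1, 0]
    cinv /= d[..., None, None]
    k_id = mat.C10 + mat.C01 / d
    k_ci = -mat.C10 / d + mat.C01 * d - mat.C01 * a / d
    return 2.0 * (k_id[..., None, None] * _I2 + k_ci[..., None, None] * cinv)


def _element_forces(u_e, dndx, wdet, thickness, mat):
    """Internal nodal forces per element, (E, 4, 2)."""
    F = np.einsum("eai,egaj->egij", u_e, dndx) + _I2
    C = np.einsum("egki,egkj->egij", F, F)
    S = _pk2_stress(C, mat)
    P = np.einsum("egik,egkj->egij", F, S)
    return np.einsum("egij,egaj,eg->eai", P, dndx, wdet) * thickness


def _energy_density(C, mat):
    a = C[..., 0, 0] + C[..., 1, 1]
    d = C[..., 0, 0] * C[..., 1, 1] - C[..., 0, 1] * C[..., 1, 0]
    i1 = a + 1.0 / d
    i2 = d + a / d
    return mat.C10 * (i1 - 3.0) + mat.C01 * (i2 - 3.0)


def internal_force(mesh: MembraneMesh, mat: MooneyRivlinMaterial, u: np.ndarray,
                   _cache=None) -> np.ndarray:
    """Assembled internal force vector (2*n_nodes,) for nodal displacements u."""
    dndx, wdet = _cache if _cache is not None else _shape_gradients(mesh)
    u2 = u.reshape(-1, 2)
    f_e = _element_forces(u2[mesh.quad_elements], dndx, wdet, mesh.thickness, mat)
    f = np.zeros(u.size)
    edof = (2 * mesh.quad_elements[:, :, None] + np.arange(2)).reshape(-1, 8)
    np.add.at(f, edof.ravel(), f_e.reshape(-1, 8).ravel())
    return f


def total_strain_energy(mesh: MembraneMesh, mat: MooneyRivlinMaterial,
                        u: np.ndarray) -> float:
    """Total strain energy (MPa * mm^3 = mJ) at nodal displacements u."""
    dndx, wdet = _shape_gradients(mesh)
    u2 = u.reshape(-1, 2)[mesh.quad_elements]
    F = np.einsum("eai,egaj->egij", u2, dndx) + _I2
    C = np.einsum("egki,egkj->egij", F, F)
    return float(np.sum(_energy_density(C, mat) * wdet) * mesh.thickness)


def _tangent(mesh, mat, u, cache):
    dndx, wdet = cache
    u2 = u.reshape(-1, 2)
    u_e = u2[mesh.quad_elements]
    n_e = u_e.shape[0]
    h = 1e-6 * max(1.0, float(np.abs(u).max()))
    k_e = np.empty((n_e, 8, 8))
    for k in range(8):
        a, i = divmod(k, 2)
        up = u_e.copy()
        up[:, a, i] += h
        um = u_e.copy()
        um[:, a, i] -= h
        fp = _element_forces(up, dndx, wdet, mesh.thickness, mat)
        fm = _element_forces(um, dndx, wdet, mesh.thickness, mat)
        k_e[:, :, k] = (fp - fm).reshape(n_e, 8) / (2.0 * h)
    edof = (2 * mesh.quad_elements[:, :, None] + np.arange(2)).reshape(n_e, 8)
    rows = np.repeat(edof, 8, axis=1).ravel()
    cols = np.tile(edof, (1, 8)).ravel()
    n_dof = u.size
    return sp.csr_matrix((k_e.ravel(), (rows, cols)), shape=(n_dof, n_dof))


# --------------------------------------------------------------------------- #
# fields and solver
# --------------------------------------------------------------------------- #

@dataclass
class StrainField:
    """Converged membrane solution with per-element centroid measures."""

    nodal_displacements: np.ndarray  # (n_nodes, 2), mm
    F: np.ndarray  # (E, 2, 2)
    green_lagrange: np.ndarray  # (E, 2, 2)
    principal_strains: np.ndarray  # (E, 2), e1 >= e2 (Green-Lagrange)
    principal_directions_deg: np.ndarray  # (E,), direction of e1, [0, 180)
    cauchy_stress: np.ndarray  # (E, 2, 2), MPa
    von_mises_stress: np.ndarray  # (E,), MPa
    element_centroids: np.ndarray  # (E, 2), mm
    quad_point_F: np.ndarray  # (E, G, 2, 2) for incompressibility diagnostics
    mesh: MembraneMesh

    @property
    def max_principal_engineering_strain(self) -> np.ndarray:
        """Engineering principal strain sqrt(1 + 2 E1) - 1 per element."""
        return np.sqrt(1.0 + 2.0 * self.principal_strains[:, 0]) - 1.0


def evaluate_field(mesh: MembraneMesh, mat: MooneyRivlinMaterial,
                   u: np.ndarray) -> StrainField:
    """Postprocess nodal displacements into per-element strain/stress measures.

    Element tensors are evaluated at the element centroid; Cauchy stress uses
    sigma = F S F^T, exact because the full 3-D Jacobian is one.
    """
    dndx, _ = _shape_gradients(mesh)
    u2 = u.reshape(-1, 2)
    u_e = u2[mesh.quad_elements]
    F_gp = np.einsum("eai,egaj->egij", u_e, dndx) + _I2

    # centroid evaluation: dN/dX at xi=eta=0 equals mean over the 2x2 points
    # only for affine elements; recompute exactly at the centroid instead
    X = mesh.node_coordinates[mesh.quad_elements]
    dn0 = 0.25 * np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
    jac = np.einsum("eak,al->ekl", X, dn0)
    det = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
    inv = np.empty_like(jac)
    inv[:, 0, 0] = jac[:, 1, 1]
    inv[:, 1, 1] = jac[:, 0, 0]
    inv[:, 0, 1] = -jac[:, 0, 1]
    inv[:, 1, 0] = -jac[:, 1, 0]
    inv /= det[:, None, None]
    dndx0 = np.einsum("al,elk->eak", dn0, inv)
    F = np.einsum("eai,eaj->eij", u_e, dndx0) + _I2

    C = np.einsum("eki,ekj->eij", F, F)
    E = 0.5 * (C - _I2)
    evals, evecs = np.linalg.eigh(E)  # ascending
    e1 = evals[:, 1]
    e2 = evals[:, 0]
    v1 = evecs[:, :, 1]
    dirs = np.rad2deg(np.arctan2(v1[:, 1], v1[:, 0])) % 180.0

    S = _pk2_stress(C, mat)
    sigma = np.einsum("eik,ekl,ejl->eij", F, S, F)
    vm = np.sqrt(sigma[:, 0, 0] ** 2 - sigma[:, 0, 0] * sigma[:, 1, 1]
                 + sigma[:, 1, 1] ** 2 + 3.0 * sigma[:, 0, 1] ** 2)
    centroids = X.mean(axis=1)
    return StrainField(
        nodal_displacements=u2,
        F=F,
        green_lagrange=E,
        principal_strains=np.column_stack([e1, e2]),
        principal_directions_deg=dirs,
        cauchy_stress=sigma,
        von_mises_stress=vm,
        element_centroids=centroids,
        quad_point_F=F_gp,
        mesh=mesh,
    )


def solve_plane_stress(
    mesh: MembraneMesh,
    mat: MooneyRivlinMaterial,
    bc: BoundaryCondition,
    n_load_steps: int = 10,
    newton_tol: float = 1e-8,
    max_iterations: int = 25,
) -> StrainField:
    """Displacement-driven Newton solve of the plane-stress membrane problem.

    The prescribed edge displacement is applied in equal increments; each step
    iterates until the free-dof residual falls below ``newton_tol`` relative
    to the step's initial residual.  Non-convergence raises
    :class:`ConvergenceError` with step and residual diagnostics.
    """
    if newton_tol <= 0:
        raise ValueError("newton_tol must be positive")
    cache = _shape_gradients(mesh)
    n_dof = 2 * mesh.node_coordinates.shape[0]
    if bc.dofs.max(initial=-1) >= n_dof:
        raise ValueError("boundary condition references nodes outside the mesh")
    free = np.setdiff1d(np.arange(n_dof), bc.dofs)
    u = np.zeros(n_dof)

    for step in range(1, n_load_steps + 1):
        u[bc.dofs] = (step / n_load_steps) * bc.values
        r0 = None
        for _ in range(max_iterations):
            r = internal_force(mesh, mat, u, _cache=cache)[free]
            rn = float(np.linalg.norm(r))
            if r0 is None:
                r0 = rn
            if rn <= newton_tol * max(r0, 1e-300) or rn < 1e-14:
                break
            K = _tangent(mesh, mat, u, cache)[free][:, free]
            u[free] += spla.spsolve(K.tocsc(), -r)
        else:
            raise ConvergenceError(
                f"Newton failed at load step {step}/{n_load_steps}: "
                f"residual {rn:.3e} (initial {r0:.3e}) after "
                f"{max_iterations} iterations"
            )
    return evaluate_field(mesh, mat, u)


def von_mises(field: StrainField) -> np.ndarray:
    """Plane-stress von Mises stress per element (sigma33 = 0), MPa."""
    s = field.cauchy_stress
    return np.sqrt(s[:, 0, 0] ** 2 - s[:, 0, 0] * s[:, 1, 1] + s[:, 1, 1] ** 2
                   + 3.0 * s[:, 0, 1] ** 2)


@dataclass(frozen=True)
class UniformityReport:
    """Strain statistics over the central region of the membrane."""

    central_region_fraction: float
    mean_max_principal_engineering_strain: float
    sd_max_principal_engineering_strain: float
    max_transverse_shear: float
    n_elements: int


def central_region_uniformity(field: StrainField, fraction: float = 1.0 / 3.0
                              ) -> UniformityReport:
    """Mean/sd of the maximum principal engineering strain in the central region.

    The region spans the central ``fraction`` of the membrane length and the
    full width minus one element row at each lateral edge, keeping it strictly
    inside the clamped boundaries.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    mesh = field.mesh
    cx = field.element_centroids[:, 0]
    cy = field.element_centroids[:, 1]
    half = fraction * mesh.length / 2.0
    dy = mesh.width / mesh.ny
    sel = (np.abs(cx - mesh.length / 2.0) <= half) & (cy > dy) & (cy < mesh.width - dy)
    if not np.any(sel):
        raise ValueError("central region contains no elements at this mesh")
    eng = field.max_principal_engineering_strain[sel]
    shear = np.abs(field.green_lagrange[sel, 0, 1])
    return UniformityReport(
        central_region_fraction=fraction,
        mean_max_principal_engineering_strain=float(eng.mean()),
        sd_max_principal_engineering_strain=float(eng.std(ddof=0)),
        max_transverse_shear=float(shear.max()),
        n_elements=int(sel.sum()),
    )


def write_vtk(field: StrainField, path) -> None:
    """Export mesh, displacements and element fields as legacy ASCII VTK."""
    mesh = field.mesh
    nodes = mesh.node_coordinates
    elems = mesh.quad_elements
    lines = [
        "# vtk DataFile Version 3.0",
        "cytostretch membrane solution",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(nodes)} double",
    ]
    lines += [f"{x:.9g} {y:.9g} 0" for x, y in nodes]
    lines.append(f"CELLS {len(elems)} {len(elems) * 5}")
    lines += ["4 " + " ".join(map(str, e)) for e in elems]
    lines.append(f"CELL_TYPES {len(elems)}")
    lines += ["9"] * len(elems)  # VTK_QUAD
    lines.append(f"POINT_DATA {len(nodes)}")
    lines.append("VECTORS displacement double")
    lines += [f"{u:.9g} {v:.9g} 0" for u, v in field.nodal_displacements]
    lines.append(f"CELL_DATA {len(elems)}")
    lines.append("SCALARS von_mises_MPa double 1")
    lines.append("LOOKUP_TABLE default")
    lines += [f"{v:.9g}" for v in field.von_mises_stress]
    lines.append("SCALARS max_principal_eng_strain double 1")
    lines.append("LOOKUP_TABLE default")
    lines += [f"{v:.9g}" for v in field.max_principal_engineering_strain]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
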