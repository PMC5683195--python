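"""Linear-elastic co-motion study of the navigation aid and the tumour.

The guidance system assumes the barbed navigation aid stays rigidly related
to the tumour while the ultrasound probe presses on the organ.  This module
re-creates that verification with a deliberately simplified model: the kidney
is a 50 mm cube of isotropic linear-elastic material (cortical 15.4 kPa or
medullary 10.8 kPa, Poisson ratio 0.45), the 20 mm tumour sits 20 mm deep,
the probe load is a uniform traction over a 28 x 5 mm footprint placed 10 mm
from the aid's edge, and the cube's base is fixed.  The mesh is a structured
grid of trilinear (8-node) hexahedra with 2x2x2 Gauss integration.

The question asked of the solve is geometric: after deformation, how far is
the tumour centre from where the aid *predicts* it (rigidly coupled, 20 mm
below the aid)?  The aid's pose is recovered as the best-fit rigid motion of
its leg nodes, so longer barbs track deeper tissue.  Because the model is
linear, displacements scale exactly with force and inversely with stiffness;
the sweep exploits this by solving once per mesh and scaling.

Coordinates: z is depth below the organ surface (consistent with the aid
frame), so the surface is z = 0 and the fixed base is z = 50.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg, spsolve, LinearOperator

__all__ = [
    "FemScenario",
    "HexMesh",
    "DisplacementField",
    "build_scenario_mesh",
    "hex_element_stiffness",
    "solve_elasticity",
    "solve_scenario",
    "nodes_to_dofs",
    "assemble_stiffness",
    "footprint_loads",
    "linearized_rigid_fit",
    "aid_tumour_error",
    "run_parameter_sweep",
    "sweep_to_csv",
    "max_sweep_error",
    "DEFAULT_FORCES_N",
    "DEFAULT_LEGS_MM",
    "DEFAULT_MODULI_KPA",
]

#: default parameter grids of the co-motion sweep
DEFAULT_FORCES_N = (0.1, 0.5, 1.0)
DEFAULT_LEGS_MM = (0.0, 5.0, 10.0)
DEFAULT_MODULI_KPA = (10.8, 15.4)


@dataclass(frozen=True)
class FemScenario:
    """Geometry, load and material of one co-motion case (mm, N, kPa)."""

    cube_edge: float = 50.0
    tumour_diameter: float = 20.0
    tumour_depth: float = 20.0
    leg_length: float = 10.0
    probe_force: float = 0.5
    modulus_kpa: float = 15.4
    poisson: float = 0.45
    aid_half_width: float = 5.0
    probe_gap: float = 10.0        # footprint offset from the aid's edge
    footprint: tuple[float, float] = (5.0, 28.0)  # (along x, along y)

    def __post_init__(self) -> None:
        r = self.tumour_diameter / 2.0
        centre = self.tumour_centre
        if np.any(centre - r < 0) or np.any(centre + r > self.cube_edge):
            raise ValueError("tumour must lie fully inside the cube")
        if self.leg_length < 0 or self.leg_length > self.cube_edge:
            raise ValueError("leg length must fit inside the cube")
        if self.probe_force < 0:
            raise ValueError("probe force must be >= 0")
        if self.modulus_kpa <= 0:
            raise ValueError("elastic modulus must be positive")
        if not (0 <= self.poisson < 0.5):
            raise ValueError("Poisson ratio must be in [0, 0.5)")
        fx0 = self.cube_edge / 2.0 + self.aid_half_width + self.probe_gap
        if fx0 + self.footprint[0] > self.cube_edge:
            raise ValueError("probe footprint falls off the cube")

    @property
    def tumour_centre(self) -> np.ndarray:
        """The tumour centre sits ``tumour_depth`` below the aid (mm)."""
        c = self.cube_edge / 2.0
        return np.array([c, c, self.tumour_depth])


@dataclass
class HexMesh:
    """Structured grid of 8-node hexahedra with named node sets."""

    nodes: np.ndarray                    # (N, 3) mm
    elements: np.ndarray                 # (M, 8) node indices
    h: float                             # element edge length mm
    sets: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]


@dataclass
class DisplacementField:
    """Per-node displacement vectors (mm) on a mesh."""

    mesh: HexMesh
    u: np.ndarray                        # (N, 3)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float).reshape(self.mesh.n_nodes, 3)

    def displaced_nodes(self) -> np.ndarray:
        return self.mesh.nodes + self.u

    def scaled(self, factor: float) -> "DisplacementField":
        return DisplacementField(mesh=self.mesh, u=self.u * factor)

    def save_vtk(self, path) -> None:
        """Legacy-ASCII VTK unstructured grid with point displacements."""
        mesh = self.mesh
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\n"
                     "displacement field (mm)\nASCII\n"
                     "DATASET UNSTRUCTURED_GRID\n")
            fh.write(f"POINTS {mesh.n_nodes} float\n")
            for p in mesh.nodes:
                fh.write(f"{p[0]} {p[1]} {p[2]}\n")
            fh.write(f"CELLS {mesh.n_elements} {9 * mesh.n_elements}\n")
            for e in mesh.elements:
                fh.write("8 " + " ".join(map(str, e)) + "\n")
            fh.write(f"CELL_TYPES {mesh.n_elements}\n")
            fh.write("\n".join(["12"] * mesh.n_elements) + "\n")
            fh.write(f"POINT_DATA {mesh.n_nodes}\n"
                     "VECTORS displacement float\n")
            for v in self.u:
                fh.write(f"{v[0]} {v[1]} {v[2]}\n")


def build_scenario_mesh(s: FemScenario, h: float = 2.5) -> HexMesh:
    """Structured hex mesh of the cube with the scenario's node sets.

    Sets: ``fixed_base`` (z = cube_edge, the retracted/resting face),
    ``aid`` (surface nodes under the aid's footprint), ``legs`` (aid column
    nodes down to the leg depth; equals ``aid`` when leg length is 0),
    ``footprint`` (probe contact nodes on the surface) and ``tumour`` (nodes
    inside the sphere).
    """
    n = s.cube_edge / h
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"element size {h} must divide the cube edge {s.cube_edge}")
    n = int(round(n))
    axis = np.arange(n + 1) * h
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (n + 1) + j) * (n + 1) + k

    i, j, k = np.mgrid[0:n, 0:n, 0:n]
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    elements = np.stack([
        nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
        nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1),
        nid(i, j + 1, k + 1)], axis=1)

    x, y, z = nodes[:, 0], nodes[:, 1], nodes[:, 2]
    c = s.cube_edge / 2.0
    eps = 1e-9
    surface = z < eps
    base = np.abs(z - s.cube_edge) < eps
    in_patch = (np.abs(x - c) <= s.aid_half_width + eps) & \
               (np.abs(y - c) <= s.aid_half_width + eps)
    aid = surface & in_patch
    legs = in_patch & (z <= s.leg_length + eps)
    fx0 = c + s.aid_half_width + s.probe_gap
    fx1 = fx0 + s.footprint[0]
    fy0 = c - s.footprint[1] / 2.0
    fy1 = c + s.footprint[1] / 2.0
    foot = surface & (x >= fx0 - eps) & (x <= fx1 + eps) & \
        (y >= fy0 - eps) & (y <= fy1 + eps)
    tum = np.linalg.norm(nodes - s.tumour_centre, axis=1) <= s.tumour_diameter / 2.0 + eps
    sets = {"fixed_base": np.nonzero(base)[0],
            "aid": np.nonzero(aid)[0],
            "legs": np.nonzero(legs)[0],
            "footprint": np.nonzero(foot)[0],
            "tumour": np.nonzero(tum)[0]}
    if not sets["tumour"].size:
        raise ValueError("mesh too coarse: no nodes inside the tumour")
    return HexMesh(nodes=nodes, elements=elements, h=h, sets=sets)


# ----------------------------------------------------------------------
# element stiffness and assembly

_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)


def _shape_gradients(xi, eta, zeta) -> np.ndarray:
    """d N_a / d (xi, eta, zeta) for the 8 trilinear shape functions, (8, 3)."""
    signs = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                      [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], dtype=float)
    g = np.empty((8, 3))
    for a in range(8):
        sx, sy, sz = signs[a]
        g[a, 0] = sx * (1 + sy * eta) * (1 + sz * zeta) / 8.0
        g[a, 1] = sy * (1 + sx * xi) * (1 + sz * zeta) / 8.0
        g[a, 2] = sz * (1 + sx * xi) * (1 + sy * eta) / 8.0
    return g


def hex_element_stiffness(h: float, e_mpa: float, nu: float) -> np.ndarray:
    """24x24 stiffness of a cube hexahedron (edge h mm, E in MPa = N/mm^2)."""
    lam = e_mpa * nu / ((1 + nu) * (1 - 2 * nu))
    mu = e_mpa / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.diag_indices(3)] = lam + 2 * mu
    C[3, 3] = C[4, 4] = C[5, 5] = mu
    jac = h / 2.0  # isotropic cube element: dx/dxi = h/2
    detJ = jac ** 3
    K = np.zeros((24, 24))
    for xi in _GP:
        for eta in _GP:
            for zeta in _GP:
                g = _shape_gradients(xi, eta, zeta) / jac  # (8, 3) physical grads
                B = np.zeros((6, 24))
                for a in range(8):
                    gx, gy, gz = g[a]
                    B[0, 3 * a] = gx
                    B[1, 3 * a + 1] = gy
                    B[2, 3 * a + 2] = gz
                    B[3, 3 * a] = gy
                    B[3, 3 * a + 1] = gx
                    B[4, 3 * a + 1] = gz
                    B[4, 3 * a + 2] = gy
                    B[5, 3 * a] = gz
                    B[5, 3 * a + 2] = gx
                K += B.T @ C @ B * detJ
    return K


def assemble_stiffness(mesh: HexMesh, e_mpa: float, nu: float) -> sparse.csr_matrix:
    """Global stiffness from the single (identical-cube) element stiffness."""
    Ke = hex_element_stiffness(mesh.h, e_mpa, nu)
    conn = mesh.elements
    dofs = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(len(conn), 24)
    rows = np.repeat(dofs, 24, axis=1).ravel()
    cols = np.tile(dofs, (1, 24)).ravel()
    vals = np.tile(Ke.ravel(), len(conn))
    ndof = 3 * mesh.n_nodes
    K = sparse.coo_matrix((vals, (rows, cols)), shape=(ndof, ndof)).tocsr()
    return K


def footprint_loads(mesh: HexMesh, s: FemScenario, force_n: float) -> np.ndarray:
    """Consistent nodal loads (N) for a uniform +z traction over the probe
    footprint on the surface (pressing into the tissue)."""
    c = s.cube_edge / 2.0
    fx0 = c + s.aid_half_width + s.probe_gap
    fx1 = fx0 + s.footprint[0]
    fy0 = c - s.footprint[1] / 2.0
    fy1 = c + s.footprint[1] / 2.0
    area = (fx1 - fx0) * (fy1 - fy0)
    p = force_n / area  # N/mm^2
    h = mesh.h
    n = int(round(s.cube_edge / h))
    f = np.zeros((mesh.n_nodes, 3))

    def nid(i, j):
        return (i * (n + 1) + j) * (n + 1) + 0  # k = 0 is the surface

    for i in range(n):
        for j in range(n):
            # overlap of surface cell (i, j) with the footprint rectangle
            ox = max(0.0, min((i + 1) * h, fx1) - max(i * h, fx0))
            oy = max(0.0, min((j + 1) * h, fy1) - max(j * h, fy0))
            if ox <= 0 or oy <= 0:
                continue
            load = p * ox * oy / 4.0
            for di in (0, 1):
                for dj in (0, 1):
                    f[nid(i + di, j + dj), 2] += load
    return f


def _rigid_coupling_transform(mesh: HexMesh, node_set: np.ndarray) -> sparse.csr_matrix:
    """Master-slave transform condensing a node set into one rigid body.

    Slave displacements follow the linearized rigid motion
    ``u_i = u0 + theta x r_i`` about the set's centroid.  Returns the sparse
    map from reduced dofs ``[remaining node dofs..., u0(3), theta(3)]`` to the
    full dof vector, plus the reduced column index of every kept full dof
    (-1 for slave dofs).
    """
    node_set = np.unique(np.asarray(node_set, dtype=int))
    ndof = 3 * mesh.n_nodes
    is_slave = np.zeros(mesh.n_nodes, dtype=bool)
    is_slave[node_set] = True
    keep_nodes = np.nonzero(~is_slave)[0]
    n_keep = 3 * keep_nodes.size
    col_of = -np.ones(ndof, dtype=int)
    keep_dofs = (3 * keep_nodes[:, None] + np.arange(3)).ravel()
    col_of[keep_dofs] = np.arange(n_keep)
    rows, cols, vals = [keep_dofs], [np.arange(n_keep)], [np.ones(n_keep)]
    centroid = mesh.nodes[node_set].mean(axis=0)
    r = mesh.nodes[node_set] - centroid
    for comp in range(3):  # u0 columns
        rows.append(3 * node_set + comp)
        cols.append(np.full(node_set.size, n_keep + comp))
        vals.append(np.ones(node_set.size))
    # theta x r contributions: u_x += th_y r_z - th_z r_y (cyclic)
    cross = [(0, 4, r[:, 2]), (0, 5, -r[:, 1]),
             (1, 5, r[:, 0]), (1, 3, -r[:, 2]),
             (2, 3, r[:, 1]), (2, 4, -r[:, 0])]
    for comp, redcol, val in cross:
        rows.append(3 * node_set + comp)
        cols.append(np.full(node_set.size, n_keep + redcol))
        vals.append(val)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    T = sparse.coo_matrix((vals, (rows, cols)), shape=(ndof, n_keep + 6)).tocsr()
    return T, col_of


def _solve_spd(A: sparse.csc_matrix, b: np.ndarray, rtol: float) -> np.ndarray:
    if A.shape[0] <= 120_000:
        return spsolve(A, b)
    # large meshes: Jacobi-preconditioned CG (memory-bounded)
    d = A.diagonal()
    M = LinearOperator(A.shape, matvec=lambda x: x / d)
    x, info = cg(A, b, rtol=rtol, atol=0.0, maxiter=100_000, M=M)
    if info != 0:
        raise RuntimeError(f"CG failed to converge (info={info})")
    return x


def solve_elasticity(mesh: HexMesh, e_kpa: float, nu: float,
                     fixed_dofs: np.ndarray, loads: np.ndarray,
                     rigid_node_set: np.ndarray | None = None,
                     rtol: float = 1e-10) -> DisplacementField:
    """Small-strain isotropic solve; raises if the relative residual of the
    reduced linear system exceeds 1e-8.

    ``rigid_node_set`` condenses those nodes into a single rigid body (the
    navigation aid with its barbed legs) via a master-slave constraint before
    applying boundary conditions.
    """
    fixed_dofs = np.unique(np.asarray(fixed_dofs, dtype=int))
    if fixed_dofs.size == 0:
        raise ValueError("no constraints: the system is singular")
    K = assemble_stiffness(mesh, e_kpa * 1e-3, nu)
    f = np.asarray(loads, dtype=float).reshape(-1)
    ndof = 3 * mesh.n_nodes
    if rigid_node_set is not None and len(rigid_node_set):
        T, col_of = _rigid_coupling_transform(mesh, rigid_node_set)
        K = (T.T @ K @ T).tocsr()
        f = T.T @ f
        # map full fixed dofs into reduced numbering (rigid set is never fixed)
        if np.any(col_of[fixed_dofs] < 0):
            raise ValueError("a rigidly coupled node cannot also be fixed")
        fixed_red = col_of[fixed_dofs]
    else:
        T = None
        fixed_red = fixed_dofs
    nred = K.shape[0]
    free = np.setdiff1d(np.arange(nred), fixed_red)
    Kff = K[free][:, free].tocsc()
    ff = f[free]
    ured = np.zeros(nred)
    if np.linalg.norm(ff) > 0:
        uf = _solve_spd(Kff, ff, rtol)
        rel = np.linalg.norm(Kff @ uf - ff) / np.linalg.norm(ff)
        if rel > 1e-8:
            raise RuntimeError(f"linear solve residual too large: {rel:.2e}")
        ured[free] = uf
    u = T @ ured if T is not None else ured
    return DisplacementField(mesh=mesh, u=u.reshape(-1, 3))


def nodes_to_dofs(node_ids: np.ndarray, components=(0, 1, 2)) -> np.ndarray:
    node_ids = np.asarray(node_ids, dtype=int)
    return (3 * node_ids[:, None] + np.asarray(components)[None, :]).ravel()


def solve_scenario(s: FemScenario, h: float = 2.5, unit: bool = False,
                   rigid_aid: bool = True) -> DisplacementField:
    """Solve one co-motion case: base fixed, probe traction on the surface,
    the aid and its barbed legs condensed into one rigid body.

    With ``unit=True`` the solve uses force 1 N and the scenario modulus;
    callers can rescale by linearity (u ~ F / E).
    """
    mesh = build_scenario_mesh(s, h)
    force = 1.0 if unit else s.probe_force
    loads = footprint_loads(mesh, s, force)
    fixed = nodes_to_dofs(mesh.sets["fixed_base"])
    rigid = mesh.sets["legs"] if rigid_aid else None
    return solve_elasticity(mesh, s.modulus_kpa, s.poisson, fixed, loads,
                            rigid_node_set=rigid)


def linearized_rigid_fit(rest: np.ndarray, u: np.ndarray):
    """Least-squares small-motion rigid fit ``u_i ~ u0 + theta x r_i``.

    Consistent with the small-strain kinematics of the solver: for a node set
    moving as a (linearized) rigid body — e.g. the condensed aid — the fit is
    exact, and the resulting prediction map is linear in the displacements.
    Returns ``(u0, theta, centroid)`` with ``r_i = rest_i - centroid``.
    """
    centroid = rest.mean(axis=0)
    r = rest - centroid
    u0 = u.mean(axis=0)
    du = u - u0
    # normal equations for theta: sum(|r|^2 I - r r^T) theta = sum(r x du)
    A = np.eye(3) * np.einsum("ij,ij->", r, r) - r.T @ r
    b = np.cross(r, du).sum(axis=0)
    if np.linalg.matrix_rank(A) < 3:
        theta = np.linalg.lstsq(A, b, rcond=None)[0]
    else:
        theta = np.linalg.solve(A, b)
    return u0, theta, centroid


def aid_tumour_error(disp: DisplacementField, s: FemScenario) -> float:
    """Distance (mm) between the aid-predicted and the actual tumour centre.

    The aid's pose change is the best-fit (linearized) rigid motion of its
    leg nodes; the predicted centre is the rest tumour centroid carried along
    by that motion; the actual centre is the centroid of the displaced tumour
    nodes.  The prediction is linear in the displacement field, so the error
    scales exactly with force and inversely with stiffness.
    """
    mesh = disp.mesh
    legs = mesh.sets["legs"]
    tum = mesh.sets["tumour"]
    if legs.size == 0 or tum.size == 0:
        raise ValueError("empty aid or tumour node set")
    u0, theta, centroid = linearized_rigid_fit(mesh.nodes[legs], disp.u[legs])
    rest_centre = mesh.nodes[tum].mean(axis=0)
    predicted = rest_centre + u0 + np.cross(theta, rest_centre - centroid)
    actual = disp.displaced_nodes()[tum].mean(axis=0)
    return float(np.linalg.norm(predicted - actual))


def run_parameter_sweep(forces: Sequence[float] = DEFAULT_FORCES_N,
                        leg_lengths: Sequence[float] = DEFAULT_LEGS_MM,
                        moduli_kpa: Sequence[float] = DEFAULT_MODULI_KPA,
                        h: float = 2.5,
                        scenario: FemScenario | None = None) -> list[dict]:
    """Full factorial co-motion sweep.

    Returns one row per (force, leg length, modulus):
    ``{"force_n", "leg_mm", "modulus_kpa", "error_mm"}``.  Exploits linearity:
    one solve per leg length (the rigid aid constraint depends on it) at unit
    force and a reference modulus, then scaling by ``F * E_ref / E``.
    """
    from dataclasses import replace as _replace

    base = scenario if scenario is not None else FemScenario()
    e_ref = base.modulus_kpa
    rows = []
    for leg in leg_lengths:
        s_leg = _replace(base, leg_length=float(leg), probe_force=1.0)
        disp_ref = solve_scenario(s_leg, h=h, unit=True)
        for e in moduli_kpa:
            for force in forces:
                d = disp_ref.scaled(force * e_ref / e)
                err = aid_tumour_error(d, s_leg)
                rows.append({"force_n": float(force), "leg_mm": float(leg),
                             "modulus_kpa": float(e), "error_mm": err})
    return rows


def sweep_to_csv(rows: list[dict], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["force_n", "leg_mm", "modulus_kpa",
                                           "error_mm"])
        w.writeheader()
        w.writerows(rows)


def max_sweep_error(rows: list[dict]) -> float:
    return max(r["error_mm"] for r in rows)
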