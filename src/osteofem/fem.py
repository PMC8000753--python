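"""Finite-element model of scaffold embedding in transversely isotropic bone.

The embedded spike array is modelled on a quarter-cylinder of periarticular
trabecular bone (symmetry reduces the full cylinder to a quarter): the
cylindrical base is fixed in all directions, the symmetry planes are
constrained in their normal directions, and the spike apex footprints are
driven axially by a prescribed displacement.  The bone is a single-phase
transversely isotropic linear-elastic material whose distinguished axis is
the spike/loading (z) axis: longitudinal modulus E2, transverse plane
(E1, G1, nu1), longitudinal shear G2.

The contact between spikes and bone is simplified to prescribed axial
displacement on the footprint node sets (the loading is quasi-static, purely
axial press-fit), and the titanium scaffold is treated as rigid -- its
modulus is two orders of magnitude above the bone's.  Equivalent stress is
evaluated by the Huber-von Mises-Hencky (HMH) distortional-energy criterion,
and the embedding force at a level follows from the limit-stress criterion:
the linear solution is scaled so that the mean of the per-footprint maximum
periapical HMH stresses equals the ultimate compressive strength sigma_c.

Meshes are structured 8-node hexahedra (2x2x2 Gauss quadrature) with a
stair-step approximation of the curved cylinder boundary.  Units: mm, N, MPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import ScaffoldLayout, spike_section_radius

# Voigt order used throughout: (xx, yy, zz, yz, xz, xy), engineering shears.

# 8-node hexahedron corner signs, standard counter-clockwise ordering.
_HEX_SIGNS = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)

_GAUSS_1D = np.array([-1.0, 1.0]) / math.sqrt(3.0)


@dataclass(frozen=True)
class ElasticConstants:
    """Transversely isotropic elastic constants of cancellous bone (MPa).

    Defaults are the periarticular cancellous-bone values used in the study:
    E1=608, E2=771, G1=260, G2=269, nu1=0.17, nu2=0.15, with ultimate
    compressive strength sigma_c=25 MPa.
    """

    E1: float = 608.0
    E2: float = 771.0
    G1: float = 260.0
    G2: float = 269.0
    nu1: float = 0.17
    nu2: float = 0.15
    sigma_c: float = 25.0

    def __post_init__(self) -> None:
        if min(self.E1, self.E2, self.G1, self.G2) <= 0:
            raise ValueError("elastic moduli must be positive")
        for nu in (self.nu1, self.nu2):
            if not -1.0 < nu < 0.5:
                raise ValueError(f"Poisson ratio {nu} outside (-1, 0.5)")
        C = self.stiffness()  # raises if not positive definite

    def compliance(self) -> np.ndarray:
        """6x6 compliance with the symmetry axis along z."""
        S = np.zeros((6, 6))
        S[0, 0] = S[1, 1] = 1.0 / self.E1
        S[2, 2] = 1.0 / self.E2
        S[0, 1] = S[1, 0] = -self.nu1 / self.E1
        S[0, 2] = S[2, 0] = S[1, 2] = S[2, 1] = -self.nu2 / self.E2
        S[3, 3] = S[4, 4] = 1.0 / self.G2
        S[5, 5] = 1.0 / self.G1
        return S

    def stiffness(self) -> np.ndarray:
        C = np.linalg.inv(self.compliance())
        try:
            np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:
            raise ValueError("elastic constants give a non-positive-definite "
                             "stiffness") from exc
        return C

    def scaled_to_modulus(self, E2_new: float) -> "ElasticConstants":
        """All moduli scaled by E2_new/E2, Poisson ratios kept (used for the
        densified-bone insert)."""
        r = E2_new / self.E2
        return replace(self, E1=self.E1 * r, E2=E2_new, G1=self.G1 * r,
                       G2=self.G2 * r)


@dataclass(frozen=True)
class ScaffoldMaterial:
    """Ti-6Al-4V spike material (kept in the configuration for users who mesh
    the spikes; the default model treats the scaffold as rigid)."""

    E_GPa: float = 116.0
    nu: float = 0.34
    yield_MPa: float = 1010.0
    tensile_MPa: float = 1150.0
    elongation_pct: float = 25.0

    def __post_init__(self) -> None:
        if self.E_GPa <= 0:
            raise ValueError("E must be positive")
        if not 0.0 < self.nu < 0.5:
            raise ValueError("nu must lie in (0, 0.5)")


@dataclass
class FEMesh:
    nodes: np.ndarray                 # (N, 3) coordinates, mm
    elements: np.ndarray              # (E, 8) node indices
    element_size: float
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_dofs(self) -> int:
        return 3 * len(self.nodes)

    def footprint_sets(self) -> list[str]:
        return sorted(k for k in self.node_sets if k.startswith("apex_footprint_"))


@dataclass
class FESystem:
    mesh: FEMesh
    K: sp.csr_matrix
    bone: ElasticConstants
    insert: ElasticConstants | None = None


@dataclass
class FEResult:
    displacement: np.ndarray          # (N, 3), mm
    element_stress: np.ndarray        # (E, 6), MPa, Voigt
    hmh: np.ndarray                   # (E,), MPa
    nodal_hmh: np.ndarray             # (N,), MPa
    reaction_footprint: float         # N, axial force on loaded sets (quarter model)
    reactions: dict[str, np.ndarray]  # per-set (3,) force sums
    embed_level: float                # mm, prescribed axial displacement magnitude


def hmh_stress(stress: np.ndarray) -> np.ndarray:
    """Huber-von Mises-Hencky equivalent stress of a Voigt stress array.

    sqrt(0.5[(s_xx-s_yy)^2 + (s_yy-s_zz)^2 + (s_zz-s_xx)^2]
         + 3(t_yz^2 + t_xz^2 + t_xy^2))
    """
    s = np.asarray(stress, dtype=float)
    sq = (0.5 * ((s[..., 0] - s[..., 1]) ** 2 + (s[..., 1] - s[..., 2]) ** 2
                 + (s[..., 2] - s[..., 0]) ** 2)
          + 3.0 * (s[..., 3] ** 2 + s[..., 4] ** 2 + s[..., 5] ** 2))
    return np.sqrt(np.maximum(sq, 0.0))


def _shape_gradients(xi: np.ndarray) -> np.ndarray:
    """(8, 3) natural-coordinate gradients of the trilinear shape functions."""
    g = np.empty((8, 3))
    for i, s in enumerate(_HEX_SIGNS):
        g[i, 0] = 0.125 * s[0] * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2])
        g[i, 1] = 0.125 * s[1] * (1 + s[0] * xi[0]) * (1 + s[2] * xi[2])
        g[i, 2] = 0.125 * s[2] * (1 + s[0] * xi[0]) * (1 + s[1] * xi[1])
    return g


def _b_matrix(dN: np.ndarray) -> np.ndarray:
    """(6, 24) strain-displacement matrix from cartesian shape gradients."""
    B = np.zeros((6, 24))
    for i in range(8):
        bx, by, bz = dN[i]
        c = 3 * i
        B[0, c] = bx
        B[1, c + 1] = by
        B[2, c + 2] = bz
        B[3, c + 1] = bz
        B[3, c + 2] = by
        B[4, c] = bz
        B[4, c + 2] = bx
        B[5, c] = by
        B[5, c + 1] = bx
    return B


def hex8_stiffness(coords: np.ndarray, C: np.ndarray) -> np.ndarray:
    """24x24 stiffness of a general 8-node hexahedron, 2x2x2 Gauss."""
    Ke = np.zeros((24, 24))
    for gx in _GAUSS_1D:
        for gy in _GAUSS_1D:
            for gz in _GAUSS_1D:
                g = _shape_gradients(np.array([gx, gy, gz]))
                J = g.T @ coords            # (3,3)
                detJ = np.linalg.det(J)
                if detJ <= 0:
                    raise ValueError("inverted element (non-positive Jacobian)")
                dN = g @ np.linalg.inv(J).T  # cartesian gradients (8,3)
                B = _b_matrix(dN)
                Ke += B.T @ C @ B * detJ
    return Ke


def build_box_mesh(lengths: tuple[float, float, float],
                   element_size: float) -> FEMesh:
    """Structured hex mesh of an axis-aligned box with z=0 base and z=Lz top.

    Node sets: ``fixed_base`` (z=0), ``top`` (z=Lz), ``symmetry_x`` (x=0),
    ``symmetry_y`` (y=0).
    """
    nx, ny, nz = (max(int(round(L / element_size)), 1) for L in lengths)
    hx, hy, hz = lengths[0] / nx, lengths[1] / ny, lengths[2] / nz
    xs, ys, zs = (np.linspace(0, L, n + 1) for L, n in zip(lengths, (nx, ny, nz)))
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    elems = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                elems.append([nid(i, j, k), nid(i + 1, j, k),
                              nid(i + 1, j + 1, k), nid(i, j + 1, k),
                              nid(i, j, k + 1), nid(i + 1, j, k + 1),
                              nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)])
    elements = np.asarray(elems, dtype=np.int64)
    tol = 1e-9
    node_sets = {
        "fixed_base": np.flatnonzero(np.abs(nodes[:, 2]) < tol),
        "top": np.flatnonzero(np.abs(nodes[:, 2] - lengths[2]) < tol),
        "symmetry_x": np.flatnonzero(np.abs(nodes[:, 0]) < tol),
        "symmetry_y": np.flatnonzero(np.abs(nodes[:, 1]) < tol),
    }
    return FEMesh(nodes=nodes, elements=elements, element_size=element_size,
                  node_sets=node_sets,
                  element_sets={"bulk_bone": np.arange(len(elements))})


def build_mesh(domain_radius: float, domain_height: float,
               layout: ScaffoldLayout, embed_depth: float,
               element_size: float) -> FEMesh:
    """Quarter-cylinder mesh with per-spike apex footprint node sets.

    The quarter domain is ``x, y >= 0`` with the scaffold axis on the z axis;
    the curved boundary is stair-stepped (elements kept when their centre is
    inside the radius).  The apex plane sits at ``z = H - embed_depth``
    (snapped to the nearest grid plane); each footprint set holds the nodes
    of that plane within the spike's cross-section radius at the embedding
    depth.  Spikes outside the quarter are dropped.
    """
    if embed_depth >= domain_height:
        raise ValueError("embed_depth must be smaller than the domain height")
    radii = spike_section_radius(layout, embed_depth)
    if element_size > min(radii) + 1e-12:
        raise ValueError(
            f"element_size {element_size} does not resolve the smallest "
            f"footprint radius {min(radii):.4f} (need >= 2 elements across)")

    box = build_box_mesh((domain_radius, domain_radius, domain_height),
                         element_size)
    centers = box.nodes[box.elements].mean(axis=1)
    keep = centers[:, 0] ** 2 + centers[:, 1] ** 2 <= domain_radius ** 2
    elements = box.elements[keep]
    used = np.unique(elements)
    remap = -np.ones(box.n_nodes, dtype=np.int64)
    remap[used] = np.arange(len(used))
    nodes = box.nodes[used]
    elements = remap[elements]

    tol = 1e-9
    node_sets = {
        "fixed_base": np.flatnonzero(np.abs(nodes[:, 2]) < tol),
        "symmetry_x": np.flatnonzero(np.abs(nodes[:, 0]) < tol),
        "symmetry_y": np.flatnonzero(np.abs(nodes[:, 1]) < tol),
    }

    nz = max(int(round(domain_height / element_size)), 1)
    hz = domain_height / nz
    k_apex = int(round((domain_height - embed_depth) / hz))
    z_apex = k_apex * hz
    on_plane = np.abs(nodes[:, 2] - z_apex) < tol

    n_foot = 0
    for i, s in enumerate(layout.spikes):
        if s.center_x < -tol or s.center_y < -tol:
            continue
        r = radii[i]
        in_disc = ((nodes[:, 0] - s.center_x) ** 2
                   + (nodes[:, 1] - s.center_y) ** 2) <= (r + tol) ** 2
        footprint = np.flatnonzero(on_plane & in_disc)
        if len(footprint) == 0:
            raise ValueError(f"footprint of spike {i} unresolved by the mesh")
        node_sets[f"apex_footprint_{i}"] = footprint
        n_foot += 1
    if n_foot == 0:
        raise ValueError("no spikes inside the quarter domain")

    return FEMesh(nodes=nodes, elements=elements, element_size=element_size,
                  node_sets=node_sets,
                  element_sets={"bulk_bone": np.arange(len(elements))})


def assemble_system(mesh: FEMesh, bone: ElasticConstants,
                    insert: ElasticConstants | None = None) -> FESystem:
    """Assemble the global stiffness.  Elements in the ``densified_insert``
    set (if present) use the insert constants."""
    C_bulk = bone.stiffness()
    coords0 = mesh.nodes[mesh.elements[0]]
    Ke_bulk = hex8_stiffness(coords0, C_bulk)

    n_el = len(mesh.elements)
    insert_ids = mesh.element_sets.get("densified_insert", np.array([], dtype=int))
    if insert is not None and len(insert_ids) > 0:
        Ke_insert = hex8_stiffness(coords0, insert.stiffness())
    else:
        Ke_insert = None

    edof = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(n_el, 24)
    rows = np.repeat(edof, 24, axis=1).ravel()
    cols = np.tile(edof, (1, 24)).ravel()
    data = np.broadcast_to(Ke_bulk.ravel(), (n_el, 576)).copy()
    if Ke_insert is not None:
        data[insert_ids] = Ke_insert.ravel()
    K = sp.coo_matrix((data.ravel(), (rows, cols)),
                      shape=(mesh.n_dofs, mesh.n_dofs)).tocsr()
    return FESystem(mesh=mesh, K=K, bone=bone, insert=insert)


def solve_linear(system: FESystem, dirichlet: dict[int, float]) -> np.ndarray:
    """Solve K u = 0 under Dirichlet constraints; returns the full DOF vector.

    Direct sparse solve below ~60k DOFs, Jacobi-preconditioned conjugate
    gradients above (relative tolerance 1e-10).
    """
    K = system.K
    n = K.shape[0]
    fixed = np.fromiter(dirichlet.keys(), dtype=np.int64)
    vals = np.fromiter(dirichlet.values(), dtype=float)
    if len(fixed) == 0:
        raise ValueError("singular system: no constraints supplied")
    free = np.setdiff1d(np.arange(n), fixed)
    u = np.zeros(n)
    u[fixed] = vals

    rhs = -K[free][:, fixed] @ vals
    Kff = K[free][:, free].tocsc()
    if len(free) <= 60_000:
        try:
            u[free] = spla.spsolve(Kff, rhs)
        except RuntimeError as exc:
            raise ValueError(f"singular system: {exc}") from exc
    else:
        diag = Kff.diagonal()
        if np.any(diag <= 0):
            raise ValueError("singular system: non-positive diagonal")
        M = sp.diags(1.0 / diag)
        uf, info = spla.cg(Kff, rhs, rtol=1e-10, maxiter=20_000, M=M)
        if info != 0:
            raise ValueError(f"iterative solve failed to converge (info={info})")
        u[free] = uf
    return u


def _recover_fields(system: FESystem, u: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Element stresses (Gauss average), element HMH, and nodal HMH
    (incident-element average)."""
    mesh = system.mesh
    C_bulk = system.bone.stiffness()
    insert_ids = mesh.element_sets.get("densified_insert", np.array([], dtype=int))
    C_ins = system.insert.stiffness() if (system.insert is not None
                                          and len(insert_ids) > 0) else None

    coords0 = mesh.nodes[mesh.elements[0]]
    Bs = []
    for gx in _GAUSS_1D:
        for gy in _GAUSS_1D:
            for gz in _GAUSS_1D:
                g = _shape_gradients(np.array([gx, gy, gz]))
                J = g.T @ coords0
                dN = g @ np.linalg.inv(J).T
                Bs.append(_b_matrix(dN))
    B_mean = np.mean(Bs, axis=0)  # uniform grid: same for every element

    ue = u.reshape(-1, 3)[mesh.elements].reshape(len(mesh.elements), 24)
    strain = ue @ B_mean.T
    stress = strain @ C_bulk.T
    if C_ins is not None:
        stress[insert_ids] = strain[insert_ids] @ C_ins.T
    hmh = hmh_stress(stress)

    nodal = np.zeros(mesh.n_nodes)
    counts = np.zeros(mesh.n_nodes)
    np.add.at(nodal, mesh.elements.ravel(), np.repeat(hmh, 8))
    np.add.at(counts, mesh.elements.ravel(), 1.0)
    nodal /= np.maximum(counts, 1.0)
    return stress, hmh, nodal


def standard_bcs(mesh: FEMesh, prescribed_apex_displacement: float) -> dict[int, float]:
    """Embedding boundary conditions: fixed base, symmetry-plane normal DOFs
    zero, footprint nodes driven axially downward."""
    bcs: dict[int, float] = {}
    for nid in mesh.node_sets["fixed_base"]:
        for d in range(3):
            bcs[3 * nid + d] = 0.0
    for nid in mesh.node_sets.get("symmetry_x", ()):
        bcs.setdefault(3 * nid + 0, 0.0)
    for nid in mesh.node_sets.get("symmetry_y", ()):
        bcs.setdefault(3 * nid + 1, 0.0)
    for name in mesh.footprint_sets():
        for nid in mesh.node_sets[name]:
            bcs[3 * nid + 2] = -prescribed_apex_displacement
    return bcs


def solve_embedding(system: FESystem, prescribed_apex_displacement: float,
                    dirichlet: dict[int, float] | None = None) -> FEResult:
    """Solve the embedding problem and recover stress/HMH fields and reactions.

    ``dirichlet`` overrides the standard boundary conditions when supplied
    (used e.g. for patch and bar tests).
    """
    mesh = system.mesh
    bcs = dirichlet if dirichlet is not None else standard_bcs(
        mesh, prescribed_apex_displacement)
    u = solve_linear(system, bcs)
    stress, hmh, nodal = _recover_fields(system, u)

    f = system.K @ u  # constraint (reaction) forces on Dirichlet DOFs
    reactions = {}
    for name, nids in mesh.node_sets.items():
        reactions[name] = np.array([f[3 * nids + d].sum() for d in range(3)])
    foot = 0.0
    for name in mesh.footprint_sets():
        foot += reactions[name][2]
    return FEResult(displacement=u.reshape(-1, 3), element_stress=stress,
                    hmh=hmh, nodal_hmh=nodal,
                    reaction_footprint=abs(foot), reactions=reactions,
                    embed_level=prescribed_apex_displacement)


def periapical_limit_stress(result: FEResult, mesh: FEMesh) -> float:
    """Mean over footprints of the maximum nodal HMH stress on each
    periapical contact surface."""
    maxima = []
    for name in mesh.footprint_sets():
        maxima.append(float(result.nodal_hmh[mesh.node_sets[name]].max()))
    if not maxima or max(maxima) <= 0:
        raise ValueError("zero periapical stress (degenerate load)")
    return float(np.mean(maxima))


def embedding_force(result: FEResult, mesh: FEMesh, bone: ElasticConstants,
                    symmetry_factor: float = 4.0) -> float:
    """Embedding force by the limit-stress criterion.

    The linear solution is scaled so that the mean per-footprint maximum
    periapical HMH stress equals the ultimate compressive strength sigma_c;
    the scaled footprint reaction (times the quarter-symmetry factor) is the
    force required to embed the scaffold at this level.
    """
    s_peri = periapical_limit_stress(result, mesh)
    scale = bone.sigma_c / s_peri
    return scale * result.reaction_footprint * symmetry_factor


def add_densified_insert(mesh: FEMesh, layout: ScaffoldLayout,
                         embed_depth: float, insert_thickness: float,
                         domain_height: float | None = None) -> FEMesh:
    """Tag the element layer of given thickness beneath the apex plane as the
    densified-bone insert.

    Returns a new mesh sharing nodes/elements with an added
    ``densified_insert`` element set.
    """
    if insert_thickness <= 0:
        raise ValueError("insert_thickness must be positive")
    H = domain_height if domain_height is not None else float(mesh.nodes[:, 2].max())
    z_apex = H - embed_depth
    centers_z = mesh.nodes[mesh.elements].mean(axis=1)[:, 2]
    in_layer = (centers_z < z_apex + 1e-9) & (centers_z > z_apex - insert_thickness - 1e-9)
    ids = np.flatnonzero(in_layer)
    if len(ids) == 0:
        raise ValueError("empty densified-insert element set")
    sets = dict(mesh.element_sets)
    sets["densified_insert"] = ids
    sets["bulk_bone"] = np.setdiff1d(np.arange(len(mesh.elements)), ids)
    return FEMesh(nodes=mesh.nodes, elements=mesh.elements,
                  element_size=mesh.element_size, node_sets=dict(mesh.node_sets),
                  element_sets=sets)


def mesh_convergence(domain_radius: float, domain_height: float,
                     layout: ScaffoldLayout, embed_depth: float,
                     bone: ElasticConstants, prescribed_displacement: float,
                     sizes: list[float], tol: float = 0.05) -> pd.DataFrame:
    """Refinement study: peak periapical HMH and footprint reaction per
    element size; successive relative changes below ``tol`` mark convergence.

    Failure to converge is reported in the ``converged`` column, never
    silently accepted.
    """
    if len(sizes) < 3:
        raise ValueError("need at least 3 element sizes")
    if not all(a > b for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be strictly decreasing")
    rows = []
    prev = None
    for h in sizes:
        mesh = build_mesh(domain_radius, domain_height, layout, embed_depth, h)
        system = assemble_system(mesh, bone)
        res = solve_embedding(system, prescribed_displacement)
        peak = periapical_limit_stress(res, mesh)
        reac = res.reaction_footprint
        change = abs(reac - prev) / abs(prev) if prev is not None else np.nan
        rows.append({"element_size": h, "n_elements": len(mesh.elements),
                     "reaction_N": reac, "peak_periapical_hmh_MPa": peak,
                     "rel_change": change,
                     "converged": bool(change < tol) if prev is not None else False})
        prev = reac
    return pd.DataFrame(rows)
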