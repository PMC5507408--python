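"""Voxel-based micro finite element models of segmented bone.

Every bone voxel becomes one 8-node linear hexahedral element with
homogeneous isotropic elasticity (tissue modulus ``E_t`` in GPa, Poisson
ratio ``nu``).  Dirichlet boundary conditions — all three displacement
components on the top and bottom node planes, interpolated from a DVC
displacement field — drive a linear-elastic solve; outputs are nodal
displacements, per-element centroid strains with principal values, and
reaction forces whose axial sum over the top surface is the model's
predicted axial force.

Units: lengths um, displacements um, forces N, moduli GPa (converted to
N/um^2 internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg, spsolve

from . import hexa
from .dvc import DisplacementGrid, interpolate_displacement
from .errors import ConvergenceError, OutOfDomainError, ParameterError, SegmentationError
from .segmentation import BinaryVolume

GPA_TO_N_PER_UM2 = 1e-3  # 1 GPa = 1e9 N/m^2 = 1e-3 N/um^2


@dataclass
class ElasticParams:
    """Homogeneous isotropic tissue properties: modulus (GPa) and Poisson ratio."""

    e_t: float = 12.0
    nu: float = 0.3

    def __post_init__(self):
        if not self.e_t > 0:
            raise ParameterError(f"tissue modulus must be positive, got {self.e_t}")
        if not (0.0 <= self.nu < 0.5):
            raise ParameterError(f"Poisson ratio must be in [0, 0.5), got {self.nu}")


@dataclass
class HexMesh:
    """Hexahedral mesh on the voxel-corner lattice.

    Node numbering is lexicographic in (z, y, x) over the lattice corners
    touched by at least one element; element local node order follows
    :data:`microval.hexa.CORNERS`.  ``origin_um`` places the mesh in the
    physical frame shared with the DVC grid (corner of voxel (0,0,0)).
    """

    nodes_um: np.ndarray  # (n_nodes, 3), (x, y, z) um
    elements: np.ndarray  # (n_elements, 8) node ids
    voxel_of_element: np.ndarray  # (n_elements, 3) (z, y, x) voxel indices
    element_of_voxel: np.ndarray  # full volume, -1 where no element
    voxel_size: float
    origin_um: np.ndarray = dataclass_field(default_factory=lambda: np.zeros(3))

    @property
    def n_nodes(self) -> int:
        return self.nodes_um.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def axial_extent(self) -> tuple:
        z = self.nodes_um[:, 2]
        return float(z.min()), float(z.max())


@dataclass
class BCSet:
    """Dirichlet conditions: constrained node ids and their imposed displacements (um)."""

    node_ids: np.ndarray
    values: np.ndarray  # (n_constrained, 3) um
    top_node_ids: np.ndarray  # subset on the top plane (minimum z, loading platen side)

    def __post_init__(self):
        if self.node_ids.size == 0:
            raise ParameterError("boundary condition set is empty")
        if self.values.shape != (self.node_ids.size, 3):
            raise ParameterError("boundary values must be (n_constrained, 3)")


@dataclass
class FESolution:
    """Converged nodal displacement field of the microFE model."""

    u: np.ndarray  # (n_nodes, 3) um
    iterations: int
    relative_residual: float
    stiffness: sparse.csr_matrix = dataclass_field(repr=False, default=None)


@dataclass
class StrainField:
    """Per-element centroid strains with compartment labels.

    ``eps6`` is the Voigt strain (dimensionless); ``principal`` holds the
    sorted principal strains ``e_p1 >= e_p2 >= e_p3``; ``compartment``
    carries the voxel's compartment label (0 unknown, 1 trabecular,
    2 cortical).
    """

    eps6: np.ndarray  # (n_elements, 6)
    principal: np.ndarray  # (n_elements, 3)
    compartment: np.ndarray  # (n_elements,)

    @property
    def principal_ue(self) -> np.ndarray:
        return self.principal * 1e6


@dataclass
class YieldCriteria:
    """Tissue-level yield strains for vertebral trabecular bone (microstrain)."""

    eps_p1y_ue: float = 7200.0
    eps_p3y_ue: float = -8000.0

    def __post_init__(self):
        if not (self.eps_p1y_ue > 0 > self.eps_p3y_ue):
            raise ParameterError("yield strains must satisfy eps_p1Y > 0 > eps_p3Y")


@dataclass
class ForceResult:
    """Reaction forces of the solved model.

    ``af`` is the magnitude of the summed axial reactions over the top
    surface nodes (compression reported positive); ``af_raw`` keeps the
    signed resultant.  ``equilibrium_residual`` is the vector sum of all
    constrained-node reactions, zero for a converged solve.
    """

    af: float
    af_raw: float
    reactions: np.ndarray  # (n_constrained, 3) N
    node_ids: np.ndarray
    equilibrium_residual: np.ndarray  # (3,) N


def build_mesh(bin_vol: BinaryVolume, origin_um=(0.0, 0.0, 0.0)) -> HexMesh:
    """Convert every bone voxel into an 8-node hexahedral element.

    Assumes the input has been connectivity-filtered (one face-connected
    component); raises :class:`SegmentationError` on an empty volume.
    """
    bone = bin_vol.data > 0
    if not bone.any():
        raise SegmentationError("cannot mesh an empty volume")
    h = bin_vol.voxel_size
    nz, ny, nx = bone.shape
    vox = np.argwhere(bone)  # (ne, 3) (z, y, x), lexicographic
    ne = vox.shape[0]
    # corner lattice flat ids, (ne, 8)
    corner_zyx = hexa.CORNERS[:, ::-1].astype(np.int64)  # local order, offsets (z, y, x)
    cz = vox[:, 0][:, None] + corner_zyx[:, 0]
    cy = vox[:, 1][:, None] + corner_zyx[:, 1]
    cx = vox[:, 2][:, None] + corner_zyx[:, 2]
    flat = (cz * (ny + 1) + cy) * (nx + 1) + cx
    unique = np.unique(flat)
    elements = np.searchsorted(unique, flat).astype(np.int32)
    uz = unique // ((ny + 1) * (nx + 1))
    rem = unique % ((ny + 1) * (nx + 1))
    uy = rem // (nx + 1)
    ux = rem % (nx + 1)
    origin = np.asarray(origin_um, dtype=float)
    nodes_um = np.column_stack([ux, uy, uz]).astype(float) * h + origin
    element_of_voxel = np.full(bone.shape, -1, dtype=np.int32)
    element_of_voxel[bone] = np.arange(ne, dtype=np.int32)
    return HexMesh(nodes_um, elements, vox, element_of_voxel, h, origin)


def element_stiffness(params: ElasticParams, voxel_size: float) -> np.ndarray:
    """Shared 24x24 stiffness matrix of one voxel element (units N/um).

    2x2x2 Gauss integration of the isotropic elasticity tensor over a cube
    of edge ``voxel_size``; identical for all elements (uniform cubes,
    uniform material).
    """
    return hexa.stiffness_matrix(params.e_t * GPA_TO_N_PER_UM2, params.nu, voxel_size)


def apply_boundary_conditions(mesh: HexMesh, field: DisplacementGrid) -> BCSet:
    """Constrain the top and bottom node planes to the interpolated DVC field.

    Every node on the mesh's minimum or maximum axial (z) node plane is
    constrained in all three components; interior nodes stay free.  The
    top plane (minimum z, closest to the loading platen) is recorded for
    the axial force sum.
    """
    zmin, zmax = mesh.axial_extent()
    z = mesh.nodes_um[:, 2]
    tol = 0.5 * mesh.voxel_size
    on_bottom = np.abs(z - zmax) < tol
    on_top = np.abs(z - zmin) < tol
    ids = np.flatnonzero(on_top | on_bottom)
    try:
        values = interpolate_displacement(field, mesh.nodes_um[ids])
    except OutOfDomainError as exc:
        raise OutOfDomainError(f"DVC grid does not cover boundary nodes of the mesh: {exc}") from exc
    return BCSet(ids, values, top_node_ids=np.flatnonzero(on_top))


def assemble_stiffness(mesh: HexMesh, params: ElasticParams) -> sparse.csr_matrix:
    """Assemble the global sparse stiffness matrix (N/um)."""
    Ke = element_stiffness(params, mesh.voxel_size)
    edofs = (mesh.elements.astype(np.int64)[:, :, None] * 3 + np.arange(3)).reshape(-1, 24)
    ne = mesh.n_elements
    ndof = mesh.n_nodes * 3
    rows = np.repeat(edofs, 24, axis=1).ravel()
    cols = np.tile(edofs, (1, 24)).ravel()
    vals = np.tile(Ke.ravel(), ne)
    K = sparse.coo_matrix((vals, (rows, cols)), shape=(ndof, ndof)).tocsr()
    return K


def solve(
    mesh: HexMesh,
    params: ElasticParams,
    bc: BCSet,
    tolerance: float = 1e-8,
    max_iterations: int = 20000,
    method: str = "auto",
    direct_threshold: int = 5000,
) -> FESolution:
    """Solve the constrained linear-elastic system ``K u = 0`` with Dirichlet BCs.

    Dirichlet dofs are eliminated by constraint reduction; the reduced
    system is solved directly (sparse LU) below ``direct_threshold``
    elements, otherwise by Jacobi-preconditioned conjugate gradients with
    relative residual ``tolerance``.

    Raises :class:`ConvergenceError` (with the residual history) if CG
    fails to converge within ``max_iterations``.
    """
    if not (0 < tolerance <= 1e-3):
        raise ParameterError("solver tolerance must be in (0, 1e-3]")
    K = assemble_stiffness(mesh, params)
    ndof = K.shape[0]
    fixed = np.zeros(ndof, dtype=bool)
    fixed_dofs = (bc.node_ids[:, None] * 3 + np.arange(3)).ravel()
    fixed[fixed_dofs] = True
    free = ~fixed
    u = np.zeros(ndof)
    u[fixed_dofs] = bc.values.ravel()
    f_free = -(K[:, fixed_dofs] @ bc.values.ravel())[free]
    K_ff = K[free][:, free].tocsr()

    if method == "direct" or (method == "auto" and mesh.n_elements <= direct_threshold):
        u_free = spsolve(K_ff.tocsc(), f_free)
        iterations = 1
    elif method in {"auto", "cg"}:
        diag = K_ff.diagonal()
        diag[diag == 0] = 1.0
        M = sparse.diags(1.0 / diag)
        history = []

        def callback(xk):
            history.append(float(np.linalg.norm(K_ff @ xk - f_free)))

        u_free, info = cg(K_ff, f_free, rtol=tolerance, maxiter=max_iterations, M=M, callback=callback)
        iterations = len(history)
        if info != 0:
            raise ConvergenceError(
                f"CG did not converge in {max_iterations} iterations", residual_history=history
            )
    else:
        raise ParameterError(f"unknown solver method {method!r}")

    u[free] = u_free
    fnorm = float(np.linalg.norm(f_free))
    res = float(np.linalg.norm(K_ff @ u_free - f_free)) / (fnorm if fnorm > 0 else 1.0)
    return FESolution(u.reshape(-1, 3), iterations, res, stiffness=K)


def reaction_forces(mesh: HexMesh, params: ElasticParams, bc: BCSet, sol: FESolution) -> ForceResult:
    """Nodal reactions at constrained nodes and the total axial force.

    The axial force AF is the sum of axial (z) reactions over the top
    surface nodes; compression is reported as a positive magnitude while
    the raw signed resultant is retained.
    """
    K = sol.stiffness if sol.stiffness is not None else assemble_stiffness(mesh, params)
    r = (K @ sol.u.ravel()).reshape(-1, 3)
    reactions = r[bc.node_ids]
    af_raw = float(r[bc.top_node_ids, 2].sum())
    return ForceResult(
        af=abs(af_raw),
        af_raw=af_raw,
        reactions=reactions,
        node_ids=bc.node_ids,
        equilibrium_residual=reactions.sum(axis=0),
    )


def element_strains(mesh: HexMesh, sol: FESolution, labels: np.ndarray | None = None) -> StrainField:
    """Centroid small-strain tensor and principal strains for every element."""
    B0 = hexa.centroid_b_matrix(mesh.voxel_size)
    u_e = sol.u[mesh.elements].reshape(mesh.n_elements, 24)
    eps6 = u_e @ B0.T
    principal = hexa.principal_strains(eps6)
    if labels is not None:
        compartment = labels[tuple(mesh.voxel_of_element.T)].astype(np.uint8)
    else:
        compartment = np.zeros(mesh.n_elements, dtype=np.uint8)
    return StrainField(eps6, principal, compartment)


@dataclass
class YieldSummary:
    """Shares of elements strained beyond the tissue yield limits."""

    tensile_fraction: float
    compressive_fraction: float
    overall_fraction: float
    tensile_by_compartment: dict
    compressive_by_compartment: dict


def yield_fractions(strains: StrainField, crit: YieldCriteria | None = None) -> YieldSummary:
    """Fractions of elements beyond yield, overall and split by compartment.

    The compartment split reports each label's share of the yielded
    elements (so shares sum to 1 when any element yields).
    """
    crit = crit or YieldCriteria()
    p1_ue = strains.principal[:, 0] * 1e6
    p3_ue = strains.principal[:, 2] * 1e6
    tens = p1_ue > crit.eps_p1y_ue
    comp = p3_ue < crit.eps_p3y_ue
    n = strains.principal.shape[0]

    def by_compartment(mask):
        total = int(mask.sum())
        if total == 0:
            return {}
        labels = strains.compartment[mask]
        return {int(k): int(v) / total for k, v in zip(*np.unique(labels, return_counts=True))}

    return YieldSummary(
        tensile_fraction=float(tens.mean()) if n else 0.0,
        compressive_fraction=float(comp.mean()) if n else 0.0,
        overall_fraction=float((tens | comp).mean()) if n else 0.0,
        tensile_by_compartment=by_compartment(tens),
        compressive_by_compartment=by_compartment(comp),
    )
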