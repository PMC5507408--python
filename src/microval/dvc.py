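"""Global digital volume correlation on a coarse nodal grid.

Estimates the 3D displacement field between a preloaded ("fixed") and a
loaded ("moved") volume by minimising the masked sum of squared grey-level
differences over a displacement field parameterised by trilinear
interpolation between nodes of a regular grid (nodal spacing ``NS``
voxels), plus a squared-Laplacian smoothness penalty on the nodal field:

    E(u) = sum_{x in mask} [ M(x + u(x)) - F(x) ]^2  +  lambda * ||L u||^2

Minimisation is damped Gauss-Newton (normal equations assembled
per grid cell, sparse direct solve, step halving), run coarse-to-fine
over a Gaussian scale-space of the images.  The procedure is fully
deterministic.  The derived strain field comes from trilinear shape
function derivatives of the same grid treated as an 8-noded hexahedral
mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from . import hexa
from .errors import MicrovalError, OutOfDomainError, ParameterError
from .io import GreyVolume
from .segmentation import MaskVolume


@dataclass
class GridSpec:
    """Regular measurement grid in voxel units.

    Node ``(kz, ky, kx)`` sits at voxel coordinate ``origin + k * nodal_spacing``
    per axis, i.e. at physical position ``(origin + k * NS) * voxel_size`` um
    measured from the volume corner (voxel centres are at ``(i + 0.5) * h``).
    """

    nodal_spacing: int
    node_counts: tuple  # (z, y, x)
    origin: tuple = (0.0, 0.0, 0.0)  # voxel coords (z, y, x) of node (0, 0, 0)

    def __post_init__(self):
        if self.nodal_spacing < 4:
            raise ParameterError(f"nodal spacing must be >= 4 voxels, got {self.nodal_spacing}")
        if min(self.node_counts) < 2:
            raise ParameterError("grid needs at least 2 nodes per axis")

    @classmethod
    def cover(cls, shape: tuple, nodal_spacing: int, origin: tuple = (0.0, 0.0, 0.0)) -> "GridSpec":
        """Smallest grid with the given spacing covering the full volume extent."""
        counts = tuple(
            int(np.ceil((n - o) / nodal_spacing)) + 1 for n, o in zip(shape, origin)
        )
        return cls(nodal_spacing, counts, origin)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.node_counts))

    def node_positions_vox(self):
        """Per-axis node coordinates in voxel units (z, y, x lists)."""
        return [
            self.origin[a] + np.arange(self.node_counts[a]) * self.nodal_spacing
            for a in range(3)
        ]


@dataclass
class RegistrationSettings:
    """Knobs of the Gauss-Newton DVC solver.

    ``regularization_weight`` multiplies the squared-Laplacian penalty
    (images are normalised to unit grey range and displacements are in
    voxels, so the default is transferable across inputs; it was fixed by
    the repeat-scan zero-strain protocol).  ``pyramid_levels`` Gaussian
    smoothing stages (sigma ``2**(levels-1-l) - 1`` voxels, ending at the
    raw images), ``max_iterations`` per stage, ``tolerance`` on the
    relative objective decrease.
    """

    regularization_weight: float = 0.5
    pyramid_levels: int = 3
    max_iterations: int = 30
    tolerance: float = 1e-6
    max_step_voxels: float | None = None  # default: nodal spacing / 4
    shift_search_voxels: int | None = None  # global init search radius; default: nodal spacing

    def __post_init__(self):
        if self.regularization_weight < 0:
            raise ParameterError("regularization weight must be >= 0")
        if self.pyramid_levels < 1:
            raise ParameterError("pyramid needs at least one level")


@dataclass
class DisplacementGrid:
    """Nodal displacement field measured by DVC.

    ``u`` has shape ``node_counts + (3,)`` in um with components
    ``(ux, uy, uz)``; ``convergence`` records the final objective value,
    total iteration count and any convergence warning.
    """

    grid: GridSpec
    u: np.ndarray
    voxel_size: float
    convergence: dict = dataclass_field(default_factory=dict)

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.u.shape != tuple(self.grid.node_counts) + (3,):
            raise ParameterError(
                f"nodal field shape {self.u.shape} does not match grid {self.grid.node_counts}"
            )
        if not np.all(np.isfinite(self.u)):
            raise ParameterError("nodal displacements must be finite")

    def node_positions_um(self) -> np.ndarray:
        """Physical node positions, shape ``node_counts + (3,)``, (x, y, z) um."""
        pz, py, px = [p * self.voxel_size for p in self.grid.node_positions_vox()]
        Z, Y, X = np.meshgrid(pz, py, px, indexing="ij")
        return np.stack([X, Y, Z], axis=-1)


@dataclass
class StrainGrid:
    """Per-cell small strains of the DVC grid treated as a hexahedral mesh.

    ``eps6`` is the Voigt strain ``(exx, eyy, ezz, gxy, gyz, gzx)`` at each
    cell centre (dimensionless), ``principal`` the sorted principal strains
    ``e_p1 >= e_p2 >= e_p3``.
    """

    eps6: np.ndarray  # (cz, cy, cx, 6)
    principal: np.ndarray  # (cz, cy, cx, 3)
    cell_size_um: float

    @property
    def principal_ue(self) -> np.ndarray:
        """Principal strains in microstrain."""
        return self.principal * 1e6


def _lattice_laplacian(shape: tuple) -> sparse.csr_matrix:
    """Graph Laplacian of the 6-neighbour node lattice."""
    n = int(np.prod(shape))
    idx = np.arange(n).reshape(shape)
    rows, cols = [], []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, -1)
        sl_b[axis] = slice(1, None)
        a = idx[tuple(sl_a)].ravel()
        b = idx[tuple(sl_b)].ravel()
        rows.extend([a, b])
        cols.extend([b, a])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    adj = sparse.coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n)).tocsr()
    deg = sparse.diags(np.asarray(adj.sum(axis=1)).ravel())
    return (deg - adj).tocsr()


_CORNERS_ZYX = [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]


class _GridProblem:
    """Precomputed geometry shared by all Gauss-Newton iterations."""

    def __init__(self, shape, grid: GridSpec, mask: np.ndarray):
        self.shape = shape
        self.grid = grid
        ns = float(grid.nodal_spacing)
        gz, gy, gx = grid.node_counts
        oz, oy, ox = grid.origin
        # basis coordinates of every voxel centre, in grid cells
        self.gc = [
            (np.arange(shape[0]) + 0.5 - oz) / ns,
            (np.arange(shape[1]) + 0.5 - oy) / ns,
            (np.arange(shape[2]) + 0.5 - ox) / ns,
        ]
        zi, yi, xi = np.nonzero(mask)
        self.n_masked = zi.size
        t = [self.gc[0][zi], self.gc[1][yi], self.gc[2][xi]]
        self.cell = []
        self.frac = []
        for a, (tc, g) in enumerate(zip(t, (gz, gy, gx))):
            c = np.clip(np.floor(tc).astype(np.int64), 0, g - 2)
            self.cell.append(c)
            self.frac.append(tc - c)
        cgz, cgy, cgx = gz - 1, gy - 1, gx - 1
        self.n_cells = cgz * cgy * cgx
        self.cell_id = (self.cell[0] * cgy + self.cell[1]) * cgx + self.cell[2]
        # per-cell corner node flat ids
        cz, cy, cx = np.meshgrid(np.arange(cgz), np.arange(cgy), np.arange(cgx), indexing="ij")
        cz, cy, cx = cz.ravel(), cy.ravel(), cx.ravel()
        self.cell_corner_nid = [
            ((cz + a) * gy + (cy + b)) * gx + (cx + c) for (a, b, c) in _CORNERS_ZYX
        ]
        # per-voxel corner weights and node ids
        wz, wy, wx = self.frac
        self.W = []
        self.vox_nid = []
        for (a, b, c) in _CORNERS_ZYX:
            w = (wz if a else 1.0 - wz) * (wy if b else 1.0 - wy) * (wx if c else 1.0 - wx)
            self.W.append(w)
            self.vox_nid.append(
                ((self.cell[0] + a) * gy + (self.cell[1] + b)) * gx + (self.cell[2] + c)
            )
        self.mask_index = (zi, yi, xi)
        self.ndof = grid.n_nodes * 3


def _dense_displacement(u_nodes_vox: np.ndarray, prob: _GridProblem) -> list:
    """Trilinear upsampling of the nodal field to every voxel (full volume)."""
    coords = np.meshgrid(*prob.gc, indexing="ij")
    coords = [np.clip(c, 0, n - 1) for c, n in zip(coords, u_nodes_vox.shape[:3])]
    return [
        ndimage.map_coordinates(u_nodes_vox[..., comp], coords, order=1, mode="nearest")
        for comp in range(3)
    ]


def register(
    fixed: GreyVolume,
    moved: GreyVolume,
    mask: MaskVolume,
    grid: GridSpec,
    settings: RegistrationSettings | None = None,
) -> DisplacementGrid:
    """Recover the nodal displacement field mapping ``fixed`` onto ``moved``.

    The nodal field ``u`` is defined by ``moved(x) ~= fixed(x - u(x))``:
    the material seen at position ``x`` in the loaded image sits at
    ``x - u(x)`` in the preloaded image, so ``u`` is the displacement that
    carried it there.  The optimiser back-warps the fixed image by the
    candidate field and matches it to the moved image; this is the same
    inverse-mapping convention :func:`microval.phantom.warp_volume` uses,
    so an imposed synthetic field is recovered without convention skew.
    For the small strains of a preload-to-load step this coincides with
    the material displacement field to first order.  Returns um.

    Nodes whose surrounding cells contain no masked voxel carry no image
    information; their values are filled by harmonic (Laplacian) extension
    of the measured nodes and flagged in ``convergence['node_support']``.

    Raises :class:`MicrovalError` on an empty mask or mismatched shapes;
    a failure to decrease the objective attaches a convergence warning to
    the result instead of raising.
    """
    settings = settings or RegistrationSettings()
    if fixed.shape != moved.shape or fixed.shape != mask.shape:
        raise ParameterError("fixed, moved and mask must share dimensions")
    if int(mask.data.sum()) == 0:
        raise MicrovalError("mask is empty")
    # grid must cover the volume extent
    for a in range(3):
        top = grid.origin[a] + (grid.node_counts[a] - 1) * grid.nodal_spacing
        if grid.origin[a] > 0 or top < fixed.shape[a]:
            raise ParameterError(f"grid does not cover the volume along axis {a}")

    F = fixed.data.astype(np.float64)
    M = moved.data.astype(np.float64)
    m = mask.data.astype(bool)
    lo, hi = F[m].min(), F[m].max()
    scale = hi - lo if hi > lo else 1.0
    F = (F - lo) / scale
    M = (M - lo) / scale

    prob = _GridProblem(fixed.shape, grid, m)
    lam = settings.regularization_weight
    L = _lattice_laplacian(grid.node_counts)
    LtL = (L.T @ L).tocsr()
    LtL_dof = sparse.kron(LtL, sparse.eye(3), format="csr")

    u = np.zeros(tuple(grid.node_counts) + (3,))  # voxel units, comps (z, y, x)
    # global integer-shift initialisation by masked cross-correlation:
    # anchors the solve in the correct basin even when the texture is
    # (quasi-)periodic or the structure is extruded along an axis
    radius = settings.shift_search_voxels
    if radius is None:
        radius = grid.nodal_spacing
    if radius > 0:
        u += _global_shift(F * m, M * m, radius)
    total_iters = 0
    warning = None
    obj = np.inf

    nz, ny, nx = fixed.shape
    base_coords = np.meshgrid(
        np.arange(nz, dtype=float), np.arange(ny, dtype=float), np.arange(nx, dtype=float),
        indexing="ij",
    )

    def evaluate(u_nodes, Fs, Ms):
        dense = _dense_displacement(u_nodes, prob)
        warped = [base_coords[c] - dense[c] for c in range(3)]
        Fw = ndimage.map_coordinates(Fs, warped, order=1, mode="nearest")
        # voxels back-warped outside the fixed image see clamped values:
        # they stay in the objective (so leaving the domain is penalised,
        # not rewarded) but carry no usable derivative information, so
        # they are masked out of the Jacobian via ``support``
        support = np.ones(prob.n_masked)
        for c, n in zip(range(3), fixed.shape):
            wc = warped[c][m]
            support *= (wc >= 0.0) & (wc <= n - 1.0)
        r = (Fw - Ms)[m]
        reg = lam * float(np.sum((L @ u_nodes.reshape(-1, 3)) ** 2))
        return float(r @ r) + reg, r, warped, support

    sigmas = [2.0 ** (settings.pyramid_levels - 1 - l) - 1.0 for l in range(settings.pyramid_levels)]
    for sigma in sigmas:
        if sigma > 0:
            F_s = ndimage.gaussian_filter(F, sigma)
            M_s = ndimage.gaussian_filter(M, sigma)
        else:
            F_s, M_s = F, M
        grads = np.gradient(F_s)
        obj, r, warped, support = evaluate(u, F_s, M_s)
        accepted_any = False
        for _ in range(settings.max_iterations):
            total_iters += 1
            # d r / d u_(node,c) = -dF/dx_c (x - u) * N_node(x)
            G = [
                ndimage.map_coordinates(grads[c], warped, order=1, mode="nearest")[m] * support
                for c in range(3)
            ]
            A = _assemble_normal_matrix(prob, G)
            b = _assemble_gradient(prob, G, r)
            if lam > 0:
                A = A + lam * LtL_dof
                b = b - lam * (LtL_dof @ u.ravel())
            ridge = 1e-8 * (A.diagonal().mean() + 1.0)
            A = A + ridge * sparse.eye(prob.ndof, format="csr")
            delta = spsolve(A.tocsc(), b).reshape(u.shape)
            # trust region: cap the nodal update so poorly-conditioned
            # directions (blurred level, periodic texture) cannot jump
            # into an alias basin far from the current estimate
            cap = settings.max_step_voxels or grid.nodal_spacing / 4.0
            dmax = float(np.abs(delta).max())
            if dmax > cap:
                delta *= cap / dmax
            # damped step: halve until the objective decreases
            step, accepted = 1.0, False
            for _ in range(8):
                cand = u + step * delta
                cand_obj, cand_r, cand_warped, cand_support = evaluate(cand, F_s, M_s)
                if cand_obj < obj:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                # stalling after progress is ordinary convergence to the
                # noise/discretisation floor; flag only final-level solves
                # where no step could be taken at all
                if sigma == sigmas[-1] and not accepted_any and obj > 1e-10 * max(prob.n_masked, 1):
                    warning = "no descent step accepted at the finest level"
                break
            rel = (obj - cand_obj) / max(obj, 1e-300)
            accepted_any = True
            u, obj, r, warped, support = cand, cand_obj, cand_r, cand_warped, cand_support
            if rel < settings.tolerance:
                break

    # per-node data weight: accumulated basis weight of masked voxels,
    # as a fraction of a fully-embedded node's weight (one cell volume).
    # Nodes below half a cell of support are not reliable measurements;
    # their values are replaced by harmonic extension of the measured
    # field (the same role the specimen mask plays in grid DVC tools)
    node_weight = np.zeros(grid.n_nodes)
    for k in range(8):
        node_weight += np.bincount(prob.vox_nid[k], weights=prob.W[k], minlength=grid.n_nodes)
    weight_frac = node_weight / float(grid.nodal_spacing**3)
    supported = weight_frac >= 0.5
    if supported.any() and not supported.all():
        u = _harmonic_extension(u, supported, L)

    u_um = u[..., ::-1] * fixed.voxel_size  # (z,y,x) -> (x,y,z) components, um
    convergence = {
        "objective": obj,
        "iterations": total_iters,
        "warning": warning,
        "node_support": supported.reshape(grid.node_counts),
        "node_weight": weight_frac.reshape(grid.node_counts),
    }
    return DisplacementGrid(grid, u_um, fixed.voxel_size, convergence)


def _harmonic_extension(u: np.ndarray, supported: np.ndarray, L: sparse.csr_matrix) -> np.ndarray:
    """Fill unsupported nodes by minimising ``||L u||^2`` with measured nodes fixed."""
    LtL = (L.T @ L).tocsr()
    free = ~supported
    A = LtL[free][:, free].tocsc()
    out = u.reshape(-1, 3).copy()
    rhs = -LtL[free][:, supported] @ out[supported]
    out[free] = spsolve(A + 1e-12 * sparse.eye(A.shape[0], format="csc"), rhs)
    return out.reshape(u.shape)


def _global_shift(A: np.ndarray, B: np.ndarray, radius: int) -> np.ndarray:
    """Integer lag maximising the circular cross-correlation of B against A.

    Returns the (z, y, x) shift, searched within ``+-radius`` voxels per
    axis; with ``B(x) ~= A(x - s)`` the returned lag is ``s``.
    """
    corr = np.fft.irfftn(np.fft.rfftn(B) * np.conj(np.fft.rfftn(A)), s=A.shape)
    best, best_val = np.zeros(3), -np.inf
    lags = [np.arange(-min(radius, n - 1), min(radius, n - 1) + 1) for n in A.shape]
    for lz in lags[0]:
        for ly in lags[1]:
            vals = corr[lz, ly, lags[2]]
            k = int(np.argmax(vals))
            if vals[k] > best_val:
                best_val = float(vals[k])
                best = np.array([lz, ly, lags[2][k]], dtype=float)
    return best


def _assemble_normal_matrix(prob: _GridProblem, G: list) -> sparse.csr_matrix:
    """Gauss-Newton normal matrix J^T J, accumulated per grid cell."""
    rows, cols, vals = [], [], []
    for k1 in range(8):
        for k2 in range(k1, 8):
            ww = prob.W[k1] * prob.W[k2]
            for c1 in range(3):
                for c2 in range(3):
                    if k1 == k2 and c2 < c1:
                        continue
                    v = np.bincount(prob.cell_id, weights=ww * G[c1] * G[c2], minlength=prob.n_cells)
                    ga = prob.cell_corner_nid[k1] * 3 + c1
                    gb = prob.cell_corner_nid[k2] * 3 + c2
                    rows.append(ga)
                    cols.append(gb)
                    vals.append(v)
                    if not (k1 == k2 and c1 == c2):
                        rows.append(gb)
                        cols.append(ga)
                        vals.append(v)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return sparse.coo_matrix((vals, (rows, cols)), shape=(prob.ndof, prob.ndof)).tocsr()


def _assemble_gradient(prob: _GridProblem, G: list, r: np.ndarray) -> np.ndarray:
    """Right-hand side ``-J^T r`` of the Gauss-Newton system.

    The Jacobian entry for (node, component) is ``-G_c * N_node`` (the
    residual back-warps the fixed image), so ``-J^T r`` accumulates with a
    plus sign.
    """
    b = np.zeros(prob.ndof)
    for k in range(8):
        for c in range(3):
            dof = prob.vox_nid[k] * 3 + c
            b += np.bincount(dof, weights=prob.W[k] * G[c] * r, minlength=prob.ndof)
    return b


def interpolate_displacement(field: DisplacementGrid, points_xyz: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the nodal field at physical points (um).

    ``points_xyz`` has shape (N, 3), ordered (x, y, z).  Points outside the
    grid's cell coverage raise :class:`OutOfDomainError` (no extrapolation).
    Affine nodal fields are reproduced exactly.
    """
    pts = np.atleast_2d(np.asarray(points_xyz, dtype=float))
    h = field.voxel_size
    ns = field.grid.nodal_spacing
    coords = []
    tol = 1e-9
    for a in range(3):  # grid axes z, y, x
        p = pts[:, 2 - a]  # physical component matching the axis
        c = (p / h - field.grid.origin[a]) / ns
        top = field.grid.node_counts[a] - 1
        if np.any(c < -tol) or np.any(c > top + tol):
            raise OutOfDomainError(
                f"point(s) outside the DVC grid along axis {a} (range 0..{top} cells)"
            )
        coords.append(np.clip(c, 0.0, top))
    coords = np.stack(coords)
    out = np.empty((pts.shape[0], 3))
    for comp in range(3):
        out[:, comp] = ndimage.map_coordinates(field.u[..., comp], coords, order=1, mode="nearest")
    return out


def grid_strain(field: DisplacementGrid) -> StrainGrid:
    """Cell-centre small strains of the DVC grid.

    Each grid cell is treated as an 8-noded hexahedral element of edge
    ``NS * voxel_size``; strains come from trilinear shape-function
    derivatives evaluated at the cell centre, principal strains from
    symmetric eigendecomposition (sorted descending).
    """
    gz, gy, gx = field.grid.node_counts
    if min(gz, gy, gx) < 2:
        raise ParameterError("grid strain needs at least 2 nodes per axis")
    cell_h = field.grid.nodal_spacing * field.voxel_size
    B0 = hexa.centroid_b_matrix(cell_h)
    cz, cy, cx = gz - 1, gy - 1, gx - 1
    # gather the 24-dof vector of each cell in the element's local order
    u_cells = np.empty((cz, cy, cx, 24))
    for a, (ox, oy, oz) in enumerate(hexa.CORNERS.astype(int)):
        block = field.u[oz : oz + cz, oy : oy + cy, ox : ox + cx, :]
        u_cells[..., 3 * a : 3 * a + 3] = block
    eps6 = u_cells @ B0.T  # (cz, cy, cx, 6), dimensionless (um / um)
    principal = hexa.principal_strains(eps6)
    return StrainGrid(eps6, principal, cell_h)


@dataclass
class PrecisionReport:
    """Random errors from a repeat-scan (zero-strain) registration."""

    displacement_std_um: np.ndarray  # per component (x, y, z)
    displacement_random_error_um: float
    strain_std_ue: np.ndarray  # per Voigt component
    strain_random_error_ue: float
    convergence: dict


def zero_strain_check(
    fixed: GreyVolume,
    repeat: GreyVolume,
    mask: MaskVolume,
    grid: GridSpec,
    settings: RegistrationSettings | None = None,
) -> PrecisionReport:
    """Register two renderings of the same geometry and report random errors.

    With no real deformation between the inputs, any measured displacement
    or strain is error; the report gives standard deviations of nodal
    displacements (um) and of cell strains (microstrain).
    """
    field = register(fixed, repeat, mask, grid, settings)
    disp_std = field.u.reshape(-1, 3).std(axis=0)
    strains = grid_strain(field)
    strain_std = strains.eps6.reshape(-1, 6).std(axis=0) * 1e6
    return PrecisionReport(
        displacement_std_um=disp_std,
        displacement_random_error_um=float(disp_std.mean()),
        strain_std_ue=strain_std,
        strain_random_error_ue=float(strain_std.mean()),
        convergence=field.convergence,
    )
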