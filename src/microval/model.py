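"""Model/Results interface over the registration and finite-element engines.

Two model classes mirror the fit/results idiom of statistical modelling
packages: :class:`DVCModel` wraps grid-based digital volume correlation of
an image pair, :class:`MicroFEModel` wraps the voxel hexahedral elasticity
solve.  Both return results objects that carry the estimates together
with convergence diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from . import dvc as _dvc
from . import fe as _fe
from .errors import ParameterError
from .segmentation import BinaryVolume


class DVCModel:
    """Digital volume correlation of a preloaded/loaded volume pair.

    Parameters
    ----------
    fixed, moved : GreyVolume
        Preloaded and loaded images (same dimensions and voxel size).
    mask : MaskVolume
        Specimen mask; only masked voxels drive the match.
    nodal_spacing : int
        Grid nodal spacing NS in voxels (default 48, ~1.9 mm at 39 um).
    grid : GridSpec, optional
        Explicit grid; overrides ``nodal_spacing``.
    settings : RegistrationSettings, optional
    """

    def __init__(self, fixed, moved, mask, nodal_spacing: int = 48, grid=None, settings=None):
        self.fixed = fixed
        self.moved = moved
        self.mask = mask
        self.grid = grid or _dvc.GridSpec.cover(fixed.shape, nodal_spacing)
        self.settings = settings or _dvc.RegistrationSettings()

    def fit(self) -> "DVCResults":
        field = _dvc.register(self.fixed, self.moved, self.mask, self.grid, self.settings)
        return DVCResults(self, field)


@dataclass
class DVCResults:
    """Fitted nodal displacement field with diagnostics."""

    model: DVCModel
    field: _dvc.DisplacementGrid

    @property
    def u(self) -> np.ndarray:
        return self.field.u

    def strain(self) -> _dvc.StrainGrid:
        return _dvc.grid_strain(self.field)

    def interpolate(self, points_xyz: np.ndarray) -> np.ndarray:
        return _dvc.interpolate_displacement(self.field, points_xyz)

    def summary(self) -> str:
        conv = self.field.convergence
        u = self.field.u.reshape(-1, 3)
        sup = conv.get("node_support")
        lines = [
            "DVC registration results",
            "========================",
            f"grid nodes            : {self.field.grid.node_counts} (NS = {self.field.grid.nodal_spacing} voxels)",
            f"supported nodes       : {int(sup.sum())}/{sup.size}" if sup is not None else "",
            f"iterations            : {conv.get('iterations')}",
            f"final objective       : {conv.get('objective'):.6g}",
            f"mean |u| (um)         : {np.linalg.norm(u, axis=1).mean():.3f}",
            f"u range per comp (um) : x [{u[:,0].min():.2f}, {u[:,0].max():.2f}]"
            f" y [{u[:,1].min():.2f}, {u[:,1].max():.2f}]"
            f" z [{u[:,2].min():.2f}, {u[:,2].max():.2f}]",
        ]
        if conv.get("warning"):
            lines.append(f"warning               : {conv['warning']}")
        return "\n".join(l for l in lines if l)


class MicroFEModel:
    """Voxel hexahedral linear-elastic model of a segmented bone volume.

    Built from a connectivity-filtered :class:`BinaryVolume`; every bone
    voxel becomes one element with homogeneous isotropic properties.
    ``fit`` applies Dirichlet boundary conditions (from a DVC displacement
    grid or an explicit :class:`~microval.fe.BCSet`) and solves.
    """

    def __init__(self, bin_vol: BinaryVolume, params: _fe.ElasticParams | None = None,
                 labels: np.ndarray | None = None, origin_um=(0.0, 0.0, 0.0)):
        self.params = params or _fe.ElasticParams()
        self.labels = labels
        self.mesh = _fe.build_mesh(bin_vol, origin_um)

    @property
    def n_elements(self) -> int:
        return self.mesh.n_elements

    def boundary_conditions(self, field: _dvc.DisplacementGrid) -> _fe.BCSet:
        return _fe.apply_boundary_conditions(self.mesh, field)

    def fit(self, bc, tolerance: float = 1e-8, method: str = "auto") -> "MicroFEResults":
        if isinstance(bc, _dvc.DisplacementGrid):
            bc = self.boundary_conditions(bc)
        elif not isinstance(bc, _fe.BCSet):
            raise ParameterError("fit expects a DisplacementGrid or a BCSet")
        sol = _fe.solve(self.mesh, self.params, bc, tolerance=tolerance, method=method)
        forces = _fe.reaction_forces(self.mesh, self.params, bc, sol)
        return MicroFEResults(self, bc, sol, forces)


@dataclass
class MicroFEResults:
    """Solved microFE model: displacements, reactions, strains.

    The displacement field of a Dirichlet-driven homogeneous model does
    not depend on the tissue modulus, and reaction forces are exactly
    proportional to it; :meth:`axial_force_at` rescales accordingly.
    """

    model: MicroFEModel
    bc: _fe.BCSet
    solution: _fe.FESolution
    forces: _fe.ForceResult
    _strains: _fe.StrainField | None = dataclass_field(default=None, repr=False)

    @property
    def u(self) -> np.ndarray:
        return self.solution.u

    @property
    def axial_force(self) -> float:
        return self.forces.af

    def axial_force_at(self, e_t: float) -> float:
        """Axial force rescaled to another tissue modulus (exact linearity)."""
        return self.forces.af * e_t / self.model.params.e_t

    def strains(self) -> _fe.StrainField:
        if self._strains is None:
            self._strains = _fe.element_strains(self.model.mesh, self.solution, self.model.labels)
        return self._strains

    def yield_fractions(self, criteria: _fe.YieldCriteria | None = None) -> _fe.YieldSummary:
        return _fe.yield_fractions(self.strains(), criteria)

    def summary(self) -> str:
        mesh = self.model.mesh
        ys = self.yield_fractions()
        eq = np.abs(self.forces.equilibrium_residual).max()
        return "\n".join(
            [
                "MicroFE model results",
                "=====================",
                f"elements / nodes      : {mesh.n_elements} / {mesh.n_nodes}",
                f"tissue modulus (GPa)  : {self.model.params.e_t}   Poisson: {self.model.params.nu}",
                f"constrained nodes     : {self.bc.node_ids.size}",
                f"solver iterations     : {self.solution.iterations}"
                f"   rel. residual: {self.solution.relative_residual:.2e}",
                f"axial force AF (N)    : {self.forces.af:.2f} (signed {self.forces.af_raw:+.2f})",
                f"equilibrium |sum R|   : {eq:.3e} N",
                f"yielded elements      : {100 * ys.compressive_fraction:.2f}% compressive,"
                f" {100 * ys.tensile_fraction:.2f}% tensile",
            ]
        )
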