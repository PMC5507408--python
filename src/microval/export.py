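"""Serialisation of meshes, fields and tables to portable text formats.

Meshes and per-element results go to legacy ASCII VTK (readable by
ParaView and meshio); displacement grids round-trip through CSV with a
small header so a solve can be re-run from persisted intermediates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dvc import DisplacementGrid, GridSpec
from .errors import ParseError
from .fe import HexMesh, StrainField


def mesh_to_vtk(mesh: HexMesh, path, strains: StrainField | None = None) -> None:
    """Write the hexahedral mesh (and optional per-element principal strains)
    as a legacy ASCII VTK unstructured grid."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n_nodes, n_elem = mesh.n_nodes, mesh.n_elements
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nmicroval voxel mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {n_nodes} float\n")
        np.savetxt(f, mesh.nodes_um, fmt="%.6g")
        f.write(f"CELLS {n_elem} {n_elem * 9}\n")
        cells = np.column_stack([np.full(n_elem, 8, dtype=np.int64), mesh.elements])
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {n_elem}\n")
        np.savetxt(f, np.full(n_elem, 12, dtype=np.int64), fmt="%d")  # VTK_HEXAHEDRON
        if strains is not None:
            f.write(f"CELL_DATA {n_elem}\n")
            for name, col in (("eps_p1", 0), ("eps_p3", 2)):
                f.write(f"SCALARS {name}_ue float 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, strains.principal[:, col] * 1e6, fmt="%.6g")
            f.write("SCALARS compartment int 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, strains.compartment, fmt="%d")


def displacement_grid_to_csv(field: DisplacementGrid, path) -> None:
    """Serialise a displacement grid: header comments + one row per node."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    grid = field.grid
    pos = field.node_positions_um().reshape(-1, 3)
    u = field.u.reshape(-1, 3)
    with open(path, "w") as f:
        f.write(f"# nodal_spacing={grid.nodal_spacing}\n")
        f.write(f"# node_counts={grid.node_counts[0]},{grid.node_counts[1]},{grid.node_counts[2]}\n")
        f.write(f"# origin={grid.origin[0]},{grid.origin[1]},{grid.origin[2]}\n")
        f.write(f"# voxel_size_um={field.voxel_size}\n")
        df = pd.DataFrame(
            {
                "node_id": np.arange(pos.shape[0]),
                "x_um": pos[:, 0], "y_um": pos[:, 1], "z_um": pos[:, 2],
                "ux_um": u[:, 0], "uy_um": u[:, 1], "uz_um": u[:, 2],
            }
        )
        df.to_csv(f, index=False)


def displacement_grid_from_csv(path) -> DisplacementGrid:
    """Read a displacement grid written by :func:`displacement_grid_to_csv`."""
    meta = {}
    with open(path) as f:
        for line in f:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val
    try:
        counts = tuple(int(v) for v in meta["node_counts"].split(","))
        origin = tuple(float(v) for v in meta["origin"].split(","))
        grid = GridSpec(int(meta["nodal_spacing"]), counts, origin)
        voxel = float(meta["voxel_size_um"])
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path}: missing or malformed grid header") from exc
    df = pd.read_csv(path, comment="#")
    u = df[["ux_um", "uy_um", "uz_um"]].to_numpy().reshape(counts + (3,))
    return DisplacementGrid(grid, u, voxel)
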