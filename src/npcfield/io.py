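"""Volumetric and tabular output helpers.

Density and propagator fields on the Cartesian grid can be written as
legacy ASCII VTK structured points for inspection in ParaView; the
axisymmetric grid exports its (r, z) field as CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .grids import AxisymmetricGrid, Grid3D


def write_vtk_structured(grid: Grid3D, values: np.ndarray, path,
                         name: str = "field") -> None:
    """Legacy ASCII VTK STRUCTURED_POINTS file of a nodal field (solid
    nodes written as 0)."""
    arr = grid.full_array(values)
    nx, ny, nz = arr.shape
    origin = [a[0] for a in grid.axes]
    sp = [a[1] - a[0] for a in grid.axes]
    lines = [
        "# vtk DataFile Version 3.0",
        name,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {origin[0]} {origin[1]} {origin[2]}",
        f"SPACING {sp[0]} {sp[1]} {sp[2]}",
        f"POINT_DATA {nx * ny * nz}",
        f"SCALARS {name} float 1",
        "LOOKUP_TABLE default",
    ]
    flat = arr.transpose(2, 1, 0).ravel()  # VTK x-fastest ordering
    lines += [" ".join(f"{v:.6g}" for v in flat[i:i + 9])
              for i in range(0, flat.size, 9)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_axisym_csv(grid: AxisymmetricGrid, values: np.ndarray, path,
                     name: str = "field") -> None:
    pd.DataFrame({
        "r_nm": grid.points[:, 0],
        "z_nm": grid.points[:, 2],
        name: values,
    }).to_csv(path, index=False)


def write_field(grid, values, path, name: str = "field") -> None:
    if isinstance(grid, Grid3D):
        write_vtk_structured(grid, values, path, name)
    else:
        write_axisym_csv(grid, values, path, name)


def write_spots_csv(spots, path) -> None:
    """Binding-spot export: one row per surface vertex with a spot flag."""
    is_spot = np.zeros(spots.n_all, dtype=bool)
    is_spot[spots.spot_indices] = True
    pd.DataFrame({
        "vertex_id": np.arange(spots.n_all),
        "x_nm": spots.vertices[:, 0],
        "y_nm": spots.vertices[:, 1],
        "z_nm": spots.vertices[:, 2],
        "is_spot": is_spot,
    }).to_csv(path, index=False)
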