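"""Minimal legacy-ASCII VTK writer for uniform 2D grids.

Writes STRUCTURED_POINTS datasets with cell data, which is all the
package needs to hand rasterized masks and flow fields to ParaView/VisIt.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_structured_points"]


def write_structured_points(path, fields, spacing_mm, origin_mm=(0.0, 0.0)):
    """Write 2D cell-centered fields as a legacy VTK STRUCTURED_POINTS file.

    Parameters
    ----------
    path : str or Path
        Output file name (conventionally ``.vtk``).
    fields : dict[str, ndarray]
        Name -> 2D array of shape (ny, nx); all arrays must share a shape.
        Integer arrays are written as ``int``, everything else as ``float``.
    spacing_mm : float
        Uniform cell size in mm.
    origin_mm : (float, float)
        Lower-left corner of the grid in mm.
    """
    if not fields:
        raise ValueError("no fields to write")
    shapes = {np.asarray(a).shape for a in fields.values()}
    if len(shapes) != 1:
        raise ValueError(f"field shapes differ: {shapes}")
    ny, nx = shapes.pop()
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("stentflow field export\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        # cell data on an (nx, ny) grid needs (nx+1, ny+1) points
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} 1\n")
        fh.write(f"ORIGIN {origin_mm[0]} {origin_mm[1]} 0\n")
        fh.write(f"SPACING {spacing_mm} {spacing_mm} {spacing_mm}\n")
        fh.write(f"CELL_DATA {nx * ny}\n")
        for name, arr in fields.items():
            a = np.asarray(arr)
            kind = "int" if np.issubdtype(a.dtype, np.integer) else "float"
            fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
            flat = a.ravel(order="C")  # row-major: x fastest within a row
            if kind == "int":
                body = "\n".join(str(int(v)) for v in flat)
            else:
                body = "\n".join(f"{float(v):.9g}" for v in flat)
            fh.write(body + "\n")
    return path
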