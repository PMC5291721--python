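"""Minimal legacy-VTK (ASCII) writer for triangle meshes.

Writes DataSet UNSTRUCTURED_GRID files with triangle cells plus nodal and
per-element scalar/vector fields — enough for ParaView time-series
inspection of runs.
"""

from __future__ import annotations

import numpy as np

from .mesh import TriMesh


def _write_fields(fh, data: dict, n: int, kind: str) -> None:
    fh.write(f"{kind} {n}\n")
    for name, values in data.items():
        arr = np.asarray(values, dtype=float)
        if arr.ndim == 1:
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for v in arr:
                fh.write(f"{v:.9g}\n")
        else:
            fh.write(f"VECTORS {name} double\n")
            for v in arr:
                fh.write(f"{v[0]:.9g} {v[1]:.9g} 0\n")


def write_vtk(path, mesh: TriMesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfasim snapshot\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} 0\n")
        m = mesh.n_triangles
        fh.write(f"CELLS {m} {4 * m}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.write("\n".join(["5"] * m) + "\n")
        if point_data:
            _write_fields(fh, point_data, mesh.n_nodes, "POINT_DATA")
        if cell_data:
            _write_fields(fh, cell_data, m, "CELL_DATA")
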