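"""Minimal legacy-ASCII VTK unstructured-grid I/O for quad meshes.

Writes nodes, 4-node quad cells and per-cell scalar fields so meshes and
strain fields can be inspected in ParaView or any VTK viewer.  Only the
subset of the legacy format this package produces is read back.
"""

from __future__ import annotations

import numpy as np

from .geometry import Mesh

VTK_QUAD = 9


def write_vtk(path, mesh: Mesh, cell_fields: dict[str, np.ndarray] | None = None,
              title: str = "sulcalstrain mesh") -> None:
    cell_fields = cell_fields or {}
    nodes3 = np.column_stack([mesh.nodes, np.zeros(mesh.n_nodes)])
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, nodes3, fmt="%.9g")
        m = mesh.n_elements
        fh.write(f"CELLS {m} {m * 5}\n")
        cells = np.column_stack([np.full(m, 4), mesh.elements])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {m}\n")
        np.savetxt(fh, np.full(m, VTK_QUAD), fmt="%d")
        fh.write(f"CELL_DATA {m}\n")
        mat = (mesh.material == "csf").astype(int)
        _write_scalars(fh, "material", mat, "int")
        for name, arr in cell_fields.items():
            arr = np.asarray(arr)
            kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
            _write_scalars(fh, name, arr, kind)


def _write_scalars(fh, name: str, arr: np.ndarray, kind: str) -> None:
    fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
    fmt = "%d" if kind == "int" else "%.9g"
    np.savetxt(fh, np.asarray(arr).ravel(), fmt=fmt)


def read_vtk(path) -> tuple[Mesh, dict[str, np.ndarray]]:
    """Read back a file produced by :func:`write_vtk`."""
    with open(path) as fh:
        tokens = fh.read().split("\n")
    idx = 0

    def seek(prefix: str) -> list[str]:
        nonlocal idx
        while idx < len(tokens):
            line = tokens[idx].strip()
            idx += 1
            if line.startswith(prefix):
                return line.split()
        raise ValueError(f"malformed VTK file: missing {prefix!r} section")

    hdr = seek("POINTS")
    n_pts = int(hdr[1])
    pts = np.array(" ".join(tokens[idx:idx + n_pts]).split(), dtype=float)
    pts = pts.reshape(n_pts, 3)[:, :2]
    idx += n_pts

    hdr = seek("CELLS")
    n_cells = int(hdr[1])
    raw = np.array(" ".join(tokens[idx:idx + n_cells]).split(), dtype=int)
    raw = raw.reshape(n_cells, 5)
    if not np.all(raw[:, 0] == 4):
        raise ValueError("only 4-node quad cells are supported")
    elements = raw[:, 1:]
    idx += n_cells
    seek("CELL_TYPES")
    idx += n_cells

    fields: dict[str, np.ndarray] = {}
    seek("CELL_DATA")
    while True:
        try:
            hdr = seek("SCALARS")
        except ValueError:
            break
        name, kind = hdr[1], hdr[2]
        idx += 1  # LOOKUP_TABLE line
        vals = np.array(" ".join(tokens[idx:idx + n_cells]).split(),
                        dtype=int if kind == "int" else float)
        fields[name] = vals
        idx += n_cells

    material = np.where(fields.pop("material", np.zeros(n_cells, int)) == 1,
                        "csf", "brain")
    # skull nodes are not stored in VTK; recover as outermost-radius ring
    r = np.hypot(pts[:, 0], pts[:, 1])
    skull = np.flatnonzero(np.isclose(r, r.max(), rtol=1e-9, atol=1e-12))
    mesh = Mesh(nodes=pts, elements=elements, material=material,
                skull_nodes=skull)
    return mesh, fields
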