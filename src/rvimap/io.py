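"""File interchange: legacy-ASCII VTK meshes, HDF5 structured grids.

Unstructured meshes travel as legacy VTK (the line-oriented ASCII
``UNSTRUCTURED_GRID`` dialect) with region labels in an integer
point-data array named ``region``. Structured grids are serialised to
HDF5 with their spacing and label arrays. Marker and RVI CSVs live with
their owning classes (:class:`rvimap.markers.MarkerMap`,
:class:`rvimap.rvi.RVIMap`).
"""

from __future__ import annotations

import json

import numpy as np

from .geometry import TissueModel
from .regions import Region

__all__ = [
    "write_vtk",
    "read_vtk",
    "save_model_h5",
    "load_model_h5",
    "write_summary_json",
]

_VTK_CELL_TYPES = {
    "triangle": (5, 3),
    "quad": (9, 4),
    "tetra": (10, 4),
    "hexahedron": (12, 8),
}
_VTK_TYPE_NAMES = {v[0]: k for k, v in _VTK_CELL_TYPES.items()}


def write_vtk(path, model: TissueModel, point_data: dict | None = None):
    """Write a mesh as legacy ASCII VTK with per-node ``region`` labels.

    Structured grids are written as their node cloud with hexahedral /
    quad elements reconstructed from the lattice, so any VTK viewer can
    render them; ``point_data`` adds extra float arrays.
    """
    pos = model.positions
    if model.cells is not None:
        cells, cell_type = np.asarray(model.cells), model.cell_type
    elif model.shape is not None:
        cells, cell_type = _lattice_cells(model.shape)
    else:
        raise ValueError("mesh has neither cells nor a structured shape")
    vtk_id, npc = _VTK_CELL_TYPES[cell_type]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nrvimap mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(pos)} float\n")
        np.savetxt(fh, pos, fmt="%.6g")
        fh.write(f"CELLS {len(cells)} {len(cells) * (npc + 1)}\n")
        np.savetxt(fh, np.column_stack(
            [np.full(len(cells), npc), cells]), fmt="%d")
        fh.write(f"CELL_TYPES {len(cells)}\n")
        np.savetxt(fh, np.full(len(cells), vtk_id), fmt="%d")
        fh.write(f"POINT_DATA {len(pos)}\n")
        fh.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, model.labels, fmt="%d")
        for name, arr in (point_data or {}).items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, np.asarray(arr, float), fmt="%.6g")


def read_vtk(path) -> TissueModel:
    """Read a legacy ASCII VTK unstructured grid (single cell type).

    Region labels come from the ``region`` point-data array when present
    (HEALTHY otherwise).
    """
    with open(path) as fh:
        tokens = fh.read().split()
    tok = iter(range(len(tokens)))

    def find(word, start=0):
        for i in range(start, len(tokens)):
            if tokens[i].upper() == word:
                return i
        return -1

    ip = find("POINTS")
    if ip < 0:
        raise ValueError("not a legacy VTK point file")
    n_pts = int(tokens[ip + 1])
    pos = np.array(tokens[ip + 3:ip + 3 + 3 * n_pts], float).reshape(-1, 3)

    ic = find("CELLS")
    n_cells = int(tokens[ic + 1])
    total = int(tokens[ic + 2])
    raw = np.array(tokens[ic + 3:ic + 3 + total], dtype=np.int64)
    npc = int(raw[0])
    cells = raw.reshape(n_cells, npc + 1)[:, 1:]

    it = find("CELL_TYPES")
    vtk_id = int(tokens[it + 2])
    cell_type = _VTK_TYPE_NAMES.get(vtk_id)
    if cell_type is None:
        raise ValueError(f"unsupported VTK cell type {vtk_id}")

    labels = np.full(n_pts, int(Region.HEALTHY), dtype=np.int64)
    ir = find("SCALARS")
    while ir >= 0:
        if tokens[ir + 1] == "region":
            start = find("LOOKUP_TABLE", ir) + 2
            labels = np.array(tokens[start:start + n_pts], dtype=np.int64)
            break
        ir = find("SCALARS", ir + 1)

    return TissueModel(kind="unstructured-mesh", positions=pos,
                       labels=labels, cells=cells, cell_type=cell_type)


def _lattice_cells(shape):
    nx, ny, nz = shape
    idx = np.arange(nx * ny * nz).reshape(shape)
    if nz == 1:
        a = idx[:-1, :-1, 0]
        cells = np.stack([a, a + ny * nz, a + ny * nz + nz, a + nz],
                         axis=-1).reshape(-1, 4)
        return cells, "quad"
    a = idx[:-1, :-1, :-1]
    sx, sy, sz = ny * nz, nz, 1
    cells = np.stack([a, a + sx, a + sx + sy, a + sy,
                      a + sz, a + sx + sz, a + sx + sy + sz, a + sy + sz],
                     axis=-1).reshape(-1, 8)
    return cells, "hexahedron"


def save_model_h5(path, model: TissueModel):
    """Serialise a tissue model (structured or unstructured) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["kind"] = model.kind
        f.create_dataset("positions_um", data=model.positions)
        f.create_dataset("labels", data=model.labels)
        if model.shape is not None:
            f.attrs["shape"] = model.shape
            f.attrs["dx_um"] = model.dx_um
        if model.cells is not None:
            f.create_dataset("cells", data=model.cells)
            f.attrs["cell_type"] = model.cell_type


def load_model_h5(path) -> TissueModel:
    import h5py

    with h5py.File(path, "r") as f:
        kw = dict(kind=f.attrs["kind"],
                  positions=f["positions_um"][...],
                  labels=f["labels"][...])
        if "shape" in f.attrs:
            kw["shape"] = tuple(int(v) for v in f.attrs["shape"])
            kw["dx_um"] = float(f.attrs["dx_um"])
        if "cells" in f:
            kw["cells"] = f["cells"][...]
            kw["cell_type"] = str(f.attrs["cell_type"])
    return TissueModel(**kw)


def write_summary_json(path, payload: dict):
    """Write a summary dict as JSON (numpy scalars coerced)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
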