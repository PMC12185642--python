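"""Minimal legacy-VTK ASCII reader/writer.

Covers the subset of the legacy format this package exchanges with CFD
post-processing tools: ``UNSTRUCTURED_GRID`` (tetrahedra) and ``POLYDATA``
(triangles), with ``POINT_DATA``/``CELL_DATA`` scalars and vectors and a
dataset ``FIELD`` entry ``TIME`` carrying the sample time.  Files written
here load in ParaView; indices are converted to/from the package's 0-based
convention at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

VTK_TET = 10


class VTKFormatError(ValueError):
    pass


@dataclass
class VTKDataset:
    """In-memory image of one legacy-VTK file."""

    kind: str  # "unstructured_grid" | "polydata"
    points: np.ndarray
    cells: np.ndarray  # (m, 4) tets or (m, 3) triangles
    point_data: dict[str, np.ndarray] = field(default_factory=dict)
    cell_data: dict[str, np.ndarray] = field(default_factory=dict)
    time: float | None = None


def _fmt_array(a: np.ndarray) -> str:
    a = np.asarray(a)
    if a.ndim == 1:
        a = a[:, None]
    return "\n".join(" ".join(f"{x:.17g}" for x in row) for row in a)


def write_vtk(path, ds: VTKDataset) -> None:
    lines = ["# vtk DataFile Version 3.0", "graftflow dataset", "ASCII"]
    if ds.kind == "unstructured_grid":
        lines.append("DATASET UNSTRUCTURED_GRID")
    elif ds.kind == "polydata":
        lines.append("DATASET POLYDATA")
    else:
        raise VTKFormatError(f"unsupported dataset kind {ds.kind!r}")
    if ds.time is not None:
        lines += ["FIELD FieldData 1", "TIME 1 1 double", f"{ds.time:.17g}"]
    pts = np.asarray(ds.points, dtype=float)
    lines.append(f"POINTS {len(pts)} double")
    lines.append(_fmt_array(pts))
    cells = np.asarray(ds.cells, dtype=np.int64)
    m, k = cells.shape
    body = "\n".join(f"{k} " + " ".join(str(i) for i in row) for row in cells)
    if ds.kind == "unstructured_grid":
        if k != 4:
            raise VTKFormatError("unstructured grids carry tetrahedra (4 nodes)")
        lines.append(f"CELLS {m} {m * 5}")
        lines.append(body)
        lines.append(f"CELL_TYPES {m}")
        lines.append("\n".join([str(VTK_TET)] * m))
    else:
        if k != 3:
            raise VTKFormatError("polydata carries triangles (3 nodes)")
        lines.append(f"POLYGONS {m} {m * 4}")
        lines.append(body)

    for section, data, n in (
        ("POINT_DATA", ds.point_data, len(pts)),
        ("CELL_DATA", ds.cell_data, m),
    ):
        if not data:
            continue
        lines.append(f"{section} {n}")
        for name, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            if len(arr) != n:
                raise VTKFormatError(f"field {name!r}: length {len(arr)} != {n}")
            if arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines.append(_fmt_array(arr))
            elif arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.append(_fmt_array(arr))
            else:
                raise VTKFormatError(f"field {name!r}: unsupported shape {arr.shape}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_numbers(tokens, it, count):
    """Collect ``count`` whitespace tokens, pulling further lines as needed."""
    out = list(tokens)
    while len(out) < count:
        try:
            out.extend(next(it).split())
        except StopIteration:  # pragma: no cover - malformed file
            raise VTKFormatError("unexpected end of file")
    return out[:count], out[count:]


def read_vtk(path) -> VTKDataset:
    text = Path(path).read_text()
    it = iter(text.splitlines())
    header = [next(it, "") for _ in range(3)]
    if not header[0].startswith("# vtk DataFile"):
        raise VTKFormatError(f"{path}: not a legacy VTK file")
    if header[2].strip().upper() != "ASCII":
        raise VTKFormatError(f"{path}: only ASCII files are supported")

    kind = None
    points = cells = None
    point_data: dict[str, np.ndarray] = {}
    cell_data: dict[str, np.ndarray] = {}
    time = None
    active = None  # current data dict
    n_active = 0
    carry: list[str] = []

    def next_tokens():
        nonlocal carry
        while not carry:
            line = next(it)
            carry = line.split()
        toks, carry = carry, []
        return toks

    while True:
        try:
            toks = next_tokens()
        except StopIteration:
            break
        key = toks[0].upper()
        if key == "DATASET":
            kind = toks[1].lower()
        elif key == "FIELD":
            n_arrays = int(toks[2])
            for _ in range(n_arrays):
                name, ncomp, ntup, _dtype = next_tokens()[:4]
                vals, carry = _read_numbers([], it, int(ncomp) * int(ntup))
                if name.upper() == "TIME":
                    time = float(vals[0])
        elif key == "POINTS":
            n = int(toks[1])
            vals, carry = _read_numbers([], it, 3 * n)
            points = np.array(vals, dtype=float).reshape(n, 3)
        elif key in ("CELLS", "POLYGONS"):
            m, total = int(toks[1]), int(toks[2])
            vals, carry = _read_numbers([], it, total)
            vals = np.array(vals, dtype=np.int64)
            k = int(vals[0])
            cells = vals.reshape(m, k + 1)[:, 1:]
            if np.any(vals.reshape(m, k + 1)[:, 0] != k):
                raise VTKFormatError("mixed cell sizes are not supported")
        elif key == "CELL_TYPES":
            m = int(toks[1])
            _, carry = _read_numbers([], it, m)
        elif key == "POINT_DATA":
            active, n_active = point_data, int(toks[1])
        elif key == "CELL_DATA":
            active, n_active = cell_data, int(toks[1])
        elif key in ("SCALARS", "VECTORS", "NORMALS"):
            if active is None:
                raise VTKFormatError(f"{toks[0]} outside POINT_DATA/CELL_DATA")
            name = toks[1]
            if key == "SCALARS":
                ncomp = int(toks[3]) if len(toks) > 3 else 1
                lut = next_tokens()  # LOOKUP_TABLE line
                if lut[0].upper() != "LOOKUP_TABLE":
                    carry = lut
                vals, carry = _read_numbers(carry, it, n_active * ncomp)
                arr = np.array(vals, dtype=float)
                active[name] = arr if ncomp == 1 else arr.reshape(n_active, ncomp)
            else:
                vals, carry = _read_numbers([], it, n_active * 3)
                active[name] = np.array(vals, dtype=float).reshape(n_active, 3)
        # silently skip anything else (METADATA etc.)

    if kind is None or points is None or cells is None:
        raise VTKFormatError(f"{path}: incomplete dataset")
    return VTKDataset(
        kind=kind, points=points, cells=cells,
        point_data=point_data, cell_data=cell_data, time=time,
    )
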