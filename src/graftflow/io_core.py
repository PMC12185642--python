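"""Field time-series containers and file I/O.

Velocity series live on a tetrahedral :class:`~graftflow.meshes.VolumeMesh`;
wall-shear-stress (WSS) series live on a triangulated
:class:`~graftflow.meshes.SurfaceMesh`.  Both are exchanged as legacy-VTK
file series (one file per timestep) indexed by a small JSON/YAML manifest,
and waveforms as two-column CSV.  All quantities are SI internally; mmHg in
configs is converted at 1 mmHg = 133.322 Pa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .meshes import MeshError, SurfaceMesh, VolumeMesh
from .vtkio import VTKDataset, read_vtk, write_vtk
from .waveforms import Waveform

MMHG_TO_PA = 133.322

DEFAULT_VELOCITY_FIELD = "velocity"
DEFAULT_WSS_FIELD = "wss"


class SeriesError(ValueError):
    pass


@dataclass
class TimeSeriesVolumeField:
    """Velocity 3-vectors per node over one cardiac cycle.

    ``values`` has shape (n_times, n_nodes, 3) in m/s; ``times`` are strictly
    increasing and span at most one period.
    """

    mesh: VolumeMesh
    times: np.ndarray
    values: np.ndarray
    period: float
    field_name: str = DEFAULT_VELOCITY_FIELD

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) < 3:
            raise SeriesError("need at least 3 time samples")
        if np.any(np.diff(self.times) <= 0):
            raise SeriesError("times must be strictly increasing")
        if self.times[-1] - self.times[0] > self.period * (1 + 1e-9):
            raise SeriesError("samples span more than one period")
        if self.values.shape != (len(self.times), self.mesh.n_nodes, 3):
            raise SeriesError("values must be (n_times, n_nodes, 3)")

    @property
    def n_times(self) -> int:
        return len(self.times)


@dataclass
class SurfaceWSSSeries:
    """WSS 3-vectors per surface node over one cardiac cycle (Pa).

    On construction each vector is projected onto the local tangent plane
    (WSS is tangential by definition); the largest normal component removed
    is recorded in ``max_normal_deviation``.
    """

    surface: SurfaceMesh
    times: np.ndarray
    values: np.ndarray
    period: float
    field_name: str = DEFAULT_WSS_FIELD
    max_normal_deviation: float = field(init=False, default=0.0)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) < 3:
            raise SeriesError("need at least 3 time samples")
        if np.any(np.diff(self.times) <= 0):
            raise SeriesError("times must be strictly increasing")
        if self.times[-1] - self.times[0] > self.period * (1 + 1e-9):
            raise SeriesError("samples span more than one period")
        if self.values.shape != (len(self.times), self.surface.n_nodes, 3):
            raise SeriesError("values must be (n_times, n_nodes, 3)")
        n = self.surface.node_normals
        normal_comp = np.einsum("tik,ik->ti", self.values, n)
        self.max_normal_deviation = float(np.abs(normal_comp).max(initial=0.0))
        self.values = self.values - normal_comp[..., None] * n[None, :, :]

    @property
    def n_times(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# VTK file series


def write_timeseries_mesh(
    out_dir,
    series: TimeSeriesVolumeField | SurfaceWSSSeries,
    prefix: str = "step",
) -> Path:
    """Write one VTK file per timestep plus a manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    is_volume = isinstance(series, TimeSeriesVolumeField)
    mesh = series.mesh if is_volume else series.surface
    files = []
    for k, t in enumerate(series.times):
        name = f"{prefix}_{k:04d}.vtk"
        ds = VTKDataset(
            kind="unstructured_grid" if is_volume else "polydata",
            points=mesh.points,
            cells=mesh.tets if is_volume else mesh.tris,
            point_data={series.field_name: series.values[k]},
            time=float(t),
        )
        if not is_volume:
            ds.point_data["normals"] = mesh.node_normals
            for roi, idx in mesh.rois.items():
                m = np.zeros(mesh.n_cells)
                m[idx] = 1.0
                ds.cell_data[f"roi_{roi}"] = m
        write_vtk(out_dir / name, ds)
        files.append(name)
    manifest = {
        "kind": "volume" if is_volume else "surface",
        "field": series.field_name,
        "period": series.period,
        "files": files,
    }
    mpath = out_dir / f"{prefix}_series.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def _mesh_from_dataset(ds: VTKDataset, kind: str):
    if kind == "volume":
        if ds.kind != "unstructured_grid":
            raise SeriesError(f"expected an unstructured grid, found {ds.kind}")
        return VolumeMesh(ds.points, ds.cells)
    if ds.kind != "polydata":
        raise SeriesError(f"expected polydata, found {ds.kind}")
    rois = {}
    for name, arr in ds.cell_data.items():
        if name.startswith("roi_"):
            rois[name[4:]] = np.flatnonzero(arr > 0.5)
    normals = ds.point_data.get("normals")
    return SurfaceMesh(ds.points, ds.cells, node_normals=normals, rois=rois)


def read_timeseries_mesh(
    paths,
    kind: str,
    period: float,
    field_name: str | None = None,
) -> TimeSeriesVolumeField | SurfaceWSSSeries:
    """Load a VTK file series into a single time-series container.

    ``paths`` is either an ordered list of per-timestep files or a single
    manifest (JSON/YAML) naming them.  Files may arrive in any order: samples
    are sorted by their embedded time stamp.  All files must share identical
    topology and carry the named vector field.
    """
    if kind not in ("volume", "surface"):
        raise SeriesError(f"kind must be 'volume' or 'surface', got {kind!r}")
    if isinstance(paths, (str, Path)):
        paths = Path(paths)
        manifest = yaml.safe_load(paths.read_text())
        field_name = field_name or manifest.get("field")
        period = manifest.get("period", period)
        paths = [paths.parent / f for f in manifest["files"]]
    if field_name is None:
        field_name = DEFAULT_VELOCITY_FIELD if kind == "volume" else DEFAULT_WSS_FIELD
    datasets = [read_vtk(p) for p in paths]
    if not datasets:
        raise SeriesError("empty file list")
    mesh = _mesh_from_dataset(datasets[0], kind)
    times, values = [], []
    for p, ds in zip(paths, datasets):
        other = _mesh_from_dataset(ds, kind)
        if not mesh.same_topology(other):
            raise MeshError(f"{p}: topology differs from the first file")
        if ds.time is None:
            raise SeriesError(f"{p}: missing TIME field")
        if field_name not in ds.point_data:
            raise SeriesError(f"{p}: missing point field {field_name!r}")
        times.append(ds.time)
        values.append(ds.point_data[field_name])
    order = np.argsort(times)
    times = np.asarray(times)[order]
    values = np.asarray(values)[order]
    if np.any(np.diff(times) <= 0):
        raise SeriesError("duplicate or non-monotone time stamps across files")
    if kind == "volume":
        return TimeSeriesVolumeField(mesh, times, values, period, field_name=field_name)
    return SurfaceWSSSeries(mesh, times, values, period, field_name=field_name)


def write_surface_fields(path, surface: SurfaceMesh, point_data=None, cell_data=None):
    """Write scalar descriptor fields on a surface to one VTK polydata file."""
    ds = VTKDataset(
        kind="polydata",
        points=surface.points,
        cells=surface.tris,
        point_data=dict(point_data or {}),
        cell_data=dict(cell_data or {}),
    )
    ds.point_data.setdefault("normals", surface.node_normals)
    write_vtk(path, ds)


# ---------------------------------------------------------------------------
# Waveform CSV


def read_waveform_csv(path, period: float, units: str = "m^3/s", periodic: bool = True) -> Waveform:
    """Read a two-column (time_s, value) CSV; header row optional."""
    first = Path(path).open().readline()
    has_header = any(c.isalpha() for c in first.split(",")[0])
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] < 2:
        raise WaveformCSVError(f"{path}: expected two columns")
    t = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy()
    v = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy()
    if np.any(~np.isfinite(t)) or np.any(~np.isfinite(v)):
        raise WaveformCSVError(f"{path}: non-numeric rows")
    order = np.argsort(t)
    t, v = t[order], v[order]
    if np.any(np.diff(t) == 0):
        raise WaveformCSVError(f"{path}: duplicate time samples")
    return Waveform(t, v, period, units=units, periodic=periodic)


def write_waveform_csv(path, w: Waveform) -> None:
    pd.DataFrame({"time_s": w.times, "value": w.values}).to_csv(
        path, index=False, float_format="%.17g"
    )


class WaveformCSVError(ValueError):
    pass
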