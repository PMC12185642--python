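"""Near-wall WSS descriptors on the triangulated lumen surface.

Per-node indices over one cardiac cycle of period T:

    TAWSS    = (1/T) int |tau| dt                       [Pa]
    OSI      = 0.5 * (1 - |int tau dt| / int |tau| dt)  in [0, 0.5]
    transWSS = (1/T) int |tau . (n x m)| dt             [Pa]

with m the unit cycle-mean WSS direction and n the outward wall normal, so
n x m is the in-plane direction perpendicular to the mean WSS.  The WSS
topological skeleton is probed through the surface divergence of the unit
WSS field, computed per triangle from the P1 interpolant (exact for fields
affine over a flat patch), and its cycle-RMS fluctuation

    TSVI = sqrt( (1/T) int (div_s u - mean)^2 dt )      [1/m]

All time integrals are trapezoidal with periodic wrap closure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import SurfaceWSSSeries
from .meshes import SurfaceMesh
from .waveforms import periodic_trapezoid

TAU_EPS = 1e-6  # Pa: |tau| below this is treated as zero for normalisation
INT_EPS = 1e-9  # Pa s: integral floor below which OSI is set to 0


@dataclass
class WallDescriptorSet:
    """Bundle of the four wall indices on one surface.

    tawss, osi, transwss are per-node; tsvi and the underlying divergence
    time series are per-cell (tagged by ``tsvi_support``).  ``transwss_flag``
    marks nodes whose cycle-mean WSS vector is numerically zero, where the
    mean direction m is undefined and transWSS is set to 0 by convention.
    """

    surface: SurfaceMesh
    tawss: np.ndarray
    osi: np.ndarray
    transwss: np.ndarray
    transwss_flag: np.ndarray
    tsvi: np.ndarray
    divergence_series: np.ndarray  # (n_t, n_cells), 1/m
    tsvi_support: str = "cell"

    def tsvi_on_nodes(self) -> np.ndarray:
        """Area-weighted transfer of cell TSVI to nodes (for thresholding on
        node support)."""
        return cell_to_node(self.surface, self.tsvi)


def cell_to_node(surface: SurfaceMesh, cell_values: np.ndarray) -> np.ndarray:
    num = np.zeros(surface.n_nodes)
    den = np.zeros(surface.n_nodes)
    w = surface.cell_areas
    np.add.at(num, surface.tris.ravel(), np.repeat(cell_values * w, 3))
    np.add.at(den, surface.tris.ravel(), np.repeat(w, 3))
    return num / den


def tawss(series: SurfaceWSSSeries) -> np.ndarray:
    mag = np.linalg.norm(series.values, axis=2)
    return periodic_trapezoid(series.times, mag, series.period) / series.period


def osi(series: SurfaceWSSSeries) -> np.ndarray:
    vec_int = periodic_trapezoid(series.times, series.values, series.period)
    mag_int = periodic_trapezoid(
        series.times, np.linalg.norm(series.values, axis=2), series.period
    )
    out = np.zeros(series.surface.n_nodes)
    ok = mag_int >= INT_EPS
    out[ok] = 0.5 * (1.0 - np.linalg.norm(vec_int[ok], axis=1) / mag_int[ok])
    return np.clip(out, 0.0, 0.5)


def transwss(series: SurfaceWSSSeries):
    """Returns (transwss, degenerate_flag) per node.

    Nodes where |int tau dt| is negligible against int |tau| dt have no
    defined mean direction (the perfectly-reversing limit, OSI -> 0.5);
    they are flagged and given the value 0.
    """
    vec_int = periodic_trapezoid(series.times, series.values, series.period)
    mag_int = periodic_trapezoid(
        series.times, np.linalg.norm(series.values, axis=2), series.period
    )
    norm = np.linalg.norm(vec_int, axis=1)
    flag = norm < np.maximum(1e-9 * mag_int, INT_EPS)
    m = np.zeros_like(vec_int)
    m[~flag] = vec_int[~flag] / norm[~flag, None]
    p = np.cross(series.surface.node_normals, m)
    proj = np.abs(np.einsum("tik,ik->ti", series.values, p))
    out = periodic_trapezoid(series.times, proj, series.period) / series.period
    out[flag] = 0.0
    return out, flag


def unit_wss_divergence(
    surface: SurfaceMesh, tau: np.ndarray, eps: float = TAU_EPS
) -> np.ndarray:
    """Per-cell surface divergence (1/m) of the normalised WSS field at one
    sample.  Nodes with |tau| < eps contribute a zero vector."""
    tau = np.asarray(tau, dtype=float)
    mag = np.linalg.norm(tau, axis=1)
    u = np.zeros_like(tau)
    ok = mag >= eps
    u[ok] = tau[ok] / mag[ok, None]

    p = surface.points[surface.tris]  # (m, 3, 3)
    n = surface.cell_normals
    inv2A = 1.0 / (2.0 * surface.cell_areas)
    div = np.zeros(surface.n_cells)
    # shape-function surface gradients: grad(phi_i) = n x (p_k - p_j) / (2A)
    for i, j, k in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        grad = np.cross(n, p[:, k] - p[:, j]) * inv2A[:, None]
        div += np.einsum("mj,mj->m", grad, u[surface.tris[:, i]])
    return div


def divergence_series(series: SurfaceWSSSeries, eps: float = TAU_EPS) -> np.ndarray:
    return np.stack(
        [unit_wss_divergence(series.surface, tau, eps=eps) for tau in series.values]
    )


def tsvi(div_series: np.ndarray, times: np.ndarray, period: float) -> np.ndarray:
    """Cycle-RMS of the divergence fluctuation about its own cycle mean."""
    mean = periodic_trapezoid(times, div_series, period) / period
    fluct2 = (div_series - mean[None]) ** 2
    return np.sqrt(periodic_trapezoid(times, fluct2, period) / period)


def compute_wall_descriptors(series: SurfaceWSSSeries, eps: float = TAU_EPS) -> WallDescriptorSet:
    """Compute the full TAWSS/OSI/transWSS/TSVI set for one WSS series."""
    tw, flag = transwss(series)
    div = divergence_series(series, eps=eps)
    return WallDescriptorSet(
        surface=series.surface,
        tawss=tawss(series),
        osi=osi(series),
        transwss=tw,
        transwss_flag=flag,
        tsvi=tsvi(div, series.times, series.period),
        divergence_series=div,
    )
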