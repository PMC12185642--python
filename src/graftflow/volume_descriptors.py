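"""Volumetric flow descriptors: TKE, vorticity, helicity, LNH.

Velocity fluctuations are deviations of the instantaneous velocity from its
single-cycle time average, so the resulting "turbulent" kinetic energy mixes
resolved turbulent and pulsatile content by construction; see the methods
note for the implications.  Helicity descriptors follow the usual cycle-and-
volume-averaged definitions:

    h1 = (1/(T V)) * int int  v . omega  dV dt      (net amount, m/s^2)
    h2 = (1/(T V)) * int int |v . omega| dV dt      (intensity, m/s^2)
    h3 = h1/h2  (signed rotational balance), h4 = |h3|

and the local normalised helicity LNH = v.omega / (|v||omega|) in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import TimeSeriesVolumeField
from .meshes import VolumeMesh
from .waveforms import cycle_mean, periodic_trapezoid

LNH_EPS = 1e-12


@dataclass(frozen=True)
class HelicityDescriptors:
    """Cycle-and-volume-averaged helicity summary for one region."""

    h1: float  # m/s^2
    h2: float  # m/s^2
    h3: float  # dimensionless signed balance
    h4: float  # dimensionless, |h3|


def cycle_average_velocity(series: TimeSeriesVolumeField) -> np.ndarray:
    """Per-node cycle-mean velocity (trapezoidal, wrap-closed)."""
    return cycle_mean(series.times, series.values, series.period, axis=0)


def velocity_fluctuations(series: TimeSeriesVolumeField, mean: np.ndarray | None = None):
    """Instantaneous minus cycle-mean velocity, per node and sample."""
    if mean is None:
        mean = cycle_average_velocity(series)
    mean = np.asarray(mean)
    if mean.shape != (series.mesh.n_nodes, 3):
        raise ValueError("mean shape does not match the series")
    return series.values - mean[None]


def tke_field(fluct_at_t: np.ndarray, rho: float) -> np.ndarray:
    """Turbulent kinetic energy density 0.5*rho*|u'|^2 (J/m^3) per node."""
    if rho <= 0:
        raise ValueError("density must be positive")
    f = np.asarray(fluct_at_t, dtype=float)
    return 0.5 * rho * np.einsum("...k,...k->...", f, f)


def _tet_gradients(mesh: VolumeMesh, values: np.ndarray) -> np.ndarray:
    """Per-cell constant gradient G[c, i, j] = d(values_j)/d(x_i) from the
    linear (P1) interpolant; exact for affine fields."""
    p = mesh.points[mesh.tets]  # (m, 4, 3)
    D = p[:, 1:] - p[:, :1]  # (m, 3, 3) edge matrix
    v = values[mesh.tets]
    U = v[:, 1:] - v[:, :1]
    return np.linalg.solve(D, U)


def vorticity_field(mesh: VolumeMesh, velocity: np.ndarray) -> np.ndarray:
    """Per-node vorticity (curl of velocity, 1/s) at one time sample.

    The P1 reconstruction gives a constant curl per tetrahedron; nodal
    values are volume-weighted averages of the incident cells, exact for
    affine velocity fields.
    """
    G = _tet_gradients(mesh, np.asarray(velocity, dtype=float))
    curl = np.stack(
        [G[:, 1, 2] - G[:, 2, 1], G[:, 2, 0] - G[:, 0, 2], G[:, 0, 1] - G[:, 1, 0]],
        axis=1,
    )
    w = mesh.cell_volumes
    num = np.zeros((mesh.n_nodes, 3))
    den = np.zeros(mesh.n_nodes)
    np.add.at(num, mesh.tets.ravel(), np.repeat(curl * w[:, None], 4, axis=0))
    np.add.at(den, mesh.tets.ravel(), np.repeat(w, 4))
    return num / den[:, None]


def vorticity_series(series: TimeSeriesVolumeField) -> np.ndarray:
    """Vorticity at every sample of a velocity series, (n_t, n_nodes, 3)."""
    return np.stack([vorticity_field(series.mesh, v) for v in series.values])


def lnh_field(velocity: np.ndarray, vorticity: np.ndarray, eps: float = LNH_EPS) -> np.ndarray:
    """Local normalised helicity, the cosine between v and omega; 0 where
    either vanishes (|v||omega| < eps)."""
    v = np.asarray(velocity, dtype=float)
    w = np.asarray(vorticity, dtype=float)
    num = np.einsum("...k,...k->...", v, w)
    den = np.linalg.norm(v, axis=-1) * np.linalg.norm(w, axis=-1)
    out = np.zeros_like(num)
    ok = den >= eps
    out[ok] = num[ok] / den[ok]
    return np.clip(out, -1.0, 1.0)


def helicity_descriptors(
    series: TimeSeriesVolumeField,
    vorticity: np.ndarray | None = None,
    region: np.ndarray | None = None,
) -> HelicityDescriptors:
    """h1, h2, h3, h4 over a cell region (default: whole mesh).

    The volume integral uses the per-cell midpoint rule: the helicity
    density v.omega is averaged over the four nodes of each tetrahedron and
    multiplied by the cell volume; the time integral is trapezoidal with
    periodic wrap.
    """
    mesh = series.mesh
    if vorticity is None:
        vorticity = vorticity_series(series)
    if vorticity.shape != series.values.shape:
        raise ValueError("vorticity series shape mismatch")
    cells = np.arange(mesh.n_cells) if region is None else np.asarray(region, dtype=np.int64)
    if cells.size == 0:
        raise ValueError("empty region")
    dens = np.einsum("tik,tik->ti", series.values, vorticity)  # (n_t, n_nodes)
    nodal = dens[:, mesh.tets[cells]]  # (n_t, n_cells_sel, 4)
    vol = mesh.cell_volumes[cells]
    V = vol.sum()
    signed = nodal.mean(axis=2) @ vol
    absolute = np.abs(nodal).mean(axis=2) @ vol
    h1 = float(periodic_trapezoid(series.times, signed, series.period) / (series.period * V))
    h2 = float(periodic_trapezoid(series.times, absolute, series.period) / (series.period * V))
    h3 = h1 / h2 if h2 > 0 else 0.0
    return HelicityDescriptors(h1=h1, h2=h2, h3=h3, h4=abs(h3))
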