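"""Synthetic geometries and analytic flow fields with known descriptor values.

Everything the descriptor and network modules compute can be exercised here
without patient data or a CFD solver: pulsatile pipe flow (Womersley /
Poiseuille) provides closed-form wall shear, a rigid-rotation helical field
provides closed-form helicity and LNH, prescribed spatio-temporal WSS
patterns provide closed-form TAWSS/OSI/transWSS/TSVI, and a six-segment 0D
network mirrors the arteriovenous-graft topology (inlet, three
Windkessel-terminated arterial outlets, graft path to a venous pressure
sink).  All generators are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import jv

from .io_core import MMHG_TO_PA, SurfaceWSSSeries
from .lumped0d import (
    FixedPressure,
    Inflow,
    Network0D,
    Segment0D,
    WK3Params,
    segment_inertance,
)
from .meshes import SurfaceMesh, VolumeMesh
from .waveforms import Waveform

BLOOD_DENSITY = 1056.0  # kg/m^3


# ---------------------------------------------------------------------------
# Rheology


@dataclass(frozen=True)
class RheologyParams:
    """Carreau-Yasuda parameters; defaults are representative whole-blood
    values (zero/infinite-shear viscosities in Pa s, relaxation time in s,
    Yasuda exponent a, power-law index n)."""

    mu0: float = 0.056
    mu_inf: float = 0.0035
    lam: float = 3.313
    a: float = 2.0
    n: float = 0.3568

    def __post_init__(self):
        if not (self.mu0 >= self.mu_inf > 0):
            raise ValueError("require mu0 >= mu_inf > 0")
        if self.lam <= 0 or self.a <= 0 or not (0 < self.n <= 1):
            raise ValueError("require lam > 0, a > 0, 0 < n <= 1")


def carreau_yasuda_viscosity(shear_rate, params: RheologyParams = RheologyParams()):
    """mu = mu_inf + (mu0 - mu_inf) * [1 + (lam*g)^a]^((n-1)/a)."""
    g = np.asarray(shear_rate, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be >= 0")
    return params.mu_inf + (params.mu0 - params.mu_inf) * (
        1.0 + (params.lam * g) ** params.a
    ) ** ((params.n - 1.0) / params.a)


# ---------------------------------------------------------------------------
# Cylinder mesh (structured, extruded wedges split to tetrahedra)


@dataclass(frozen=True)
class CylinderFixtureSpec:
    """Structured cylinder: ``n_radial`` rings, ``n_theta`` sectors,
    ``n_axial`` extrusion layers; deterministic for a fixed spec."""

    radius: float = 0.003  # m
    length: float = 0.02  # m
    n_radial: int = 4
    n_theta: int = 16
    n_axial: int = 8
    density: float = BLOOD_DENSITY
    viscosity: float = 0.0035  # Pa s, the high-shear plateau

    def __post_init__(self):
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("radius and length must be positive")
        if self.n_radial < 1 or self.n_theta < 3 or self.n_axial < 1:
            raise ValueError("resolution too coarse for a valid tetrahedral mesh")


def _disc_points(R, n_radial, n_theta):
    pts = [(0.0, 0.0)]
    for j in range(1, n_radial + 1):
        r = R * j / n_radial
        ang = 2.0 * np.pi * np.arange(n_theta) / n_theta
        pts.extend(zip(r * np.cos(ang), r * np.sin(ang)))
    return np.array(pts)


def _disc_triangles(n_radial, n_theta):
    tris = []
    ring = lambda j, i: 1 + (j - 1) * n_theta + (i % n_theta)
    for i in range(n_theta):
        tris.append((0, ring(1, i), ring(1, i + 1)))
    for j in range(1, n_radial):
        for i in range(n_theta):
            a, b = ring(j, i), ring(j, i + 1)
            c, d = ring(j + 1, i), ring(j + 1, i + 1)
            # split quad (a, b, d, c) along the diagonal through its smallest node
            if min(a, d) < min(b, c):
                tris.append((a, b, d))
                tris.append((a, d, c))
            else:
                tris.append((a, b, c))
                tris.append((b, d, c))
    return np.array(tris, dtype=np.int64)


def _split_prism(g):
    """Split a wedge (bottom g[0:3], top g[3:6]) into 3 tetrahedra using the
    smallest-global-index diagonal rule, so shared quad faces of adjacent
    wedges receive matching diagonals."""
    g = list(g)
    m = int(np.argmin(g))
    if m >= 3:
        g = g[3:] + g[:3]
        m -= 3
    r = [m, (m + 1) % 3, (m + 2) % 3]
    g = [g[r[0]], g[r[1]], g[r[2]], g[3 + r[0]], g[3 + r[1]], g[3 + r[2]]]
    quad = [g[1], g[2], g[5], g[4]]
    if min(quad) in (g[1], g[5]):
        return [(g[0], g[1], g[2], g[5]), (g[0], g[1], g[5], g[4]), (g[0], g[4], g[5], g[3])]
    return [(g[0], g[1], g[2], g[4]), (g[0], g[4], g[2], g[5]), (g[0], g[4], g[5], g[3])]


def make_cylinder_mesh(spec: CylinderFixtureSpec, roi_bands=None):
    """Conforming tet mesh of a cylinder along +z plus its lateral-wall
    triangulation with outward radial normals.

    ``roi_bands`` optionally names axial intervals {name: (z0, z1)} that
    become cell ROIs on the wall surface (assigned by triangle centroid).
    """
    R, Lz = spec.radius, spec.length
    disc = _disc_points(R, spec.n_radial, spec.n_theta)
    tris2d = _disc_triangles(spec.n_radial, spec.n_theta)
    npl = len(disc)
    z = Lz * np.arange(spec.n_axial + 1) / spec.n_axial
    points = np.column_stack(
        [
            np.tile(disc[:, 0], spec.n_axial + 1),
            np.tile(disc[:, 1], spec.n_axial + 1),
            np.repeat(z, npl),
        ]
    )
    tets = []
    for l in range(spec.n_axial):
        lo, hi = l * npl, (l + 1) * npl
        for (a, b, c) in tris2d:
            tets.extend(_split_prism([lo + a, lo + b, lo + c, hi + a, hi + b, hi + c]))
    volume = VolumeMesh(points, np.array(tets, dtype=np.int64))

    # lateral wall: outer-ring nodes of every layer
    outer0 = 1 + (spec.n_radial - 1) * spec.n_theta
    wall_ids = np.concatenate(
        [l * npl + outer0 + np.arange(spec.n_theta) for l in range(spec.n_axial + 1)]
    )
    remap = {g: i for i, g in enumerate(wall_ids)}
    wpts = points[wall_ids]
    wtris = []
    nt = spec.n_theta
    for l in range(spec.n_axial):
        for i in range(nt):
            a = l * npl + outer0 + i
            b = l * npl + outer0 + (i + 1) % nt
            c = (l + 1) * npl + outer0 + i
            d = (l + 1) * npl + outer0 + (i + 1) % nt
            if min(a, d) < min(b, c):
                quads = [(a, b, d), (a, d, c)]
            else:
                quads = [(a, b, c), (b, d, c)]
            wtris.extend([(remap[x], remap[y], remap[z_]) for x, y, z_ in quads])
    wtris = np.array(wtris, dtype=np.int64)
    # orient triangles so normals point radially outward
    cent = wpts[wtris].mean(axis=1)
    radial = np.column_stack([cent[:, 0], cent[:, 1], np.zeros(len(cent))])
    cr = np.cross(
        wpts[wtris[:, 1]] - wpts[wtris[:, 0]], wpts[wtris[:, 2]] - wpts[wtris[:, 0]]
    )
    flip = np.einsum("ij,ij->i", cr, radial) < 0
    wtris[flip, 1], wtris[flip, 2] = wtris[flip, 2].copy(), wtris[flip, 1].copy()
    normals = wpts.copy()
    normals[:, 2] = 0.0
    normals /= np.linalg.norm(normals, axis=1)[:, None]
    rois = {}
    if roi_bands:
        zc = wpts[wtris].mean(axis=1)[:, 2]
        for name, (z0, z1) in roi_bands.items():
            rois[name] = np.flatnonzero((zc >= z0) & (zc < z1))
    wall = SurfaceMesh(wpts, wtris, node_normals=normals, rois=rois)
    return volume, wall


def make_annulus_surface(r_inner, r_outer, n_radial=8, n_theta=32) -> SurfaceMesh:
    """Flat annulus in the z = 0 plane with normals +z; the fixture for
    surface-divergence oracles (div of the radial unit field is 1/r)."""
    pts2, tris = [], []
    for j in range(n_radial + 1):
        r = r_inner + (r_outer - r_inner) * j / n_radial
        ang = 2.0 * np.pi * np.arange(n_theta) / n_theta
        pts2.extend(zip(r * np.cos(ang), r * np.sin(ang)))
    pts2 = np.array(pts2)
    ring = lambda j, i: j * n_theta + (i % n_theta)
    for j in range(n_radial):
        for i in range(n_theta):
            a, b = ring(j, i), ring(j, i + 1)
            c, d = ring(j + 1, i), ring(j + 1, i + 1)
            if min(a, d) < min(b, c):
                tris.extend([(a, b, d), (a, d, c)])
            else:
                tris.extend([(a, b, c), (b, d, c)])
    pts = np.column_stack([pts2, np.zeros(len(pts2))])
    normals = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
    return SurfaceMesh(pts, np.array(tris, dtype=np.int64), node_normals=normals)


# ---------------------------------------------------------------------------
# Analytic flow fields


@dataclass(frozen=True)
class WomersleyFlow:
    """Fully developed pulsatile pipe flow driven by flow-rate harmonics.

    ``q_harmonics[n]`` is the complex amplitude of harmonic n of the flow
    rate, Q(t) = Re(sum_n Q_n exp(i n w t)); harmonic 0 is the steady
    Poiseuille component.  Requires constant viscosity ``mu``.
    """

    radius: float
    mu: float
    rho: float
    omega: float  # fundamental angular frequency, rad/s
    q_harmonics: tuple  # complex amplitudes, index = harmonic number

    def _profile(self, n, r):
        """Complex velocity profile shape for harmonic n, normalised so the
        cross-sectional integral equals 1."""
        R = self.radius
        if n == 0:
            return 2.0 / (np.pi * R**2) * (1.0 - (r / R) ** 2)
        alpha = R * np.sqrt(self.rho * n * self.omega / self.mu)
        lam = 1j**1.5 * alpha
        denom = 1.0 - 2.0 * jv(1, lam) / (lam * jv(0, lam))
        shape = (1.0 - jv(0, lam * r / R) / jv(0, lam)) / denom
        return shape / (np.pi * R**2)

    def velocity(self, r, t):
        """Axial velocity u(r, t) in m/s."""
        r = np.asarray(r, dtype=float)
        u = 0.0j
        for n, q in enumerate(self.q_harmonics):
            u = u + q * self._profile(n, r) * np.exp(1j * n * self.omega * np.asarray(t))
        return np.real(u)

    def flow(self, t):
        q = sum(
            qn * np.exp(1j * n * self.omega * np.asarray(t, dtype=float))
            for n, qn in enumerate(self.q_harmonics)
        )
        return np.real(q)

    def wall_shear(self, t):
        """Axial wall shear stress tau(t) = -mu du/dr |_{r=R}, positive in
        the flow direction; steady part is 4 mu Q0 / (pi R^3)."""
        R = self.radius
        tau = np.zeros(np.shape(t), dtype=complex)
        for n, q in enumerate(self.q_harmonics):
            if n == 0:
                tau = tau + 4.0 * self.mu * q / (np.pi * R**3)
                continue
            alpha = R * np.sqrt(self.rho * n * self.omega / self.mu)
            lam = 1j**1.5 * alpha
            denom = 1.0 - 2.0 * jv(1, lam) / (lam * jv(0, lam))
            dshape = -lam * jv(1, lam) / (R * jv(0, lam)) / denom
            tau = tau - self.mu * q / (np.pi * R**2) * dshape * np.exp(
                1j * n * self.omega * np.asarray(t, dtype=float)
            )
        return np.real(tau)

    def velocity_field(self, points, t):
        """Axial velocity vectors at mesh points (nodes on/inside radius R)."""
        r = np.linalg.norm(points[:, :2], axis=1)
        u = self.velocity(r, t)
        out = np.zeros((len(points), 3))
        out[:, 2] = u
        return out


@dataclass(frozen=True)
class HelicalField:
    """Rigid rotation about +z with uniform axial drift:
    v = (-Omega y, Omega x, W).  Closed forms: vorticity (0, 0, 2 Omega),
    helicity density 2 Omega W, LNH(r) = W / sqrt(Omega^2 r^2 + W^2)."""

    omega: float  # 1/s
    w: float  # m/s

    def velocity(self, points):
        p = np.asarray(points, dtype=float)
        return np.column_stack([-self.omega * p[:, 1], self.omega * p[:, 0],
                                np.full(len(p), self.w)])

    def vorticity(self, points):
        out = np.zeros((len(points), 3))
        out[:, 2] = 2.0 * self.omega
        return out

    def lnh(self, points):
        r = np.linalg.norm(np.asarray(points)[:, :2], axis=1)
        den = np.sqrt(self.omega**2 * r**2 + self.w**2)
        out = np.zeros(len(r))
        ok = den > 0
        out[ok] = np.sign(self.omega) * self.w / den[ok]
        return out

    @property
    def helicity_density(self) -> float:
        return 2.0 * self.omega * self.w


# ---------------------------------------------------------------------------
# Prescribed WSS patterns


def _tangent_frame(surface: SurfaceMesh):
    """Per-node orthonormal tangent basis (e1, e2) with e2 = n x e1."""
    n = surface.node_normals
    ref = np.tile([0.0, 0.0, 1.0], (len(n), 1))
    nearly_parallel = np.abs(np.einsum("ij,ij->i", n, ref)) > 0.9
    ref[nearly_parallel] = [1.0, 0.0, 0.0]
    e1 = ref - np.einsum("ij,ij->i", ref, n)[:, None] * n
    e1 /= np.linalg.norm(e1, axis=1)[:, None]
    e2 = np.cross(n, e1)
    return e1, e2


def _square_wave(n_samples):
    if n_samples % 2:
        raise ValueError("square-wave patterns need an even sample count")
    s = np.ones(n_samples)
    s[n_samples // 2 :] = -1.0
    return s


def synthetic_wss_pattern(
    kind: str,
    surface: SurfaceMesh,
    period: float = 1.0,
    n_samples: int = 32,
    tau0: float = 1.0,
    amplitude: float = 0.5,
) -> SurfaceWSSSeries:
    """Spatio-temporal WSS series with closed-form descriptor values.

    kinds:
      unidirectional-pulsatile : tau = tau0 (1 + amplitude sin) e1
          -> OSI 0, transWSS 0, TAWSS tau0 (amplitude < 1)
      reversing : square wave +/- tau0 e1 -> OSI 0.5, TAWSS tau0
      rotating : tau0 (cos e1 + sin e2), constant magnitude -> TAWSS tau0
      biaxial : e1 + amplitude sin e2 (Pa) -> transWSS oracle fixture
      divergence-switching : square wave +/- tau0 r_hat (flat surface)
          -> TSVI at radius r = tau0-independent 1/r
    """
    t = period * np.arange(n_samples) / n_samples
    e1, e2 = _tangent_frame(surface)
    n_nodes = surface.n_nodes
    tau = np.zeros((n_samples, n_nodes, 3))
    if kind == "unidirectional-pulsatile":
        mod = 1.0 + amplitude * np.sin(2.0 * np.pi * t / period)
        tau = tau0 * mod[:, None, None] * e1[None]
    elif kind == "reversing":
        s = _square_wave(n_samples)
        tau = tau0 * s[:, None, None] * e1[None]
    elif kind == "rotating":
        ang = 2.0 * np.pi * t / period
        tau = tau0 * (
            np.cos(ang)[:, None, None] * e1[None] + np.sin(ang)[:, None, None] * e2[None]
        )
    elif kind == "biaxial":
        mod = amplitude * np.sin(2.0 * np.pi * t / period)
        tau = tau0 * (e1[None] + mod[:, None, None] * e2[None]) * np.ones((n_samples, 1, 1))
    elif kind == "divergence-switching":
        s = _square_wave(n_samples)
        r_hat = surface.points.copy()
        r_hat[:, 2] = 0.0
        rn = np.linalg.norm(r_hat, axis=1)
        rn[rn == 0] = 1.0
        r_hat /= rn[:, None]
        tau = tau0 * s[:, None, None] * r_hat[None]
    else:
        raise ValueError(f"unknown WSS pattern kind {kind!r}")
    return SurfaceWSSSeries(surface, t, tau, period)


# ---------------------------------------------------------------------------
# Parametric inflow and the toy AVG network


def parametric_inflow(
    q_mean: float = 1.6667e-5,  # m^3/s (~1 L/min access flow)
    period: float = 1.0,
    n_samples: int = 100,
    amplitudes=(0.7, 0.2),
) -> Waveform:
    """Two-harmonic pulsatile flow waveform with a clear systolic peak."""
    t = period * np.arange(n_samples) / n_samples
    v = np.ones_like(t)
    for k, a in enumerate(amplitudes, start=1):
        v = v + a * np.sin(2.0 * np.pi * k * t / period)
    return Waveform(t, q_mean * v, period, units="m^3/s", periodic=True)


def toy_avg_network(
    rho: float = BLOOD_DENSITY,
    venous_pressure: float = 8.0 * MMHG_TO_PA,
    wk3: WK3Params | None = None,
) -> Network0D:
    """Six-segment 0D twin of the graft circuit.

    Topology: inlet (brachial artery) -> anastomosis node; three arterial
    branches with distinct calibres, each ending in an identical WK3 model;
    and the graft path (graft loop, then venous restriction) draining to the
    fixed venous pressure.  Segment coefficients are plausible for a
    ~1 L/min access: the graft path takes ~73% of the mean flow once the
    arterial outlets are calibrated to the 27% split.
    """
    if wk3 is None:
        # pre-calibration placeholder; calibrate_wk3 replaces it
        wk3 = WK3Params(r_p=1.7e9, r_d=2.5e9, c=2.5e-10, p_ref=venous_pressure)

    def seg(name, a_node, b_node, a, b, length, radius):
        area = np.pi * radius**2
        return Segment0D(
            name, a_node, b_node, a=a, b=b,
            L=segment_inertance(length, area, rho), length=length, area=area,
        )

    segments = [
        seg("inlet", "IN", "JA", a=1.0e12, b=5.0e7, length=0.08, radius=2.5e-3),
        seg("arterial_1", "JA", "AO1", a=5.0e12, b=1.5e8, length=0.05, radius=1.6e-3),
        seg("arterial_2", "JA", "AO2", a=5.0e12, b=2.5e8, length=0.05, radius=1.4e-3),
        seg("arterial_3", "JA", "AO3", a=5.0e12, b=4.5e8, length=0.05, radius=1.2e-3),
        seg("graft", "JA", "VR", a=2.0e12, b=2.3e8, length=0.30, radius=3.0e-3),
        seg("venous_restriction", "VR", "VO", a=3.0e12, b=2.3e8, length=0.04, radius=2.0e-3),
    ]
    terminations = {
        "IN": Inflow(),
        "AO1": wk3,
        "AO2": WK3Params(wk3.r_p, wk3.r_d, wk3.c, wk3.p_ref),
        "AO3": WK3Params(wk3.r_p, wk3.r_d, wk3.c, wk3.p_ref),
        "VO": FixedPressure(venous_pressure),
    }
    return Network0D(["IN", "JA", "AO1", "AO2", "AO3", "VR", "VO"], segments, terminations)
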