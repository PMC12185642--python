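"""0D lumped-parameter model of an arteriovenous-graft flow network.

The vascular domain is reduced to a directed graph of segments, each a
nonlinear resistor and inductor in series with pressure drop

    dP(Q) = a*Q|Q| + b*Q + L*dQ/dt

where the quadratic/linear coefficients (a, b) come from fitting pressure
drop against flow over a representative range, and the inertance follows the
large-artery estimate L = (4/3)*rho*l/A.  Arterial outlets terminate in
three-element Windkessel (WK3) models, venous outlets in fixed static
pressures, and the single inlet carries a prescribed pulsatile inflow.

The WK3 state law is  C*dPc/dt = Q - (Pc - P_ref)/R_d  with boundary
pressure  P = Pc + R_p*Q.  Time integration is implicit (backward Euler)
with a Newton solve per step; junction mass balances are enforced inside the
Newton system, so flow conservation holds to solver tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .waveforms import Waveform, cyclic_periodicity_index

MMHG_TO_PA = 133.322


class NetworkError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


class CalibrationError(RuntimeError):
    """Raised when the calibration targets cannot be met; carries the best
    achieved values for inspection."""

    def __init__(self, message, achieved_systolic=None, achieved_split=None):
        super().__init__(message)
        self.achieved_systolic = achieved_systolic
        self.achieved_split = achieved_split


def segment_inertance(length: float, area: float, rho: float) -> float:
    """Inertance of a large-artery segment: L = (4/3) * rho * l / A."""
    if area <= 0:
        raise NetworkError("cross-sectional area must be positive")
    if length < 0 or rho <= 0:
        raise NetworkError("length must be >= 0 and density > 0")
    return (4.0 / 3.0) * rho * length / area


def fit_quadratic_resistance(flows, pressure_drops):
    """Least-squares fit of dP = a*Q^2 + b*Q with zero intercept.

    Returns (a, b, residual_norm).  The zero intercept is physically
    required (no pressure drop at zero flow).
    """
    q = np.asarray(flows, dtype=float)
    dp = np.asarray(pressure_drops, dtype=float)
    if q.ndim != 1 or q.shape != dp.shape or len(q) < 2:
        raise NetworkError("need >= 2 (flow, pressure drop) samples")
    if len(np.unique(q)) < 2:
        raise NetworkError("all flows identical: rank-deficient fit")
    A = np.column_stack([q**2, q])
    coef, res, rank, _ = np.linalg.lstsq(A, dp)
    if rank < 2:
        raise NetworkError("rank-deficient fit")
    resid = float(np.linalg.norm(A @ coef - dp))
    return float(coef[0]), float(coef[1]), resid


@dataclass(frozen=True)
class Segment0D:
    """Resistor-inductor segment between two named nodes.

    a [Pa s^2/m^6] and b [Pa s/m^3] define dP_R(Q) = a*Q|Q| + b*Q; the
    quadratic term uses Q|Q| so the drop opposes reversed flow.  L is the
    inertance [Pa s^2/m^3], optionally derived from (length, area, rho).
    """

    name: str
    node_from: str
    node_to: str
    a: float = 0.0
    b: float = 0.0
    L: float = 0.0
    length: float | None = None
    area: float | None = None

    def __post_init__(self):
        if self.b < 0 or self.L < 0:
            raise NetworkError(f"segment {self.name!r}: b and L must be >= 0")


@dataclass(frozen=True)
class WK3Params:
    """Three-element Windkessel: proximal/distal resistances and compliance."""

    r_p: float  # Pa s/m^3
    r_d: float  # Pa s/m^3
    c: float  # m^3/Pa
    p_ref: float = 0.0  # Pa, distal reference pressure

    def __post_init__(self):
        if self.r_p <= 0 or self.r_d <= 0 or self.c <= 0:
            raise NetworkError("WK3 parameters R_p, R_d, C must be positive")


@dataclass(frozen=True)
class FixedPressure:
    pressure: float  # Pa


@dataclass(frozen=True)
class Inflow:
    """Marker termination: prescribed inflow enters at this node."""


@dataclass
class Network0D:
    """Directed 0D network; every non-inflow boundary node is terminated."""

    nodes: list[str]
    segments: list[Segment0D]
    terminations: dict[str, object]

    def __post_init__(self):
        names = set(self.nodes)
        if len(names) != len(self.nodes):
            raise NetworkError("duplicate node names")
        for s in self.segments:
            if s.node_from not in names or s.node_to not in names:
                raise NetworkError(f"segment {s.name!r}: unknown node")
        inflows = [n for n, t in self.terminations.items() if isinstance(t, Inflow)]
        if len(inflows) != 1:
            raise NetworkError("exactly one inflow node is required")
        self.inflow_node = inflows[0]
        # connectivity + boundary closure
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        degree = {n: 0 for n in self.nodes}
        for s in self.segments:
            adj[s.node_from].add(s.node_to)
            adj[s.node_to].add(s.node_from)
            degree[s.node_from] += 1
            degree[s.node_to] += 1
        seen = {self.inflow_node}
        stack = [self.inflow_node]
        while stack:
            for m in adj[stack.pop()]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        if seen != names:
            raise NetworkError("network is not connected")
        for n in self.nodes:
            if degree[n] == 1 and n not in self.terminations:
                raise NetworkError(f"boundary node {n!r} has no termination")

    @property
    def wk3_nodes(self) -> list[str]:
        return [n for n, t in self.terminations.items() if isinstance(t, WK3Params)]

    @property
    def sink_nodes(self) -> list[str]:
        return [n for n, t in self.terminations.items() if isinstance(t, FixedPressure)]

    def with_wk3(self, params: WK3Params) -> "Network0D":
        """Copy with the same WK3 parameters at every WK3 outlet (the
        calibration convention: identical parameters at each arterial
        outlet, flow split set by the geometric resistances)."""
        terms = dict(self.terminations)
        for n in self.wk3_nodes:
            terms[n] = replace(params, p_ref=self.terminations[n].p_ref)
        return Network0D(list(self.nodes), list(self.segments), terms)


@dataclass
class NetworkSolution:
    """Last simulated cycle of a network run."""

    times: np.ndarray  # (n+1,) spanning exactly one period
    pressures: dict[str, np.ndarray]  # Pa per node
    flows: dict[str, np.ndarray]  # m^3/s per segment
    outlet_flows: dict[str, np.ndarray]  # termination flux per boundary node
    inflow_values: np.ndarray
    outlet_mean_fractions: dict[str, float]
    systolic_inlet_pressure: float  # Pa
    cycle_peaks: np.ndarray  # peak inlet pressure of every simulated cycle
    mass_residual: float  # max junction imbalance / max inflow

    @property
    def converged_cycle(self) -> int:
        return cyclic_periodicity_index(self.cycle_peaks)

    def arterial_split(self, net: Network0D) -> float:
        """Summed cycle-mean WK3 outlet flow as a fraction of mean inflow."""
        return float(sum(self.outlet_mean_fractions[n] for n in net.wk3_nodes))


def _newton_step_system(net, idx_p, idx_q, idx_c, fixed_p, dt):
    """Precompute index arrays for the per-step Newton assembly."""
    n_p, n_q, n_c = len(idx_p), len(idx_q), len(idx_c)
    n = n_p + n_q + n_c
    seg_from = [idx_p.get(s.node_from) for s in net.segments]
    seg_to = [idx_p.get(s.node_to) for s in net.segments]
    return n, seg_from, seg_to


def simulate_network(
    net: Network0D,
    inflow: Waveform,
    dt: float,
    n_cycles: int = 6,
    newton_tol: float = 1e-12,
    max_newton: int = 50,
) -> NetworkSolution:
    """Backward-Euler simulation over ``n_cycles`` cycles; returns the last.

    Junction balances are part of the nonlinear system, so the reported
    ``mass_residual`` reflects pure solver tolerance (<= ~1e-12 of the
    inflow scale in practice).
    """
    T = inflow.period
    nps = max(2, int(round(T / dt)))
    dt = T / nps

    pressure_nodes = [n for n in net.nodes if n not in net.sink_nodes]
    idx_p = {n: i for i, n in enumerate(pressure_nodes)}
    n_p = len(pressure_nodes)
    n_q = len(net.segments)
    wk3_nodes = net.wk3_nodes
    idx_c = {n: n_p + n_q + i for i, n in enumerate(wk3_nodes)}
    n_x = n_p + n_q + len(wk3_nodes)
    fixed_val = {n: net.terminations[n].pressure for n in net.sink_nodes}

    q_scale = max(float(np.abs(inflow.values).max()), 1e-30)
    p_scale = max(
        abs(max((fixed_val.get(n, 0.0) for n in net.nodes), default=0.0)),
        q_scale * max((s.b for s in net.segments), default=1.0),
        1.0,
    )

    seg_from = [idx_p.get(s.node_from) for s in net.segments]
    seg_to = [idx_p.get(s.node_to) for s in net.segments]
    seg_a = np.array([s.a for s in net.segments])
    seg_b = np.array([s.b for s in net.segments])
    seg_L = np.array([s.L for s in net.segments])
    seg_fix_from = np.array([fixed_val.get(s.node_from, 0.0) for s in net.segments])
    seg_fix_to = np.array([fixed_val.get(s.node_to, 0.0) for s in net.segments])

    # initial state: pressures at reference level, zero flow, Pc at p_ref
    x = np.zeros(n_x)
    for n in wk3_nodes:
        x[idx_c[n]] = net.terminations[n].p_ref
        x[idx_p[n]] = net.terminations[n].p_ref
    inlet_i = idx_p[net.inflow_node]

    def residual_and_jac(x, q_prev, pc_prev, q_in):
        R = np.zeros(n_x)
        J = np.zeros((n_x, n_x))
        P = x[:n_p]
        Q = x[n_p : n_p + n_q]
        # segment laws
        for j in range(n_q):
            pu = P[seg_from[j]] if seg_from[j] is not None else seg_fix_from[j]
            pv = P[seg_to[j]] if seg_to[j] is not None else seg_fix_to[j]
            q = Q[j]
            R[n_p + j] = pu - pv - seg_a[j] * q * abs(q) - seg_b[j] * q - seg_L[j] * (
                q - q_prev[j]
            ) / dt
            if seg_from[j] is not None:
                J[n_p + j, seg_from[j]] = 1.0
            if seg_to[j] is not None:
                J[n_p + j, seg_to[j]] = -1.0
            J[n_p + j, n_p + j] = -(2.0 * seg_a[j] * abs(q) + seg_b[j] + seg_L[j] / dt)
        # node balances (non-sink nodes)
        for j, s in enumerate(net.segments):
            for node, sign in ((s.node_from, -1.0), (s.node_to, 1.0)):
                i = idx_p.get(node)
                if i is not None:
                    R[i] += sign * Q[j]
                    J[i, n_p + j] += sign
        R[inlet_i] += q_in
        for k, n in enumerate(wk3_nodes):
            t = net.terminations[n]
            i, ic = idx_p[n], idx_c[n]
            q_term = (x[i] - x[ic]) / t.r_p
            R[i] -= q_term
            J[i, i] -= 1.0 / t.r_p
            J[i, ic] += 1.0 / t.r_p
            # WK3 state: C dPc/dt = q_term - (Pc - P_ref)/R_d
            R[ic] = t.c * (x[ic] - pc_prev[k]) / dt - q_term + (x[ic] - t.p_ref) / t.r_d
            J[ic, ic] = t.c / dt + 1.0 / t.r_p + 1.0 / t.r_d
            J[ic, i] = -1.0 / t.r_p
        return R, J

    scale = np.empty(n_x)
    scale[:n_p] = q_scale  # node balances have flow units
    scale[n_p : n_p + n_q] = p_scale  # segment laws have pressure units
    scale[n_p + n_q :] = q_scale

    q_prev = x[n_p : n_p + n_q].copy()
    pc_prev = x[n_p + n_q :].copy()

    n_total = nps * n_cycles
    hist_x = np.empty((n_total + 1, n_x))
    hist_x[0] = x
    q_in_hist = np.empty(n_total + 1)
    q_in_hist[0] = inflow(0.0)
    mass_res = 0.0

    for k in range(1, n_total + 1):
        t = k * dt
        q_in = float(inflow(t))
        for it in range(max_newton):
            R, J = residual_and_jac(x, q_prev, pc_prev, q_in)
            err = float(np.abs(R / scale).max())
            if err < newton_tol:
                break
            try:
                dx = np.linalg.solve(J, -R)
            except np.linalg.LinAlgError as e:
                raise ConvergenceError(f"singular Newton system at t={t:.4g}s") from e
            # backtracking line search guards against overshoot of the
            # non-smooth quadratic term near flow reversal
            alpha = 1.0
            while alpha > 1.0 / 256.0:
                R_new, _ = residual_and_jac(x + alpha * dx, q_prev, pc_prev, q_in)
                if float(np.abs(R_new / scale).max()) < err:
                    break
                alpha *= 0.5
            x = x + alpha * dx
        else:
            raise ConvergenceError(f"Newton did not converge at t={t:.4g}s (err={err:.2e})")
        mass_res = max(mass_res, float(np.abs(R[:n_p] / q_scale).max()))
        hist_x[k] = x
        q_in_hist[k] = q_in
        q_prev = x[n_p : n_p + n_q].copy()
        pc_prev = x[n_p + n_q :].copy()

    # per-cycle inlet-pressure peaks
    peaks = np.array(
        [hist_x[c * nps + 1 : (c + 1) * nps + 1, inlet_i].max() for c in range(n_cycles)]
    )
    sl = slice(n_total - nps, n_total + 1)
    times = np.arange(nps + 1) * dt
    pressures = {}
    for n in net.nodes:
        if n in fixed_val:
            pressures[n] = np.full(nps + 1, fixed_val[n])
        else:
            pressures[n] = hist_x[sl, idx_p[n]].copy()
    flows = {s.name: hist_x[sl, n_p + j].copy() for j, s in enumerate(net.segments)}

    outlet_flows = {}
    for n in wk3_nodes:
        t = net.terminations[n]
        outlet_flows[n] = (pressures[n] - hist_x[sl, idx_c[n]]) / t.r_p
    for n in net.sink_nodes:
        q = np.zeros(nps + 1)
        for j, s in enumerate(net.segments):
            if s.node_to == n:
                q += flows[s.name]
            if s.node_from == n:
                q -= flows[s.name]
        outlet_flows[n] = q

    q_in_last = q_in_hist[sl]
    mean_in = float(np.trapezoid(q_in_last, times) / T)
    fractions = {
        n: float(np.trapezoid(q, times) / T / mean_in) for n, q in outlet_flows.items()
    }
    return NetworkSolution(
        times=times,
        pressures=pressures,
        flows=flows,
        outlet_flows=outlet_flows,
        inflow_values=q_in_last,
        outlet_mean_fractions=fractions,
        systolic_inlet_pressure=float(pressures[net.inflow_node].max()),
        cycle_peaks=peaks,
        mass_residual=mass_res,
    )


def calibrate_wk3(
    net: Network0D,
    inflow: Waveform,
    systolic_target: float,
    split_target: float,
    band: float = 0.05,
    rp_fraction: float = 0.4,
    dt: float | None = None,
    n_cycles: int = 6,
    systolic_rtol: float = 0.01,
    x0_log_jitter: np.ndarray | None = None,
) -> WK3Params:
    """Automated WK3 calibration against systolic pressure and flow split.

    Identical WK3 parameters are applied at every arterial outlet; the flow
    split among them is then set by the segment resistances, mirroring the
    clinical tuning procedure.  Two targets (systolic inlet pressure in Pa,
    summed arterial cycle-mean outflow fraction) are matched by adjusting
    (R_total, C) in log space with ``R_p = rp_fraction * R_total``; the
    0.4:0.6 proximal:distal default reflects common practice.  Raises
    :class:`CalibrationError`, reporting the achieved values, when the
    optimum misses the systolic target by more than ``systolic_rtol``
    (relative) or the split target by more than ``band`` (absolute).

    ``x0_log_jitter`` optionally perturbs the log10 starting point (2-vector)
    to probe robustness of the deterministic optimiser.
    """
    wk3_nodes = net.wk3_nodes
    if not wk3_nodes:
        raise NetworkError("network has no WK3 outlets to calibrate")
    if not (0 < split_target <= 1):
        raise NetworkError("split_target must be in (0, 1]")
    T = inflow.period
    if dt is None:
        dt = T / 250.0
    p_ref = net.terminations[wk3_nodes[0]].p_ref
    q_mean = inflow.mean()
    q_out = max(split_target * q_mean / len(wk3_nodes), 1e-30)
    r_tot0 = max((0.85 * systolic_target - p_ref) / q_out, 1e3)
    c0 = 1.5 * T / (0.6 * r_tot0)
    x0 = np.array([np.log10(r_tot0), np.log10(c0)])
    if x0_log_jitter is not None:
        x0 = x0 + np.asarray(x0_log_jitter, dtype=float)

    def make_params(x):
        r_tot = 10.0 ** x[0]
        c = 10.0 ** x[1]
        return WK3Params(rp_fraction * r_tot, (1 - rp_fraction) * r_tot, c, p_ref)

    def run(x):
        sol = simulate_network(net.with_wk3(make_params(x)), inflow, dt, n_cycles)
        split = sum(sol.outlet_mean_fractions[n] for n in wk3_nodes)
        return sol.systolic_inlet_pressure, split

    def residuals(x):
        sys_p, split = run(x)
        return np.array(
            [(sys_p - systolic_target) / systolic_target, (split - split_target) / split_target]
        )

    # bounds keep the optimiser inside the physically meaningful decades
    # (resistance in Pa s/m^3, compliance in m^3/Pa)
    bounds = (np.array([6.0, -13.0]), np.array([13.0, -6.0]))
    x0 = np.clip(x0, bounds[0] + 0.01, bounds[1] - 0.01)
    res = least_squares(
        residuals, x0, bounds=bounds, diff_step=1e-3, xtol=1e-12, ftol=1e-12, gtol=1e-12
    )
    sys_p, split = run(res.x)
    if abs(sys_p - systolic_target) > systolic_rtol * systolic_target or abs(
        split - split_target
    ) > band:
        raise CalibrationError(
            "calibration targets infeasible: achieved systolic "
            f"{sys_p:.1f} Pa (target {systolic_target:.1f}), split {split:.4f} "
            f"(target {split_target:.4f} +/- {band})",
            achieved_systolic=sys_p,
            achieved_split=split,
        )
    return make_params(res.x)


# ---------------------------------------------------------------------------
# YAML-friendly (de)serialisation


def network_to_dict(net: Network0D) -> dict:
    segs = []
    for s in net.segments:
        d = {"name": s.name, "from": s.node_from, "to": s.node_to, "a": s.a, "b": s.b, "L": s.L}
        if s.length is not None:
            d["length"] = s.length
        if s.area is not None:
            d["area"] = s.area
        segs.append(d)
    terms = {}
    for n, t in net.terminations.items():
        if isinstance(t, WK3Params):
            terms[n] = {"type": "wk3", "r_p": t.r_p, "r_d": t.r_d, "c": t.c, "p_ref": t.p_ref}
        elif isinstance(t, FixedPressure):
            terms[n] = {"type": "pressure", "pressure": t.pressure}
        else:
            terms[n] = {"type": "inflow"}
    return {"nodes": list(net.nodes), "segments": segs, "terminations": terms}


def network_from_dict(d: dict) -> Network0D:
    segs = [
        Segment0D(
            name=s["name"],
            node_from=s["from"],
            node_to=s["to"],
            a=float(s.get("a", 0.0)),
            b=float(s.get("b", 0.0)),
            L=float(s.get("L", 0.0)),
            length=s.get("length"),
            area=s.get("area"),
        )
        for s in d["segments"]
    ]
    terms: dict[str, object] = {}
    for n, t in d["terminations"].items():
        if t["type"] == "wk3":
            terms[n] = WK3Params(
                float(t["r_p"]), float(t["r_d"]), float(t["c"]), float(t.get("p_ref", 0.0))
            )
        elif t["type"] == "pressure":
            terms[n] = FixedPressure(float(t["pressure"]))
        elif t["type"] == "inflow":
            terms[n] = Inflow()
        else:
            raise NetworkError(f"unknown termination type {t['type']!r}")
    return Network0D(list(d["nodes"]), segs, terms)
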