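"""Periodic waveforms: resampling, unit conversion, comparison statistics.

A :class:`Waveform` is a scalar periodic time series (inlet velocity, flow
rate or pressure) over one cardiac cycle of period ``T``.  Samples may omit
the wrap point at ``t0 + T``; all cycle integrals close the period with the
first sample (trapezoidal rule with wrap closure).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

NOT_CONVERGED = -1


class WaveformError(ValueError):
    pass


def periodic_trapezoid(times: np.ndarray, values: np.ndarray, period: float, axis: int = 0):
    """Integral of a periodic signal over one full period.

    The signal is sampled at strictly increasing ``times`` spanning at most
    one period; the wrap interval back to ``times[0] + period`` is closed
    with the first sample before applying the trapezoidal rule.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise WaveformError("need at least two time samples")
    if np.any(np.diff(t) <= 0):
        raise WaveformError("times must be strictly increasing")
    if t[-1] - t[0] > period * (1 + 1e-9):
        raise WaveformError("samples span more than one period")
    v = np.moveaxis(v, axis, 0)
    if abs((t[-1] - t[0]) - period) <= 1e-9 * period:
        tt, vv = t, v
    else:
        tt = np.concatenate([t, [t[0] + period]])
        vv = np.concatenate([v, v[:1]], axis=0)
    out = np.trapezoid(vv, tt, axis=0)
    return out


def cycle_mean(times, values, period, axis: int = 0):
    """Time average over one period (trapezoidal with wrap closure)."""
    return periodic_trapezoid(times, values, period, axis=axis) / period


@dataclass(frozen=True)
class Waveform:
    """Scalar periodic time series with unit tag.

    times are in seconds within [0, T]; values carry ``units``
    (one of ``m/s``, ``m^3/s``, ``Pa`` or a user tag).
    """

    times: np.ndarray
    values: np.ndarray
    period: float
    units: str = "m^3/s"
    periodic: bool = True

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.shape != t.shape:
            raise WaveformError("times and values must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise WaveformError("times must be strictly increasing")
        if self.period <= 0:
            raise WaveformError("period must be positive")
        if t[-1] - t[0] > self.period * (1 + 1e-9):
            raise WaveformError("samples span more than one period")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)

    def mean(self) -> float:
        """Cycle-mean value (wrap-closed trapezoid) if periodic, else plain trapezoid."""
        if self.periodic:
            return float(cycle_mean(self.times, self.values, self.period))
        return float(np.trapezoid(self.values, self.times) / (self.times[-1] - self.times[0]))

    def max(self) -> float:
        return float(self.values.max())

    def _spline(self) -> CubicSpline:
        if len(self) < 4:
            raise WaveformError("cubic spline needs at least 4 samples")
        if self.periodic:
            t, v = self.times, self.values
            if abs((t[-1] - t[0]) - self.period) <= 1e-9 * self.period:
                if abs(v[-1] - v[0]) > 1e-9 * (1 + np.abs(v).max()):
                    raise WaveformError("periodic waveform endpoints disagree")
                tt, vv = t, v.copy()
                vv[-1] = vv[0]
            else:
                tt = np.concatenate([t, [t[0] + self.period]])
                vv = np.concatenate([v, v[:1]])
            return CubicSpline(tt, vv, bc_type="periodic")
        # not-a-knot ends keep the interpolant exact for cubic signals
        return CubicSpline(self.times, self.values, bc_type="not-a-knot")

    def __call__(self, t) -> np.ndarray:
        """Evaluate by cubic spline; periodic waveforms wrap modulo T."""
        s = self._spline()
        t = np.asarray(t, dtype=float)
        if self.periodic:
            t0 = self.times[0]
            t = t0 + np.mod(t - t0, self.period)
        return s(t)


def resample_waveform(w: Waveform, dt: float) -> Waveform:
    """Resample onto a uniform grid of spacing ``dt`` over [0, T).

    Cubic-spline interpolation; periodic end conditions when the waveform is
    periodic (the clinical inflow case), not-a-knot otherwise.
    """
    if dt <= 0:
        raise WaveformError("dt must be positive")
    if dt >= w.period:
        raise WaveformError("dt must be smaller than the period")
    n = int(round(w.period / dt))
    t_new = w.times[0] + dt * np.arange(n)
    t_new = t_new[t_new < w.times[0] + w.period * (1 - 1e-12)]
    return Waveform(t_new, w(t_new), w.period, units=w.units, periodic=w.periodic)


def velocity_to_flow(v: Waveform, area: float) -> Waveform:
    """Convert a velocity waveform (m/s) to volumetric flow (m^3/s) via a
    fixed cross-sectional area, as done when deriving flow from Doppler
    velocity traces."""
    if area <= 0:
        raise WaveformError("area must be positive")
    if v.units != "m/s":
        raise WaveformError(f"expected units 'm/s', got {v.units!r}")
    return replace(v, values=v.values * area, units="m^3/s")


@dataclass(frozen=True)
class WaveformComparison:
    """Pointwise percentage-difference statistics between two waveforms.

    mean_pct and sd_pct are the mean and population standard deviation of
    100*(test - reference)/reference over the compared samples; n_excluded
    counts samples dropped because the reference was numerically zero.
    """

    mean_pct: float
    sd_pct: float
    n: int
    n_excluded: int = 0


def waveform_difference_stats(
    reference: Waveform, test: Waveform, eps_rel: float = 1e-6
) -> WaveformComparison:
    """Mean and SD of the pointwise percentage difference on a common grid.

    Samples where ``|reference| < eps_rel * max|reference|`` are excluded
    (the relative difference is undefined there) and counted.
    """
    if len(reference) != len(test) or not np.allclose(
        reference.times, test.times, rtol=0.0, atol=1e-12
    ):
        raise WaveformError("waveforms must share a common resampled time grid")
    ref = reference.values
    tst = test.values
    keep = np.abs(ref) >= eps_rel * np.abs(ref).max()
    if not np.any(keep):
        raise WaveformError("no comparable samples (reference everywhere ~0)")
    d = 100.0 * (tst[keep] - ref[keep]) / ref[keep]
    return WaveformComparison(
        mean_pct=float(d.mean()),
        sd_pct=float(d.std(ddof=0)),
        n=int(keep.sum()),
        n_excluded=int((~keep).sum()),
    )


def cyclic_periodicity_index(peak_values, tol: float = 0.01) -> int:
    """First cycle whose peak differs < ``tol`` (relative) from the previous.

    Mirrors the cyclic-convergence rule used for transient simulations:
    convergence when the peak systolic value changes by less than 1% between
    subsequent cycles.  Cycles are numbered from 1; returns ``NOT_CONVERGED``
    (-1) when no cycle satisfies the rule.
    """
    p = np.asarray(peak_values, dtype=float)
    if len(p) < 2:
        raise WaveformError("need at least two cycles")
    if not np.all(np.isfinite(p)):
        raise WaveformError("non-finite peak value")
    for k in range(1, len(p)):
        if abs(p[k] - p[k - 1]) < tol * abs(p[k - 1]):
            return k + 1
    return NOT_CONVERGED
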