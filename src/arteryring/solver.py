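"""Time integration of the ring equations and peak-response extraction.

The ring ODEs are stiff: the forcing period tcp/t_char is thousands of
characteristic times, while the ring oscillates on the scale of one. The
integrator is therefore restarted at every waveform discontinuity (the
switch times are known a priori), and within each constant-pressure
segment the solution is undamped and smooth.

Peaks are located exactly: turning points of the displacement (v = 0) are
found by the integrator's event machinery, and every derived response
quantity is a smooth function of the attained stretch, so its extremum
over the trace occurs at a turning point, a segment boundary, or t = 0 —
all of which are in the sample set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy.integrate import quad, solve_ivp

from .constitutive import (
    ArteryGeometry,
    normalized_energy,
    normalized_stresses,
    thickness_ratio,
)
from .dynamics import (
    DimensionlessGroups,
    ODEState,
    restoring_term,
)
from .loading import DimensionlessPulse, PressurePulse

__all__ = [
    "SolverSettings",
    "ResponseTrace",
    "ResponseSummary",
    "Peak",
    "simulate",
    "summarize",
    "dimensionalize",
    "linear_closed_form",
    "potential_energy",
    "STRETCH_CAP",
]

#: terminal stretch bound: the Mooney-Rivlin ring grows without bound for
#: normalized systolic pressure >= 1; integration aborts gracefully here.
STRETCH_CAP = 20.0
_COLLAPSE_FLOOR = 1e-3


@dataclass(frozen=True)
class SolverSettings:
    """Stiff-integrator controls.

    ``samples_per_cycle`` sets the density of the equispaced output grid
    per cardiac cycle; turning points are added to it exactly.
    """

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = np.inf
    samples_per_cycle: int = 5000

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")
        if self.samples_per_cycle < 1000:
            raise ValueError("samples_per_cycle must be >= 1000")


@dataclass
class ResponseTrace:
    """Sampled response of one simulation, dimensionless plus derived."""

    groups: DimensionlessGroups
    tau: np.ndarray
    x: np.ndarray
    v: np.ndarray
    p_hat: np.ndarray
    lam_theta: np.ndarray = field(init=False)
    h_over_H: np.ndarray = field(init=False)
    W_norm: np.ndarray = field(init=False)
    stress_theta_norm: np.ndarray = field(init=False)
    stress_z_norm: np.ndarray = field(init=False)
    diverged: bool = False
    termination: Optional[str] = None

    def __post_init__(self):
        g = self.groups
        self.lam_theta = 1.0 + self.x
        self.h_over_H = thickness_ratio(self.lam_theta, g.lam_z0)
        if g.law == "linear":
            # stresses and energy relative to E_theta for the linear ring
            self.W_norm = self.x**2 / 2.0
            self.stress_theta_norm = self.x.copy()
            self.stress_z_norm = self.x.copy()
        else:
            self.W_norm = np.asarray(
                normalized_energy(g.law, g.material_ratio, self.lam_theta, g.lam_z0))
            s_t, s_z = normalized_stresses(
                g.law, g.material_ratio, self.lam_theta, g.lam_z0)
            self.stress_theta_norm = np.asarray(s_t)
            self.stress_z_norm = np.asarray(s_z)

    @property
    def t(self) -> np.ndarray:
        """Physical time [s] (tau rescaled by the characteristic time)."""
        return self.tau * self.groups.t_char_seconds

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.t,
            "tau": self.tau,
            "x": self.x,
            "lam_theta": self.lam_theta,
            "h_over_H": self.h_over_H,
            "W_norm": self.W_norm,
            "stress_theta_norm": self.stress_theta_norm,
            "stress_z_norm": self.stress_z_norm,
            "p_hat": self.p_hat,
        })


class Peak(NamedTuple):
    value: float
    t_peak_s: float
    tau_peak: float


_QUANTITIES = ("ur_over_R", "lam_theta", "h_over_H", "W_norm",
               "stress_theta_norm", "stress_z_norm")


@dataclass
class ResponseSummary:
    """Signed largest-magnitude extrema of each response quantity."""

    peaks: dict
    diverged: bool = False
    termination: Optional[str] = None

    def __getitem__(self, key) -> Peak:
        return self.peaks[key]


def _segment_rhs(groups, p_const):
    # scalar closures: the integrator calls these millions of times, so
    # they avoid any numpy per-call overhead
    law, ratio, lz = groups.law, groups.material_ratio, groups.lam_z0
    if law == "skalak" and groups.order < 3:
        from .dynamics import skalak_polynomial_coeffs

        c = skalak_polynomial_coeffs(ratio, lz)
        order = groups.order
        if order == 0:
            def fun(tau, y):
                x, v = y
                return (v, p_const - c[0] - c[1] * x)
        else:
            def fun(tau, y):
                x, v = y
                g = c[0]
                xk = 1.0
                for k in range(1, order + 1):
                    xk *= x
                    g += c[k] * xk
                return (v, (1.0 + x) * p_const - g)
        return fun
    if law == "linear":
        def fun(tau, y):
            x, v = y
            return (v, p_const - x)
        return fun
    if law == "skalak":
        bc = ratio
        lz2, lz4 = lz * lz, lz**4

        def fun(tau, y):
            x, v = y
            lam = 1.0 + x
            lam2 = lam * lam
            g = (lam / lz) * (0.5 * bc * (lam2 - 1.0)
                              + 0.5 * lz2 * (lam2 * lz2 - 1.0))
            return (v, lam * p_const - g)
        return fun
    if law == "hariton":
        b = ratio
        lz2 = lz * lz

        def fun(tau, y):
            x, v = y
            lam = 1.0 + x
            lam2 = lam * lam
            inv = 1.0 / (lam2 * lz2)
            G = lam2 + lz2 + inv - 3.0
            arg = 0.5 * b * G * G
            if arg > 700.0:
                raise FloatingPointError("Hariton exponent overflow")
            g = (2.0 / lz) * (lam - inv / lam) * G * math.exp(arg)
            return (v, lam * p_const - g)
        return fun
    if law == "mooney_rivlin":
        beta = ratio
        lz2 = lz * lz

        def fun(tau, y):
            x, v = y
            lam = 1.0 + x
            lam3 = lam * lam * lam
            g = (1.0 / lz) * ((0.5 + beta) * (lam - 1.0 / (lam3 * lz2))
                              + (0.5 - beta) * (lam * lz2 - 1.0 / lam3))
            return (v, lam * p_const - g)
        return fun
    raise ValueError(f"unknown law {law!r}")


def simulate(groups: DimensionlessGroups,
             settings: SolverSettings | None = None,
             initial_state: ODEState | None = None) -> ResponseTrace:
    """Integrate a ring problem over its cardiac cycles.

    Default initial conditions: the nonlinear rings start at the reference
    radius at rest (x = v = 0, i.e. axially pre-stretched but radially
    undeformed); the linear ring starts at x = lam_z0 - 1, the displacement
    equivalent of the pre-stretch.
    """
    settings = settings or SolverSettings()
    if initial_state is None:
        x0 = groups.lam_z0 - 1.0 if groups.law == "linear" else 0.0
        initial_state = ODEState(x0, 0.0)

    pulse = DimensionlessPulse(
        groups.p_hat_s, groups.pressure_ratio,
        groups.time_ratio, groups.duty, groups.n_cycles)
    switches = pulse.switch_times()

    def ev_turn(tau, y):
        return y[1]

    def ev_cap(tau, y):
        return (1.0 + y[0]) - STRETCH_CAP

    ev_cap.terminal = True

    def ev_collapse(tau, y):
        return (1.0 + y[0]) - _COLLAPSE_FLOOR

    ev_collapse.terminal = True

    taus, xs, vs = [np.array([0.0])], [np.array([initial_state.x])], [
        np.array([initial_state.v])]
    y0 = np.array([initial_state.x, initial_state.v], dtype=float)
    diverged = False
    termination = None

    for a, b in zip(switches[:-1], switches[1:]):
        p_const = float(pulse((a + b) / 2.0))
        fun = _segment_rhs(groups, p_const)
        n_pts = max(8, int(round(settings.samples_per_cycle
                                 * (b - a) / pulse.period)))
        sol = solve_ivp(
            fun, (a, b), y0,
            method=settings.method,
            rtol=settings.rtol, atol=settings.atol,
            max_step=settings.max_step,
            dense_output=True,
            events=[ev_turn, ev_cap, ev_collapse],
        )
        if not sol.success and sol.status != 1:
            raise RuntimeError(
                f"integration failed on [{a:g}, {b:g}]: {sol.message}; "
                f"last state x={sol.y[0, -1]:.6g}")
        t_end = sol.t[-1]
        grid = np.linspace(a, t_end, n_pts)
        t_all = np.unique(np.concatenate([grid, sol.t_events[0],
                                          [a, t_end]]))
        t_all = t_all[(t_all >= a) & (t_all <= t_end)]
        y_all = sol.sol(t_all)
        # skip the duplicated left endpoint
        taus.append(t_all[1:])
        xs.append(y_all[0, 1:])
        vs.append(y_all[1, 1:])
        y0 = y_all[:, -1].copy()
        if sol.status == 1:  # a terminal event fired
            diverged = len(sol.t_events[1]) > 0
            termination = "stretch_cap" if diverged else "collapse"
            break

    tau = np.concatenate(taus)
    x = np.concatenate(xs)
    v = np.concatenate(vs)
    return ResponseTrace(
        groups=groups, tau=tau, x=x, v=v,
        p_hat=np.asarray(pulse(tau)),
        diverged=diverged, termination=termination)


def summarize(trace: ResponseTrace) -> ResponseSummary:
    """Signed largest-magnitude extremum and its time, per quantity.

    The t = 0 sample is included: for strongly pre-stretched rings the
    reference state itself can carry the peak strain energy.
    """
    series = {
        "ur_over_R": trace.x,
        "lam_theta": trace.lam_theta,
        "h_over_H": trace.h_over_H,
        "W_norm": trace.W_norm,
        "stress_theta_norm": trace.stress_theta_norm,
        "stress_z_norm": trace.stress_z_norm,
    }
    t = trace.t
    peaks = {}
    for name, y in series.items():
        i = _first_peak_index(y)
        peaks[name] = Peak(float(y[i]), float(t[i]), float(trace.tau[i]))
    return ResponseSummary(peaks=peaks, diverged=trace.diverged,
                           termination=trace.termination)


def _first_peak_index(y, rel=1e-4):
    """Index of the first occurrence of the largest-magnitude value.

    The motion is undamped and periodic, so the global extremum recurs
    every cycle of the ring oscillation; the physically quoted peak time
    is its first attainment (within a small relative band that absorbs
    integration drift).
    """
    mag = np.abs(y)
    m = mag.max()
    if m == 0.0:
        return 0
    return int(np.argmax(mag >= m * (1.0 - rel)))


def dimensionalize(trace: ResponseTrace, law, params,
                   geometry: ArteryGeometry) -> dict:
    """Physical peak report [SI + kPa/mm] from a dimensionless trace.

    The Skalak law is two-dimensional (tensions in N/m): Cauchy stress and
    volumetric energy density follow by dividing by the current thickness,
    sigma = T * lam_theta * lam_z0 / H, and likewise for W (reported per
    current volume). The 3-D laws are already volumetric and only need
    their stress scale (a or mu).
    """
    g = trace.groups
    if law == "skalak":
        scale = params.C
        conv = trace.lam_theta * g.lam_z0 / geometry.H
        s_t = trace.stress_theta_norm * scale * conv
        s_z = trace.stress_z_norm * scale * conv
        W = trace.W_norm * scale * conv
    elif law == "hariton":
        s_t = trace.stress_theta_norm * params.a
        s_z = trace.stress_z_norm * params.a
        W = trace.W_norm * params.a
    elif law == "mooney_rivlin":
        s_t = trace.stress_theta_norm * params.mu
        s_z = trace.stress_z_norm * params.mu
        W = trace.W_norm * params.mu
    elif law == "linear":
        # params is E_theta [Pa]
        s_t = trace.stress_theta_norm * params
        s_z = trace.stress_z_norm * params
        W = trace.W_norm * params
    else:
        raise ValueError(f"unknown law {law!r}")

    t = trace.t
    out = {}
    for name, y in [("sigma_theta_Pa", s_t), ("sigma_z_Pa", s_z),
                    ("W_Pa", W), ("ur_m", trace.x * geometry.R),
                    ("ur_over_R", trace.x)]:
        i = _first_peak_index(y)
        out[name] = Peak(float(y[i]), float(t[i]), float(trace.tau[i]))
    return out


def linear_closed_form(E_theta, geometry: ArteryGeometry,
                       pulse: PressurePulse, u0=None,
                       samples_per_cycle=5000):
    """Exact piecewise-harmonic solution of the linear ring model.

    rho0 H u'' = p(t) - (E_theta H / R^2) u — an undamped single-DOF
    oscillator with stiffness E_theta H/R^2 and mass rho0 H per unit area,
    forced by the rectangular pulse. Initial displacement defaults to
    u0 = R (lam_z0 - 1), at rest. Returns (t, u) arrays; state is carried
    continuously across the pressure switches.
    """
    if E_theta <= 0:
        raise ValueError("E_theta must be positive (lam_z0 >= 1 ensures it)")
    geom = geometry
    if u0 is None:
        u0 = geom.R * (geom.lam_z0 - 1.0)
    omega = np.sqrt(E_theta / (geom.rho0 * geom.R**2))
    k = E_theta * geom.H / geom.R**2

    switches = [0.0]
    for c in range(pulse.n_cycles):
        switches += [c * pulse.tcp + pulse.ts, (c + 1) * pulse.tcp]
    t_out, u_out = [np.array([0.0])], [np.array([u0])]
    u, v = float(u0), 0.0
    for a, b in zip(switches[:-1], switches[1:]):
        p = pulse.ps if ((a % pulse.tcp) < pulse.ts - 1e-12) else pulse.pd
        u_stat = p / k
        n = max(8, int(round(samples_per_cycle * (b - a) / pulse.tcp)))
        tt = np.linspace(a, b, n)
        dt = tt - a
        uu = u_stat + (u - u_stat) * np.cos(omega * dt) + (v / omega) * np.sin(omega * dt)
        vv = -(u - u_stat) * omega * np.sin(omega * dt) + v * np.cos(omega * dt)
        t_out.append(tt[1:])
        u_out.append(uu[1:])
        u, v = float(uu[-1]), float(vv[-1])
    return np.concatenate(t_out), np.concatenate(u_out)


def potential_energy(law, material_ratio, lam_z0, x):
    """Potential V(x) = integral of the restoring force from 0 to x.

    On a constant-pressure segment the total v^2/2 + V(x) - p_hat (x +
    x^2/2) is conserved (the system is undamped); used as an integration
    audit.
    """

    def g(s):
        return float(restoring_term(law, material_ratio, lam_z0, s))

    val, _ = quad(g, 0.0, float(x), limit=200)
    return val
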