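"""Dimensionless equations of motion of the pressurized artery ring.

With x = u_r/R the normalized radial displacement and tau = t/t_char the
normalized time, every ring model takes the form

    x'' = (1 + x) p_hat(tau) - g(x)

where g is the law-specific restoring force (normalized circumferential
tension divided by the stretch scale) and p_hat the normalized pressure.
The characteristic times t_Sk, t_H, t_MR absorb geometry, density and the
material stress scale; spectra are parameterized by tcp/t_char.

The Skalak g is an exact cubic polynomial in x, which defines the
truncation hierarchy: order 3 is the full model, orders 2 and 1 drop the
higher powers, and order 0 additionally drops the parametric p_hat*x
coupling, leaving a linear constant-coefficient oscillator whose natural
frequency is the radial resonance frequency of the ring.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from .constitutive import (
    ArteryGeometry,
    HaritonParams,
    MooneyRivlinParams,
    SkalakParams,
    _hariton_exp,
)

__all__ = [
    "DimensionlessGroups",
    "ODEState",
    "characteristic_time",
    "restoring_term",
    "restoring_derivative",
    "skalak_polynomial_coeffs",
    "rhs",
    "natural_frequency_zero_order",
    "static_equilibrium",
    "groups_from_physical",
    "NaturalFrequency",
]

DEFAULT_PRESSURE_RATIO = 10660.0 / 16000.0


class RingCollapseError(RuntimeError):
    """The ring radius reached zero (1 + x <= 0)."""


@dataclass(frozen=True)
class DimensionlessGroups:
    """Complete dimensionless statement of a ring problem.

    Parameters
    ----------
    law : {"skalak", "hariton", "mooney_rivlin", "linear"}
    material_ratio : float
        B/C (Skalak), b (Hariton), beta (Mooney-Rivlin); ignored for the
        linear model.
    p_hat_s : float
        Normalized systolic pressure: ps*R/C, ps*R/(aH), ps*R/(muH), or
        ps*R/(E_theta*H) for the linear model.
    lam_z0 : float
        Longitudinal pre-stretch.
    time_ratio : float
        tcp/t_char — cardiac period over characteristic time.
    duty : float
        Systolic fraction ts/tcp of the cycle.
    pressure_ratio : float
        pd/ps.
    n_cycles : int
    order : int
        Skalak truncation order (0-3); 3 = full. Ignored by other laws.
    tcp_seconds : float
        Physical cycle length [s], used only to report times in seconds.
    """

    law: str
    material_ratio: float = 0.0
    p_hat_s: float = 0.16
    lam_z0: float = 1.0
    time_ratio: float = 2000.0
    duty: float = 0.35
    pressure_ratio: float = DEFAULT_PRESSURE_RATIO
    n_cycles: int = 1
    order: int = 3
    tcp_seconds: float = 1.0

    def __post_init__(self):
        if self.law not in ("skalak", "hariton", "mooney_rivlin", "linear"):
            raise ValueError(f"unknown law {self.law!r}")
        if self.p_hat_s < 0 or self.time_ratio <= 0:
            raise ValueError("p_hat_s >= 0 and time_ratio > 0 required")
        if not 0 < self.duty < 1:
            raise ValueError("duty must lie in (0, 1)")
        if not 0 <= self.pressure_ratio <= 1:
            raise ValueError("pressure_ratio must lie in [0, 1]")
        if self.order not in (0, 1, 2, 3):
            raise ValueError("order must be 0, 1, 2 or 3")
        if self.lam_z0 <= 0:
            raise ValueError("lam_z0 must be positive")

    @property
    def t_char_seconds(self) -> float:
        return self.tcp_seconds / self.time_ratio

    def with_(self, **kw) -> "DimensionlessGroups":
        return replace(self, **kw)


@dataclass
class ODEState:
    """State vector (x = u_r/R, v = dx/dtau)."""

    x: float = 0.0
    v: float = 0.0

    def __post_init__(self):
        if 1.0 + self.x <= 0:
            raise RingCollapseError("ring collapsed: 1 + u_r/R <= 0")


def characteristic_time(law, params, geometry: ArteryGeometry) -> float:
    """Characteristic response time [s] of a ring model.

    t_Sk = sqrt(rho0 R^2 H / (C lam_z0)),
    t_H  = sqrt(rho0 R^2 / (a lam_z0)),
    t_MR = sqrt(rho0 R^2 / (mu lam_z0)).

    These follow from an inertia coefficient rho0*H*R/lam_z0 (constant in
    time by mass conservation) in the radial momentum balance.
    """
    g = geometry
    if law == "skalak":
        return float(np.sqrt(g.rho0 * g.R**2 * g.H / (params.C * g.lam_z0)))
    if law == "hariton":
        return float(np.sqrt(g.rho0 * g.R**2 / (params.a * g.lam_z0)))
    if law == "mooney_rivlin":
        return float(np.sqrt(g.rho0 * g.R**2 / (params.mu * g.lam_z0)))
    if law == "linear":
        # params is the tangent modulus E_theta [Pa] here
        return float(np.sqrt(g.rho0 * g.R**2 / params))
    raise ValueError(f"unknown law {law!r}")


def restoring_term(law, material_ratio, lam_z0, x):
    """Normalized restoring force g(x) of the ring equation of motion.

    lam = 1 + x is the circumferential stretch. The linear model has
    g(x) = x (its stiffness is absorbed into the pressure scale).
    """
    lam = 1.0 + np.asarray(x, dtype=float)
    if np.any(lam <= 0):
        raise RingCollapseError("ring collapsed: 1 + u_r/R <= 0")
    lz = lam_z0
    if law == "skalak":
        bc = material_ratio
        return (lam / lz) * (
            bc / 2.0 * (lam**2 - 1.0) + lz**2 / 2.0 * (lam**2 * lz**2 - 1.0)
        )
    if law == "hariton":
        b = material_ratio
        i1 = lam**2 + lz**2 + 1.0 / (lam**2 * lz**2)
        return (2.0 / lz) * (lam - 1.0 / (lam**3 * lz**2)) * (i1 - 3.0) * _hariton_exp(b, i1)
    if law == "mooney_rivlin":
        beta = material_ratio
        return (1.0 / lz) * (
            (0.5 + beta) * (lam - 1.0 / (lam**3 * lz**2))
            + (0.5 - beta) * (lam * lz**2 - 1.0 / lam**3)
        )
    if law == "linear":
        return np.asarray(x, dtype=float)
    raise ValueError(f"unknown law {law!r}")


def restoring_derivative(law, material_ratio, lam_z0, x):
    """Analytic dg/dx, used for linearized stiffness and frequencies."""
    lam = 1.0 + np.asarray(x, dtype=float)
    if np.any(lam <= 0):
        raise RingCollapseError("ring collapsed: 1 + u_r/R <= 0")
    lz = lam_z0
    if law == "skalak":
        bc = material_ratio
        return (1.0 / lz) * (
            bc / 2.0 * (3.0 * lam**2 - 1.0)
            + lz**2 / 2.0 * (3.0 * lam**2 * lz**2 - 1.0)
        )
    if law == "hariton":
        b = material_ratio
        i1 = lam**2 + lz**2 + 1.0 / (lam**2 * lz**2)
        G = i1 - 3.0
        f = lam - 1.0 / (lam**3 * lz**2)
        fp = 1.0 + 3.0 / (lam**4 * lz**2)
        Gp = 2.0 * lam - 2.0 / (lam**3 * lz**2)
        e = _hariton_exp(b, i1)
        return (2.0 / lz) * e * (fp * G + f * Gp + f * G * b * G * Gp)
    if law == "mooney_rivlin":
        beta = material_ratio
        return (1.0 / lz) * (
            (0.5 + beta) * (1.0 + 3.0 / (lam**4 * lz**2))
            + (0.5 - beta) * (lz**2 + 3.0 / lam**4)
        )
    if law == "linear":
        return np.ones_like(np.asarray(x, dtype=float))
    raise ValueError(f"unknown law {law!r}")


def skalak_polynomial_coeffs(B_over_C, lam_z0):
    """Exact cubic coefficients (c0, c1, c2, c3) of the Skalak g(x).

    g(x) = c0 + c1 x + c2 x^2 + c3 x^3 identically; c1 is the zero-order
    (resonance) stiffness and c0 the pre-stretch load offset.
    """
    lz = lam_z0
    bc = B_over_C
    c0 = (lz**3 - lz) / 2.0
    c1 = bc / lz + 1.5 * lz**3 - lz / 2.0
    c2 = 1.5 * (bc / lz + lz**3)
    c3 = 0.5 * (bc / lz + lz**3)
    return c0, c1, c2, c3


def rhs(law, order, groups: DimensionlessGroups, tau, state, p_hat=None):
    """Right-hand side (dx/dtau, dv/dtau) of the first-order system.

    ``p_hat`` may be a callable of tau or a constant; defaults to the
    rectangular waveform implied by ``groups``. For the Skalak law,
    ``order`` selects the truncation: 3 (full cubic), 2, 1, or 0; order 0
    also drops the parametric p_hat*x load term. Other laws are always
    integrated in full.
    """
    x, v = state
    if p_hat is None:
        from .loading import DimensionlessPulse

        p_hat = DimensionlessPulse(
            groups.p_hat_s, groups.pressure_ratio,
            groups.time_ratio, groups.duty, groups.n_cycles,
        )
    p = p_hat(tau) if callable(p_hat) else p_hat
    if law == "skalak" and order < 3:
        c = skalak_polynomial_coeffs(groups.material_ratio, groups.lam_z0)
        # order 0 keeps the linear stiffness but drops the parametric
        # p_hat * x load; orders 1 and 2 truncate g at x^1 and x^2
        n_keep = max(order, 1)
        g = sum(c[k] * x**k for k in range(n_keep + 1))
        load = p if order == 0 else (1.0 + x) * p
        return v, load - g
    g = restoring_term(law, groups.material_ratio, groups.lam_z0, x)
    if law == "linear":
        # Eq. of motion x'' = p_hat - x in the linear scaling (no p*x term)
        return v, p - g
    return v, (1.0 + x) * p - g


class NaturalFrequency(NamedTuple):
    omega0: float  # [rad/s]
    oscillatory: bool


def natural_frequency_zero_order(law, material_ratio, lam_z0,
                                 t_char) -> NaturalFrequency:
    """Zero-order (linearized about x=0) radial natural frequency.

    omega0 = sqrt(g'(0))/t_char. The Hariton ring has g'(0) = 0 at
    lam_z0 = 1, hence zero zero-order frequency. A negative stiffness
    (Skalak with lam_z0 < 1 and C > 24 B) signals possible material
    instability and is returned flagged non-oscillatory instead of raising.
    """
    k = float(restoring_derivative(law, material_ratio, lam_z0, 0.0))
    if k < 0:
        return NaturalFrequency(0.0, False)
    return NaturalFrequency(float(np.sqrt(k)) / t_char, True)


def static_equilibrium(law, material_ratio, lam_z0, p_hat_const,
                       x_hint=None):
    """Static root x* of (1 + x) p_hat = g(x) under a constant load.

    Raises ValueError when no equilibrium exists in the search bracket
    (e.g. the Mooney-Rivlin ring at lam_z0 = 1 for p_hat >= 1, whose
    response is unbounded).
    """

    def f(x):
        try:
            g = float(restoring_term(law, material_ratio, lam_z0, x))
        except FloatingPointError:
            # Hariton exponent overflow: the restoring force dominates
            g = 1e300
        return (1.0 + x) * p_hat_const - g

    lo, hi = -0.999, 19.0
    xs = np.linspace(lo, hi, 4001)
    vals = np.array([f(x) for x in xs])
    sign = np.sign(vals)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        raise ValueError("no static equilibrium in the admissible range "
                         "(unbounded response regime)")
    # pick the root nearest the hint (or nearest zero displacement)
    x0 = 0.0 if x_hint is None else x_hint
    best = min(idx, key=lambda i: abs(xs[i] - x0))
    return brentq(f, xs[best], xs[best + 1], xtol=1e-14, rtol=1e-15)


def groups_from_physical(law, params, geometry: ArteryGeometry, pulse,
                         order=3) -> DimensionlessGroups:
    """Build the dimensionless problem from physical inputs.

    ``params`` is the law's parameter record (or E_theta [Pa] for the
    linear model); ``pulse`` a :class:`~arteryring.loading.PressurePulse`.
    """
    g = geometry
    t_char = characteristic_time(law, params, g)
    if law == "skalak":
        scale, ratio = params.C / g.R, params.B / params.C
    elif law == "hariton":
        scale, ratio = params.a * g.H / g.R, params.b
    elif law == "mooney_rivlin":
        scale, ratio = params.mu * g.H / g.R, params.beta
    elif law == "linear":
        scale, ratio = params * g.H / g.R, 0.0
    else:
        raise ValueError(f"unknown law {law!r}")
    return DimensionlessGroups(
        law=law,
        material_ratio=ratio,
        p_hat_s=pulse.ps / scale,
        lam_z0=g.lam_z0,
        time_ratio=pulse.tcp / t_char,
        duty=pulse.ts / pulse.tcp,
        pressure_ratio=pulse.pd / pulse.ps if pulse.ps > 0 else 0.0,
        n_cycles=pulse.n_cycles,
        order=order,
        tcp_seconds=pulse.tcp,
    )
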