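"""Pulsatile pressure loading.

The cardiac cycle is idealized as a rectangular two-level wave: systolic
pressure ``ps`` held for ``ts`` seconds, then diastolic pressure ``pd`` for
the remainder of the cycle ``tcp``, repeated periodically. The instantaneous
rise makes this the most conservative (dynamically severest) loading and is
what produces the dynamic overshoot of the ring response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MMHG_TO_PA",
    "mmHg_to_Pa",
    "PressurePulse",
    "pressure_at",
    "DimensionlessPulse",
    "normalized_profile",
]

MMHG_TO_PA = 133.322


def mmHg_to_Pa(x):
    """Convert pressure from mmHg to Pa (1 mmHg = 133.322 Pa)."""
    return np.asarray(x, dtype=float) * MMHG_TO_PA if np.ndim(x) else float(x) * MMHG_TO_PA


@dataclass(frozen=True)
class PressurePulse:
    """Rectangular systole/diastole pressure waveform.

    Defaults are the nominal human values: ps = 120 mmHg = 16 kPa,
    pd = 80 mmHg = 10.66 kPa, systolic phase 0.35 s of a 1 s cycle.
    """

    ps: float = 16000.0
    pd: float = 10660.0
    ts: float = 0.35
    tcp: float = 1.0
    n_cycles: int = 1

    def __post_init__(self):
        if not self.ps >= self.pd >= 0:
            raise ValueError("require ps >= pd >= 0")
        if not 0 < self.ts < self.tcp:
            raise ValueError("require 0 < ts < tcp")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be a positive integer")


def pressure_at(pulse: PressurePulse, t):
    """Pressure [Pa] at time(s) ``t`` >= 0, periodic with period ``tcp``.

    The systolic plateau is the closed interval [0, ts] of each cycle.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    phase = np.mod(t, pulse.tcp)
    p = np.where(phase <= pulse.ts, pulse.ps, pulse.pd)
    return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class DimensionlessPulse:
    """Two-level periodic load in characteristic-time units.

    ``p_hat_s`` is the normalized systolic level (e.g. ps*R/C for the Skalak
    ring), held for a ``duty`` fraction of each period of length ``period``
    (= tcp/t_char); the low level is ``p_hat_s * pressure_ratio``.
    """

    p_hat_s: float
    pressure_ratio: float = 10660.0 / 16000.0
    period: float = 2000.0
    duty: float = 0.35
    n_cycles: int = 1

    def __post_init__(self):
        if self.p_hat_s < 0 or self.period <= 0:
            raise ValueError("p_hat_s >= 0 and period > 0 required")
        if not 0 < self.duty < 1:
            raise ValueError("duty must lie in (0, 1)")
        if not 0 <= self.pressure_ratio <= 1:
            raise ValueError("pressure_ratio must lie in [0, 1]")

    @property
    def p_hat_d(self) -> float:
        return self.p_hat_s * self.pressure_ratio

    def __call__(self, tau):
        tau = np.asarray(tau, dtype=float)
        if np.any(tau < 0):
            raise ValueError("time must be non-negative")
        phase = np.mod(tau, self.period)
        p = np.where(phase <= self.duty * self.period, self.p_hat_s, self.p_hat_d)
        return float(p) if p.ndim == 0 else p

    def switch_times(self, n_cycles=None):
        """Discontinuity instants (tau) over ``n_cycles``, including 0 and end.

        The integrator is restarted at each of these so the stiff solver
        never straddles a jump of the forcing.
        """
        n = self.n_cycles if n_cycles is None else n_cycles
        times = [0.0]
        for k in range(n):
            times.append((k + self.duty) * self.period)
            times.append((k + 1.0) * self.period)
        return np.array(times)


def normalized_profile(pulse: PressurePulse, pressure_scale: float,
                       t_char: float) -> DimensionlessPulse:
    """Collapse a physical pulse into a dimensionless two-level waveform.

    ``pressure_scale`` is the stress-like group the pressure is divided by
    (C/R for the Skalak ring, a*H/R for Hariton, mu*H/R for Mooney-Rivlin),
    and ``t_char`` the characteristic time, so that the returned callable
    satisfies p_hat(tau) = p(tau * t_char)/pressure_scale.
    """
    if pressure_scale <= 0 or t_char <= 0:
        raise ValueError("pressure_scale and t_char must be positive")
    return DimensionlessPulse(
        p_hat_s=pulse.ps / pressure_scale,
        pressure_ratio=pulse.pd / pulse.ps if pulse.ps > 0 else 0.0,
        period=pulse.tcp / t_char,
        duty=pulse.ts / pulse.tcp,
        n_cycles=pulse.n_cycles,
    )
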