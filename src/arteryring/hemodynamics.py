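"""Worked physiological examples and pulse-wave helper relations.

Two benchmark cases from the dynamic-artery literature are built in:

* ``demiray`` — a dog abdominal aorta (Demiray & Vito data): strongly
  pre-stretched (lam_z0 = 1.53), moderate pressures.
* ``humphrey`` — a small artery (Humphrey & Na data) with residual
  circumferential stress modeled as a constant 50 mmHg compressive
  pressure offset, leaving effective systolic/diastolic pressures of
  55/41 mmHg, run over two cardiac cycles.

Also provided are the empirical pulse-wave relations linking the ring
response to arterial distension measurements: the exponential
pressure-area exponent alpha (from simulated or measured systolic and
diastolic stretches, or from age), and the axial-to-radial displacement
ratio of the travelling wall wave.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constitutive import (
    ArteryGeometry,
    HaritonParams,
    MooneyRivlinParams,
    SkalakParams,
)
from .dynamics import DimensionlessGroups, characteristic_time
from .loading import PressurePulse, mmHg_to_Pa
from .solver import SolverSettings, dimensionalize, simulate, summarize

__all__ = [
    "ExampleCase",
    "EXAMPLES",
    "run_example",
    "derived_time_ratio",
    "AlphaInputs",
    "alpha_from_stretches",
    "alpha_from_age",
    "simulated_systolic_diastolic_stretches",
    "AxialInputs",
    "axial_ratio",
]


@dataclass(frozen=True)
class ExampleCase:
    """Benchmark inputs: geometry, pulse, and per-law printed groups.

    ``residual_offset`` [Pa] is subtracted from both systolic and
    diastolic pressure before normalization (a constant-pressure proxy for
    residual circumferential stress; no opening-angle mechanics).
    """

    name: str
    geometry: ArteryGeometry
    pulse_raw: PressurePulse
    residual_offset: float = 0.0
    groups_by_law: dict = field(default_factory=dict)
    lam_z0_warn: float = 1.5  # softening laws unreliable beyond this

    @property
    def pulse(self) -> PressurePulse:
        if self.residual_offset == 0.0:
            return self.pulse_raw
        return PressurePulse(
            ps=self.pulse_raw.ps - self.residual_offset,
            pd=self.pulse_raw.pd - self.residual_offset,
            ts=self.pulse_raw.ts, tcp=self.pulse_raw.tcp,
            n_cycles=self.pulse_raw.n_cycles)


def _build_examples():
    demiray = ExampleCase(
        name="demiray",
        geometry=ArteryGeometry(R=3.46e-3, H=0.68e-3, rho0=1160.0,
                                lam_z0=1.53),
        pulse_raw=PressurePulse(ps=9892.0, pd=3466.0, ts=0.35, tcp=1.0,
                                n_cycles=1),
        groups_by_law={
            "skalak": dict(material_ratio=1.0, p_hat_s=1.16,
                           time_ratio=2187.0),
            "hariton": dict(material_ratio=1.5, p_hat_s=4.19,
                            time_ratio=1143.0),
        },
    )
    humphrey = ExampleCase(
        name="humphrey",
        geometry=ArteryGeometry(R=1.69e-3, H=0.6e-3, rho0=1160.0,
                                lam_z0=1.832),
        pulse_raw=PressurePulse(ps=mmHg_to_Pa(105.0), pd=mmHg_to_Pa(91.0),
                                ts=0.3, tcp=0.8, n_cycles=2),
        residual_offset=mmHg_to_Pa(50.0),
        groups_by_law={
            "skalak": dict(material_ratio=0.5, p_hat_s=4.04,
                           time_ratio=1679.0),
            "hariton": dict(material_ratio=1.5, p_hat_s=111.9,
                            time_ratio=319.0),
        },
    )
    return {c.name: c for c in (demiray, humphrey)}


EXAMPLES = _build_examples()


def _params_from_groups(case: ExampleCase, law: str):
    """Back out the material stress scale from the printed groups."""
    gdict = case.groups_by_law[law]
    geom = case.geometry
    ps = case.pulse.ps
    if law == "skalak":
        C = ps * geom.R / gdict["p_hat_s"]
        return SkalakParams(B=gdict["material_ratio"] * C, C=C)
    if law == "hariton":
        a = ps * geom.R / (gdict["p_hat_s"] * geom.H)
        return HaritonParams(a=a, b=gdict["material_ratio"])
    if law == "mooney_rivlin":
        mu = ps * geom.R / (gdict["p_hat_s"] * geom.H)
        return MooneyRivlinParams(mu=mu, beta=gdict["material_ratio"])
    raise ValueError(f"no groups for law {law!r} in case {case.name!r}")


def derived_time_ratio(case: ExampleCase, law: str) -> float:
    """Recompute tcp/t_char from the data block and the printed pressure
    group alone — a closed-form consistency check of the printed tables."""
    params = _params_from_groups(case, law)
    t_char = characteristic_time(law, params, case.geometry)
    return case.pulse.tcp / t_char


def run_example(case, law: str,
                settings: SolverSettings | None = None) -> dict:
    """Simulate a benchmark case for one law; report groups and physical peaks.

    The printed dimensionless groups are the simulation inputs (they are
    what the original normalization used); material constants are backed
    out of them only to dimensionalize the response. Peaks are reported in
    kPa and mm.
    """
    if isinstance(case, str):
        case = EXAMPLES[case]
    gdict = case.groups_by_law.get(law)
    if gdict is None:
        raise ValueError(f"case {case.name!r} has no groups for law {law!r}")
    if law in ("mooney_rivlin",) and case.geometry.lam_z0 > case.lam_z0_warn:
        import warnings

        warnings.warn(
            f"lam_z0={case.geometry.lam_z0} is outside the validated range "
            f"of the {law} law for this case", stacklevel=2)
    pulse = case.pulse
    groups = DimensionlessGroups(
        law=law,
        material_ratio=gdict["material_ratio"],
        p_hat_s=gdict["p_hat_s"],
        lam_z0=case.geometry.lam_z0,
        time_ratio=gdict["time_ratio"],
        duty=pulse.ts / pulse.tcp,
        pressure_ratio=pulse.pd / pulse.ps,
        n_cycles=pulse.n_cycles,
        tcp_seconds=pulse.tcp,
    )
    params = _params_from_groups(case, law)
    trace = simulate(groups, settings)
    phys = dimensionalize(trace, law, params, case.geometry)
    summ = summarize(trace)
    return {
        "case": case.name,
        "law": law,
        "groups": {
            "material_ratio": groups.material_ratio,
            "p_hat_s": groups.p_hat_s,
            "lam_z0": groups.lam_z0,
            "time_ratio": groups.time_ratio,
            "time_ratio_derived": derived_time_ratio(case, law),
            "duty": groups.duty,
            "pressure_ratio": groups.pressure_ratio,
            "n_cycles": groups.n_cycles,
        },
        "peaks": {
            "ur_over_R": summ["ur_over_R"].value,
            "ur_mm": phys["ur_m"].value * 1e3,
            "sigma_theta_kPa": phys["sigma_theta_Pa"].value / 1e3,
            "sigma_z_kPa": phys["sigma_z_Pa"].value / 1e3,
            "W_kPa": phys["W_Pa"].value / 1e3,
        },
    }


@dataclass(frozen=True)
class AlphaInputs:
    """Pressure ratio and systolic/diastolic circumferential stretches."""

    ps_over_pd: float
    lam_theta_s: float
    lam_theta_d: float

    def __post_init__(self):
        if min(self.ps_over_pd, self.lam_theta_s, self.lam_theta_d) <= 0:
            raise ValueError("all inputs must be positive")
        if self.lam_theta_s < self.lam_theta_d:
            raise ValueError("systolic stretch must be >= diastolic stretch")


def alpha_from_stretches(inputs: AlphaInputs) -> float:
    """Exponential pressure-area exponent from the stretch excursion.

    alpha = ln(ps/pd) / [(lam_s/lam_d)^2 - 1], the exponent of the
    empirical distension law p = pd exp(alpha (A/Ad - 1)).
    """
    ratio2 = (inputs.lam_theta_s / inputs.lam_theta_d) ** 2 - 1.0
    if ratio2 == 0.0:
        raise ZeroDivisionError(
            "equal systolic and diastolic stretches: alpha is undefined "
            "(zero distension)")
    return math.log(inputs.ps_over_pd) / ratio2


def alpha_from_age(age_years: float) -> float:
    """Empirical carotid distension exponent, alpha = 0.42 (1 + 0.0602 age)."""
    if age_years < 0:
        raise ValueError("age must be non-negative")
    return 0.42 * (1.0 + 0.0602 * age_years)


def simulated_systolic_diastolic_stretches(
        p_hat_s, B_over_C, lam_z0, time_ratio=2000.0,
        pressure_ratio=10660.0 / 16000.0,
        settings: SolverSettings | None = None):
    """Quasi-steady systolic/diastolic stretches from a ring simulation.

    The undamped ring overshoots to twice its quasi-steady displacement
    when systole starts abruptly; the pressure-area relation is a
    quasi-steady property, so the systolic stretch is taken as half the
    peak systolic-phase displacement and the diastolic one scales with the
    pressure ratio.
    """
    groups = DimensionlessGroups(
        law="skalak", material_ratio=B_over_C, p_hat_s=p_hat_s,
        lam_z0=lam_z0, time_ratio=time_ratio,
        pressure_ratio=pressure_ratio)
    trace = simulate(groups, settings)
    systole = trace.tau <= groups.duty * groups.time_ratio
    ur_s = float(trace.x[systole].max()) / 2.0
    ur_d = ur_s * pressure_ratio
    return 1.0 + ur_s, 1.0 + ur_d


@dataclass(frozen=True)
class AxialInputs:
    """Inputs of the axial-to-radial wall displacement estimate."""

    nu: float          # Poisson ratio of the wall
    wavelength: float  # longitudinal wavelength [m]
    R: float           # artery radius [m]
    c: float           # pulse phase velocity [m/s]
    cp: float          # plate velocity sqrt(E_theta/((1-nu^2) rho0)) [m/s]

    def __post_init__(self):
        if not 0 <= self.nu <= 0.5:
            raise ValueError("nu must lie in [0, 1/2]")
        if min(self.wavelength, self.R) <= 0 or self.c < 0:
            raise ValueError("lengths must be positive, c non-negative")
        if self.cp <= 0:
            raise ValueError("cp must be positive")


def axial_ratio(inputs: AxialInputs) -> float:
    """Systolic axial-to-radial displacement ratio of the wall wave.

    u_z/u_r = (nu lambda / (2 pi R)) (1 - c^2/cp^2); zero for nu = 0 or
    when the phase velocity reaches the plate velocity.
    """
    return (inputs.nu * inputs.wavelength / (2.0 * math.pi * inputs.R)
            * (1.0 - inputs.c**2 / inputs.cp**2))
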