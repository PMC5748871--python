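"""Hyperelastic constitutive relations for thin-walled artery rings.

Three incompressible laws are implemented, each associated in the
cardiovascular literature with a different wall condition:

* the Skalak membrane law (healthy, convex strain hardening),
* the Hariton/Delfino exponential law (atherosclerotic, strong hardening),
* the Mooney-Rivlin law (aneurysmatic, softening).

All functions work in normalized form — energies and stresses are returned
divided by the law's stress-like scale (``C`` [N/m] for Skalak, ``a`` [Pa]
for Hariton, ``mu`` [Pa] for Mooney-Rivlin) — and accept scalars or numpy
arrays for the stretches.

Kinematics: the ring deforms radially under a fixed axial pre-stretch
``lam_z0``; the circumferential stretch is ``lam_theta = r/R = 1 + u_r/R``
and incompressibility fixes the radial stretch ``lam_r = 1/(lam_theta *
lam_z0)`` (thickness change ``h/H``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArteryGeometry",
    "SkalakParams",
    "HaritonParams",
    "MooneyRivlinParams",
    "KinematicState",
    "green_strains",
    "skalak_invariants",
    "skalak_energy",
    "skalak_tensions",
    "iso_invariants",
    "hariton_energy",
    "hariton_stresses",
    "mr_energy",
    "mr_stresses",
    "thickness_ratio",
    "tangent_modulus",
    "EXP_CAP",
]

#: largest allowed argument of the exponential in the Hariton law; the
#: exponent grows quartically in stretch and silently overflows otherwise.
EXP_CAP = 700.0

LAWS = ("skalak", "hariton", "mooney_rivlin", "linear")


class OverflowGuardError(FloatingPointError):
    """Hariton exponent argument exceeded the configured cap."""


def _check_stretch(*vals):
    for v in vals:
        if np.any(np.asarray(v) <= 0):
            raise ValueError("stretches must be strictly positive")


@dataclass(frozen=True)
class ArteryGeometry:
    """Reference (unloaded, axially pre-stretched) segment geometry.

    Parameters
    ----------
    R : float
        Thickness-averaged reference radius [m].
    H : float
        Reference wall thickness [m].
    rho0 : float
        Wall tissue density [kg/m^3]; conserved under incompressibility.
    lam_z0 : float
        Longitudinal pre-stretch l/L (dimensionless), typically 1-1.9.
    """

    R: float
    H: float
    rho0: float = 1160.0
    lam_z0: float = 1.0

    def __post_init__(self):
        if self.R <= 0 or self.H <= 0 or self.rho0 <= 0 or self.lam_z0 <= 0:
            raise ValueError("geometry fields must be strictly positive")
        if self.H >= self.R:
            warnings.warn(
                "wall thickness H >= radius R: outside the thin-wall regime",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SkalakParams:
    """Skalak membrane moduli B, C [N/m], with C >= B >= 0."""

    B: float
    C: float

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")
        if not 0 <= self.B <= self.C:
            raise ValueError("material stability requires C >= B >= 0")

    @property
    def ratio(self) -> float:
        return self.B / self.C


@dataclass(frozen=True)
class HaritonParams:
    """Exponential-law parameters: stress-like a [Pa], dimensionless b."""

    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be positive")

    @property
    def ratio(self) -> float:
        return self.b


@dataclass(frozen=True)
class MooneyRivlinParams:
    """Mooney-Rivlin shear modulus mu [Pa] and mixing parameter beta.

    beta = 1/2 recovers the neo-Hookean solid; beta must lie in
    [-1/2, 1/2].
    """

    mu: float
    beta: float = 0.0

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if not -0.5 <= self.beta <= 0.5:
            raise ValueError("beta must lie in [-1/2, 1/2]")

    @property
    def ratio(self) -> float:
        return self.beta


@dataclass(frozen=True)
class KinematicState:
    """Triaxial stretch state of the incompressible wall."""

    lam_theta: float
    lam_z0: float
    lam_r: float = field(init=False)

    def __post_init__(self):
        _check_stretch(self.lam_theta, self.lam_z0)
        object.__setattr__(self, "lam_r", 1.0 / (self.lam_theta * self.lam_z0))


def green_strains(lam_theta, lam_z0):
    """Green strains (e_thetatheta, e_zz) = ((lam^2-1)/2, ...)."""
    _check_stretch(lam_theta, lam_z0)
    lt = np.asarray(lam_theta, dtype=float)
    lz = np.asarray(lam_z0, dtype=float)
    return (lt**2 - 1.0) / 2.0, (lz**2 - 1.0) / 2.0


def skalak_invariants(lam_theta, lam_z0):
    """Membrane strain invariants I = lt^2+lz^2-2, II = lt^2 lz^2 - 1."""
    _check_stretch(lam_theta, lam_z0)
    lt = np.asarray(lam_theta, dtype=float)
    lz = np.asarray(lam_z0, dtype=float)
    return lt**2 + lz**2 - 2.0, lt**2 * lz**2 - 1.0


def skalak_energy(B_over_C, lam_theta, lam_z0):
    """Skalak strain energy per reference area, normalized by C.

    W/C = (B/4C)(I^2/2 + I - II) + II^2/8.
    """
    if not 0 <= B_over_C <= 1:
        raise ValueError("B/C must lie in [0, 1]")
    I, II = skalak_invariants(lam_theta, lam_z0)
    return (B_over_C / 4.0) * (I**2 / 2.0 + I - II) + II**2 / 8.0


def skalak_tensions(B_over_C, lam_theta, lam_z0):
    """Membrane tensions (T_theta/C, T_z/C) [dimensionless].

    T_theta/C = (lt/lz)[(B/2C)(lt^2-1) + (lz^2/2)(lt^2 lz^2 - 1)] and the
    z-tension with theta and z roles exchanged. For B/C = 0 the two are
    equal. Cauchy stress follows as sigma = T * lt * lz / H.
    """
    _check_stretch(lam_theta, lam_z0)
    if not 0 <= B_over_C <= 1:
        raise ValueError("B/C must lie in [0, 1]")
    lt = np.asarray(lam_theta, dtype=float)
    lz = np.asarray(lam_z0, dtype=float)
    common = (lt**2 * lz**2 - 1.0) / 2.0
    t_theta = (lt / lz) * (B_over_C / 2.0 * (lt**2 - 1.0) + lz**2 * common)
    t_z = (lz / lt) * (B_over_C / 2.0 * (lz**2 - 1.0) + lt**2 * common)
    return t_theta, t_z


def iso_invariants(lam_theta, lam_z0):
    """Isochoric invariants (I1, I2) of the incompressible stretch state."""
    _check_stretch(lam_theta, lam_z0)
    lt = np.asarray(lam_theta, dtype=float)
    lz = np.asarray(lam_z0, dtype=float)
    i1 = lt**2 + lz**2 + 1.0 / (lt**2 * lz**2)
    i2 = lt**2 * lz**2 + 1.0 / lz**2 + 1.0 / lt**2
    return i1, i2


def _hariton_exp(b, i1):
    arg = (b / 2.0) * (i1 - 3.0) ** 2
    if np.any(arg > EXP_CAP):
        raise OverflowGuardError(
            f"Hariton exponent argument exceeds {EXP_CAP}; "
            "the stretch state is far outside the law's range"
        )
    return np.exp(arg)


def hariton_energy(b, lam_theta, lam_z0):
    """Exponential strain energy per volume, normalized by a.

    W/a = (1/b)[exp((b/2)(I1-3)^2) - 1]; zero iff the state is undeformed.
    """
    if b <= 0:
        raise ValueError("b must be positive")
    i1, _ = iso_invariants(lam_theta, lam_z0)
    return (_hariton_exp(b, i1) - 1.0) / b


def hariton_stresses(b, lam_theta, lam_z0):
    """Cauchy stresses (sigma_theta/a, sigma_z/a) for the Hariton law.

    The hydrostatic pressure is eliminated with the thin-wall, traction-free
    outer surface condition (sigma_rr = 0).
    """
    if b <= 0:
        raise ValueError("b must be positive")
    lt = np.asarray(lam_theta, dtype=float)
    lz = np.asarray(lam_z0, dtype=float)
    i1, _ = iso_invariants(lt, lz)
    e = _hariton_exp(b, i1)
    inv = 1.0 / (lt**2 * lz**2)
    s_t = 2.0 * (lt**2 - inv) * (i1 - 3.0) * e
    s_z = 2.0 * (lz**2 - inv) * (i1 - 3.0) * e
    return s_t, s_z


def mr_energy(beta, lam_theta, lam_z0):
    """Mooney-Rivlin strain energy per volume, normalized by mu."""
    if not -0.5 <= beta <= 0.5:
        raise ValueError("beta must lie in [-1/2, 1/2]")
    i1, i2 = iso_invariants(lam_theta, lam_z0)
    return 0.5 * ((0.5 + beta) * (i1 - 3.0) + (0.5 - beta) * (i2 - 3.0))


def mr_stresses(beta, lam_theta, lam_z0):
    """Cauchy stresses (sigma_theta/mu, sigma_z/mu), sigma_rr = 0.

    Derived as sigma_i - sigma_rr for the incompressible solid; in the
    absence of axial pre-stretch (lam_z0 = 1) beta drops out entirely.
    """
    if not -0.5 <= beta <= 0.5:
        raise ValueError("beta must lie in [-1/2, 1/2]")
    _check_stretch(lam_theta, lam_z0)
    lt = np.asarray(lam_theta, dtype=float)
    lz = np.asarray(lam_z0, dtype=float)
    inv = 1.0 / (lt**2 * lz**2)
    s_t = (0.5 + beta) * (lt**2 - inv) + (0.5 - beta) * (lt**2 * lz**2 - 1.0 / lt**2)
    s_z = (0.5 + beta) * (lz**2 - inv) + (0.5 - beta) * (lt**2 * lz**2 - 1.0 / lz**2)
    return s_t, s_z


def thickness_ratio(lam_theta, lam_z0):
    """Current-to-reference wall thickness h/H = 1/(lam_theta lam_z0)."""
    _check_stretch(lam_theta, lam_z0)
    lt = np.asarray(lam_theta, dtype=float)
    lz = np.asarray(lam_z0, dtype=float)
    return 1.0 / (lt * lz)


def tangent_modulus(law, params, H=None, lam_z0=1.0):
    """Initial tangent circumferential Young's modulus [Pa].

    Defined as d(sigma_thetatheta)/d(lam_theta) at lam_theta = 1 for the
    given axial pre-stretch, with the radial stretch slaved to
    incompressibility. Used to build the equivalent linear ring model.

    Closed forms per law:

    * Skalak (membrane, needs ``H``): (B + 2 C lz^4 - C lz^2)/H
    * Hariton: 4 a exp((b/2)D^2) [ (1 + 1/lz^2) D + (1 - 1/lz^2)^2 (1 + b D^2) ],
      D = lz^2 + 1/lz^2 - 2; vanishes at lz = 1
    * Mooney-Rivlin: 2 mu [ (1/2+beta)(1 + 1/lz^2) + (1/2-beta)(1 + lz^2) ]
    """
    if lam_z0 <= 0:
        raise ValueError("lam_z0 must be positive")
    lz = float(lam_z0)
    if law == "skalak":
        if H is None or H <= 0:
            raise ValueError("Skalak tangent modulus requires H > 0")
        return (params.B + 2.0 * params.C * lz**4 - params.C * lz**2) / H
    if law == "hariton":
        D = lz**2 + 1.0 / lz**2 - 2.0
        e = np.exp((params.b / 2.0) * D**2)
        return 4.0 * params.a * e * (
            (1.0 + 1.0 / lz**2) * D
            + (1.0 - 1.0 / lz**2) ** 2 * (1.0 + params.b * D**2)
        )
    if law == "mooney_rivlin":
        return 2.0 * params.mu * (
            (0.5 + params.beta) * (1.0 + 1.0 / lz**2)
            + (0.5 - params.beta) * (1.0 + lz**2)
        )
    raise ValueError(f"unknown law {law!r}")


def normalized_energy(law, material_ratio, lam_theta, lam_z0):
    """Dispatch the normalized strain energy for a law by name."""
    if law == "skalak":
        return skalak_energy(material_ratio, lam_theta, lam_z0)
    if law == "hariton":
        return hariton_energy(material_ratio, lam_theta, lam_z0)
    if law == "mooney_rivlin":
        return mr_energy(material_ratio, lam_theta, lam_z0)
    raise ValueError(f"unknown law {law!r}")


def normalized_stresses(law, material_ratio, lam_theta, lam_z0):
    """Dispatch normalized (theta, z) tensions/stresses for a law by name.

    Skalak returns membrane tensions over C; the 3-D laws return Cauchy
    stresses over their stress scale.
    """
    if law == "skalak":
        return skalak_tensions(material_ratio, lam_theta, lam_z0)
    if law == "hariton":
        return hariton_stresses(material_ratio, lam_theta, lam_z0)
    if law == "mooney_rivlin":
        return mr_stresses(material_ratio, lam_theta, lam_z0)
    raise ValueError(f"unknown law {law!r}")
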