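"""Constitutive relations: frozen examples and energy-stress consistency."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from arteryring.constitutive import (
    ArteryGeometry,
    HaritonParams,
    KinematicState,
    MooneyRivlinParams,
    SkalakParams,
    green_strains,
    hariton_energy,
    hariton_stresses,
    iso_invariants,
    mr_energy,
    mr_stresses,
    skalak_energy,
    skalak_invariants,
    skalak_tensions,
    tangent_modulus,
    thickness_ratio,
)

LT = st.floats(0.8, 1.8)
LZ = st.floats(1.0, 1.9)


class TestKinematics:
    @pytest.mark.parametrize("lt, lz, expected", [
        ((1.0, 1.0), None, (0.0, 0.0)),
        ((1.2, 1.0), None, (0.22, 0.0)),
        ((1.0, 1.53), None, (0.0, 0.67045)),
    ])
    def test_green_strains(self, lt, lz, expected):
        del lz
        e_t, e_z = green_strains(*lt)
        assert e_t == pytest.approx(expected[0], abs=1e-12)
        assert e_z == pytest.approx(expected[1], abs=1e-5)

    @pytest.mark.parametrize("args, expected", [
        ((1.0, 1.0), (0.0, 0.0)),
        ((1.0, 1.2), (0.44, 0.44)),
        ((1.06, 1.53), (1.4645, 1.6302)),
    ])
    def test_skalak_invariants(self, args, expected):
        I, II = skalak_invariants(*args)
        assert I == pytest.approx(expected[0], abs=1e-4)
        assert II == pytest.approx(expected[1], abs=1e-4)

    @pytest.mark.parametrize("args, expected", [
        ((1.0, 1.0), (3.0, 3.0)),
        ((1.0, 1.25), (3.2025, 3.2025)),
        ((1.42, 1.53), (4.5692, None)),
    ])
    def test_iso_invariants(self, args, expected):
        i1, i2 = iso_invariants(*args)
        assert i1 == pytest.approx(expected[0], abs=1e-4)
        if expected[1] is not None:
            assert i2 == pytest.approx(expected[1], abs=1e-4)

    @pytest.mark.parametrize("args, expected", [
        ((1.0, 1.0), 1.0),
        ((1.06, 1.53), 0.6166),
        ((2.0, 0.5), 1.0),
    ])
    def test_thickness_ratio(self, args, expected):
        assert thickness_ratio(*args) == pytest.approx(expected, abs=1e-4)

    def test_rejects_nonpositive_stretch(self):
        with pytest.raises(ValueError):
            green_strains(-1.0, 1.0)
        with pytest.raises(ValueError):
            iso_invariants(1.0, 0.0)

    @given(lt=LT, lz=LZ)
    @hyp_settings(max_examples=50, derandomize=True)
    def test_incompressibility_product(self, lt, lz):
        state = KinematicState(lam_theta=lt, lam_z0=lz)
        assert state.lam_theta * state.lam_r * state.lam_z0 == pytest.approx(
            1.0, abs=1e-12)

    @given(lt=LT, lz=LZ)
    @hyp_settings(max_examples=50, derandomize=True)
    def test_iso_invariants_bounded_below_by_three(self, lt, lz):
        i1, i2 = iso_invariants(lt, lz)
        assert i1 >= 3.0 - 1e-12 and i2 >= 3.0 - 1e-12


class TestEnergies:
    @pytest.mark.parametrize("bc, lt, lz, expected", [
        (0.0, 1.0, 1.0, 0.0),
        (1.0, 1.0, 1.0, 0.0),
        (0.0, 1.0, 1.2, 0.0242),
        (0.5, 1.0, 1.2, 0.0363),
    ])
    def test_skalak_energy(self, bc, lt, lz, expected):
        assert skalak_energy(bc, lt, lz) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("b, lt, lz, expected", [
        (1.5, 1.0, 1.0, 0.0),
        (15.0, 1.0, 1.0, 0.0),
        (1.5, 1.42, 1.53, 3.559),
    ])
    def test_hariton_energy(self, b, lt, lz, expected):
        assert hariton_energy(b, lt, lz) == pytest.approx(expected, abs=2e-3)

    def test_hariton_energy_matches_direct_formula(self):
        b, lt, lz = 15.0, 1.0, 1.1
        i1 = lt**2 + lz**2 + 1.0 / (lt**2 * lz**2)
        expected = (np.exp(7.5 * (i1 - 3.0) ** 2) - 1.0) / 15.0
        assert hariton_energy(b, lt, lz) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("beta, lt, lz, expected", [
        (0.0, 1.0, 1.0, 0.0),
        (0.0, 1.0, 1.25, 0.10125),
        (-0.5, 1.0, 1.25, 0.10125),
        (0.0, 1.21, 1.0, 0.0736),
    ])
    def test_mr_energy(self, beta, lt, lz, expected):
        assert mr_energy(beta, lt, lz) == pytest.approx(expected, abs=5e-5)

    @given(lt=LT, lz=LZ)
    @hyp_settings(max_examples=50, derandomize=True)
    def test_energies_positive_away_from_reference(self, lt, lz):
        if abs(lt - 1) < 1e-6 and abs(lz - 1) < 1e-6:
            return
        assert skalak_energy(0.5, lt, lz) > 0
        assert hariton_energy(5.0, lt, lz) > 0
        assert mr_energy(0.2, lt, lz) > 0

    def test_hariton_overflow_guard(self):
        with pytest.raises(FloatingPointError):
            hariton_energy(100.0, 3.0, 1.9)


class TestStresses:
    @pytest.mark.parametrize("bc, lt, lz, expected", [
        (0.0, 1.0, 1.0, (0.0, 0.0)),
        (0.0, 1.2, 1.0, (0.264, 0.264)),
    ])
    def test_skalak_tensions(self, bc, lt, lz, expected):
        t_t, t_z = skalak_tensions(bc, lt, lz)
        assert t_t == pytest.approx(expected[0], abs=1e-4)
        assert t_z == pytest.approx(expected[1], abs=1e-4)

    def test_skalak_demiray_state(self):
        # tension at the Demiray-case peak state, feeding the 96.7 kPa chain
        t_t, _ = skalak_tensions(1.0, 1.06, 1.53)
        sigma_kpa = t_t * (9892 * 3.46e-3 / 1.16) * 1.06 * 1.53 / 0.68e-3 / 1e3
        assert t_t == pytest.approx(1.365, abs=5e-3)
        assert sigma_kpa == pytest.approx(96.7, rel=0.01)

    @given(lt=LT, lz=LZ)
    @hyp_settings(max_examples=50, derandomize=True)
    def test_skalak_isotropic_limit_equal_tensions(self, lt, lz):
        t_t, t_z = skalak_tensions(0.0, lt, lz)
        assert t_t == pytest.approx(t_z, rel=1e-12, abs=1e-12)

    def test_hariton_stress_value(self):
        s_t, _ = hariton_stresses(1.5, 1.42, 1.53)
        assert s_t == pytest.approx(35.90, abs=0.05)

    @given(lt=LT, lz=st.floats(1.0, 1.5), beta=st.floats(-0.5, 0.5))
    @hyp_settings(max_examples=50, derandomize=True)
    def test_mr_beta_irrelevant_without_prestretch(self, lt, lz, beta):
        del lz
        ref = mr_stresses(0.0, lt, 1.0)
        alt = mr_stresses(beta, lt, 1.0)
        assert ref[0] == pytest.approx(alt[0], rel=1e-12, abs=1e-12)
        assert mr_energy(beta, lt, 1.0) == pytest.approx(
            mr_energy(0.0, lt, 1.0), rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("law", ["skalak", "hariton", "mooney_rivlin"])
    def test_stress_is_energy_derivative(self, law):
        # sigma_theta = lam_theta dW/dlam_theta at fixed lam_z0, with the
        # radial stretch slaved to incompressibility (already eliminated
        # in the W(lam_theta, lam_z0) parameterization)
        rng = np.random.default_rng(42)
        h = 1e-6
        for _ in range(20):
            lt = rng.uniform(0.85, 1.7)
            lz = rng.uniform(1.0, 1.8)
            if law == "skalak":
                ratio, energy, stress = 0.7, skalak_energy, skalak_tensions
                # membrane law: T_theta = (lt/lz) dW/de_theta; as a
                # lam-derivative T_theta = (1/lz) dW/dlt
                num = (energy(ratio, lt + h, lz) - energy(ratio, lt - h, lz)) / (2 * h)
                expected = num / lz
            elif law == "hariton":
                ratio, energy, stress = 2.5, hariton_energy, hariton_stresses
                num = (energy(ratio, lt + h, lz) - energy(ratio, lt - h, lz)) / (2 * h)
                expected = lt * num
            else:
                ratio, energy, stress = 0.3, mr_energy, mr_stresses
                num = (energy(ratio, lt + h, lz) - energy(ratio, lt - h, lz)) / (2 * h)
                expected = lt * num
            got = stress(ratio, lt, lz)[0]
            assert got == pytest.approx(expected, rel=2e-6), (lt, lz)


class TestTangentModulus:
    def test_closed_forms_at_unit_prestretch(self):
        assert tangent_modulus(
            "mooney_rivlin", MooneyRivlinParams(mu=1e4, beta=0.3)
        ) == pytest.approx(4e4, rel=1e-12)
        assert tangent_modulus(
            "hariton", HaritonParams(a=4e4, b=10.0)) == pytest.approx(0.0)
        assert tangent_modulus(
            "skalak", SkalakParams(B=2.0, C=5.0), H=1e-3
        ) == pytest.approx(7.0 / 1e-3, rel=1e-12)

    @pytest.mark.parametrize("law, params", [
        ("skalak", SkalakParams(B=3.0, C=10.0)),
        ("hariton", HaritonParams(a=44.2e3, b=16.7)),
        ("mooney_rivlin", MooneyRivlinParams(mu=3e4, beta=-0.2)),
    ])
    @pytest.mark.parametrize("lz", [1.0, 1.2, 1.5])
    def test_matches_finite_difference_of_cauchy_stress(self, law, params, lz):
        H = 0.68e-3
        h = 1e-6

        def sigma(lt):
            if law == "skalak":
                t_t, _ = skalak_tensions(params.ratio, lt, lz)
                return t_t * params.C * lt * lz / H
            if law == "hariton":
                return hariton_stresses(params.b, lt, lz)[0] * params.a
            return mr_stresses(params.beta, lt, lz)[0] * params.mu

        fd = (sigma(1.0 + h) - sigma(1.0 - h)) / (2 * h)
        got = tangent_modulus(law, params, H=H, lam_z0=lz)
        assert got == pytest.approx(fd, rel=1e-6, abs=1e-4)


class TestParameterRecords:
    def test_invariant_enforcement(self):
        with pytest.raises(ValueError):
            SkalakParams(B=2.0, C=1.0)
        with pytest.raises(ValueError):
            HaritonParams(a=-1.0, b=2.0)
        with pytest.raises(ValueError):
            MooneyRivlinParams(mu=1.0, beta=0.7)
        with pytest.raises(ValueError):
            ArteryGeometry(R=-1e-3, H=1e-4)

    def test_thin_wall_warning(self):
        with pytest.warns(UserWarning):
            ArteryGeometry(R=1e-3, H=2e-3)
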