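import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from plaquemech.materials import (
    DeformationOutOfRangeError, DeformationState, MaterialParams,
    MaterialRegistry, _incompressible_energy, cauchy_stress, default_registry,
    fiber_energy, fiber_invariant, strain_energy_aniso, strain_energy_iso,
    stress_stretch_curve, volumetric_penalty,
)

ALL_MATERIALS = ["intima", "media", "adventitia", "lipid", "calcification"]


class TestEnergies:
    def test_zero_at_reference_for_every_material(self, registry):
        state = DeformationState(np.eye(3), lam_theta=1.0, lam_z=1.0)
        for name in ALL_MATERIALS:
            assert strain_energy_iso(state, registry[name]) == 0.0
            assert strain_energy_aniso(state, registry[name]) == 0.0

    def test_lipid_energy_closed_form(self, registry):
        # I1 = 3.2 via uniaxial-in-x stretch; c2 = 0 so I2 is irrelevant
        state = DeformationState(np.diag([np.sqrt(1.2), 1.0, 1.0]))
        assert state.I1 == pytest.approx(3.2)
        expected = 0.5 * 0.2 + 0.5 * (math.exp(1.5 * 0.2) - 1.0)
        assert strain_energy_iso(state, registry["lipid"]) == pytest.approx(expected, rel=1e-12)

    def test_calcification_ignores_second_invariant(self, registry):
        # c2 = 0: energy must equal the I1-only closed form on any state
        p = registry["calcification"]
        state = DeformationState(np.diag([1.1, 0.95, 1.02]))
        expected = p.c1 * (state.I1 - 3) + p.D1 * (math.exp(p.D2 * (state.I1 - 3)) - 1)
        assert strain_energy_iso(state, p) == pytest.approx(expected, rel=1e-12)

    def test_media_fiber_term_closed_form(self, registry):
        state = DeformationState(np.eye(3))
        w = strain_energy_aniso(state, registry["media"], I4=1.05)
        assert w == pytest.approx(7.0 / 4.0 * (math.exp(4 * 0.05**2) - 1.0), rel=1e-12)

    def test_fiber_term_vanishes_at_i4_one(self, registry):
        state = DeformationState(np.diag([1.1, 1 / 1.1, 1.0]))
        p = registry["media"]
        assert strain_energy_aniso(state, p, I4=1.0) == strain_energy_iso(state, p)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.5, 1.8))
    def test_fiber_energy_nonnegative(self, i4):
        p = default_registry()["adventitia"]
        assert fiber_energy(i4, p) >= 0.0

    def test_overflow_guard(self, registry):
        state = DeformationState(np.diag([3.0, 1.0, 1.0]))
        with pytest.raises(DeformationOutOfRangeError):
            strain_energy_iso(state, registry["intima"])


class TestFiberInvariant:
    def test_circumferential_fibers(self):
        assert fiber_invariant(1.2, 0.7, 0.0) == pytest.approx(1.44)

    def test_axial_fibers(self):
        assert fiber_invariant(1.3, 1.05, 90.0) == pytest.approx(1.1025)

    def test_media_angle_against_trig_oracle(self):
        phi = math.radians(24.9)
        expected = 1.1**2 * math.cos(phi) ** 2 + 1.05**2 * math.sin(phi) ** 2
        assert fiber_invariant(1.1, 1.05, 24.9) == pytest.approx(expected, rel=1e-14)

    def test_positive_stretch_required(self):
        with pytest.raises(ValueError):
            fiber_invariant(-1.0, 1.0, 10.0)


class TestCauchyStress:
    def test_zero_at_identity(self, registry):
        for name in ALL_MATERIALS:
            sig = cauchy_stress(np.eye(3), registry[name])
            assert np.abs(sig).max() < 1e-10

    def test_symmetry_for_random_states(self, registry):
        rng = np.random.default_rng(12)
        for _ in range(20):
            F = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
            if np.linalg.det(F) <= 0:
                continue
            sig = cauchy_stress(F, registry["media"])
            assert np.abs(sig - sig.T).max() < 1e-10

    def test_inverted_state_rejected(self, registry):
        with pytest.raises(ValueError, match="positive"):
            cauchy_stress(np.diag([-1.0, 1.0, 1.0]), registry["lipid"])

    @pytest.mark.parametrize("name", ALL_MATERIALS)
    def test_energy_consistency_finite_difference(self, registry, name):
        """sigma_ii - sigma_jj equals the stretch derivative of the
        incompressible energy for random isochoric diagonal states."""
        p = registry[name]
        rng = np.random.default_rng(hash(name) % 2**31)
        h = 1e-5
        for _ in range(10):
            lc, lz = rng.uniform(0.9, 1.2, 2)
            lr = 1.0 / (lc * lz)
            sig = cauchy_stress(np.diag([lc, lr, lz]), p)

            def dW(i):
                lam = [lc, lr, lz]
                up, dn = list(lam), list(lam)
                up[i] += h
                dn[i] -= h
                return (_incompressible_energy(p, *up) - _incompressible_energy(p, *dn)) / (2 * h)

            expect = lc * dW(0) - lr * dW(1)
            got = sig[0, 0] - sig[1, 1]
            scale = max(abs(expect), 1.0)
            assert abs(got - expect) / scale < 1e-3

    def test_isotropic_materials_rotation_invariant(self, registry):
        rng = np.random.default_rng(5)
        F = np.diag([1.15, 0.95, 1.0 / (1.15 * 0.95)])
        for name in ("lipid", "calcification"):
            sig = cauchy_stress(F, registry[name])
            for R in Rotation.random(5, rng=rng).as_matrix():
                left = cauchy_stress(R @ F @ R.T, registry[name])
                right = R @ sig @ R.T
                assert np.abs(left - right).max() < 1e-8


class TestStressStretchCurves:
    def test_zero_stress_at_unit_stretch(self, registry):
        for name in ALL_MATERIALS:
            tab = stress_stretch_curve(name, "circumferential", [1.0, 1.1])
            assert tab[0, 1] == 0.0

    @pytest.mark.parametrize("direction", ["circumferential", "axial"])
    def test_strictly_increasing_on_physiologic_range(self, direction):
        grid = np.linspace(1.0, 1.3, 13)
        for name in ALL_MATERIALS:
            tab = stress_stretch_curve(name, direction, grid)
            assert np.all(np.diff(tab[:, 1]) > 0), name

    def test_adventitia_axial_stiffer_than_circumferential(self):
        """Fibers at 75.3 degrees lie near-axial, so the axial curve must
        dominate at moderate stretch."""
        c = stress_stretch_curve("adventitia", "circumferential", [1.15])[0, 1]
        z = stress_stretch_curve("adventitia", "axial", [1.15])[0, 1]
        assert z > c

    def test_stiffness_ordering(self):
        """Before the intima fiber term locks (lambda ~ 1.05) calcification
        is the stiffest tissue; past the lock-up the intima exponential
        dominates.  Lipid is softest throughout."""
        at = lambda n, lam: stress_stretch_curve(n, "circumferential", [lam])[0, 1]
        assert at("calcification", 1.05) > at("intima", 1.05) > at("lipid", 1.05)
        assert at("intima", 1.2) > at("calcification", 1.2) > at("lipid", 1.2)

    def test_grid_outside_range_rejected(self):
        with pytest.raises(ValueError):
            stress_stretch_curve("media", "circumferential", [0.8, 1.0])


class TestRegistry:
    def test_round_trip_json(self, tmp_path, registry):
        path = tmp_path / "mats.json"
        registry.to_json(path)
        back = MaterialRegistry.from_json(path)
        assert back["media"] == registry["media"]
        assert back["wall"] == registry["wall"]

    def test_single_layer_wall_material_configurable(self):
        reg = default_registry(single_layer_material="media")
        assert reg["wall"].c1 == reg["media"].c1

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="D2"):
            MaterialParams("x", c1=1, c2=0, D1=1, D2=-1)
        with pytest.raises(ValueError, match="phi"):
            MaterialParams("x", c1=1, c2=0, D1=1, D2=1, K1=1, K2=1, phi_deg=120)

    def test_penalty_floor_for_soft_components(self, registry):
        assert volumetric_penalty(registry["lipid"]) == 5000.0
        assert volumetric_penalty(registry["intima"]) == pytest.approx(177400.0)
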