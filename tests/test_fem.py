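import numpy as np
import pytest

from plaquemech.cylinder import axisym_cylinder_oracle
from plaquemech.fem import MMHG_TO_KPA, mesh_convergence_study, solve_inflation
from dataclasses import replace

from plaquemech.materials import MaterialRegistry, default_registry
from plaquemech.mesh import build_mesh
from plaquemech.contours import merge_to_single_layer
from plaquemech.synthetic import SyntheticCohortSpec, generate_synthetic_slice

from conftest import circle_contour, concentric_slice


def hoop_component(sol, about=(0.0, 0.0)):
    """Element-centroid hoop stress and deformed radius."""
    c = sol.elem_centroid
    r = np.hypot(c[:, 0] - about[0], c[:, 1] - about[1])
    th = np.arctan2(c[:, 1] - about[1], c[:, 0] - about[0])
    e_c = np.stack([-np.sin(th), np.cos(th), np.zeros_like(th)], axis=1)
    return r, np.einsum("ei,eij,ej->e", e_c, sol.elem_stress, e_c)


def test_zero_load_gives_zero_field(registry, three_layer_slice):
    mesh = build_mesh(three_layer_slice, n_rays=36, n_radial_per_layer=1)
    sol = solve_inflation(mesh, registry, 0.0, 1.0)
    assert np.abs(sol.displacements).max() == 0.0
    assert np.abs(sol.node_stress).max() < 1e-8


def test_converged_residual_below_tolerance(solved_concentric):
    _, sol = solved_concentric
    assert sol.residual_norm < 1e-8 * sol.load_norm


def test_near_incompressibility(solved_concentric):
    _, sol = solved_concentric
    jmin, jmax = sol.j_range
    assert abs(jmin - 1) < 1e-2 and abs(jmax - 1) < 1e-2


def test_global_force_balance(solved_concentric):
    """Internal forces sum to zero identically, the closed-surface pressure
    load has zero resultant, and the free-dof residual is converged; hence
    constrained-face reactions balance the applied load to round-off."""
    _, sol = solved_concentric
    load_scale = np.abs(sol.external_force).sum()
    net_external = sol.external_force.reshape(-1, 3).sum(axis=0)
    assert np.abs(net_external).max() < 1e-9 * load_scale
    reactions = sol.residual.copy()
    reactions[sol.free_dofs] = 0.0
    net = reactions.reshape(-1, 3).sum(axis=0) + net_external
    assert np.abs(net).max() < 1e-6 * load_scale


def test_thin_wall_laplace_limit(registry):
    """Single-layer cylinder with r/t = 20 under small pressure: mean hoop
    stress within 5% of the Laplace estimate p*r/t (deformed geometry)."""
    slc = concentric_slice(radii=(2.0, 2.033, 2.066, 2.1))
    mesh = build_mesh(merge_to_single_layer(slc), n_rays=48, n_radial_per_layer=1)
    reg = MaterialRegistry(single_layer_material="lipid")
    p = 1.0
    sol = solve_inflation(mesh, reg, p, 1.0)
    r_in = sol.lumen_circumference() / (2 * np.pi)
    outer = sol.deformed_nodes[mesh.outer_ring][:, :2]
    r_out = np.hypot(outer[:, 0], outer[:, 1]).mean()
    laplace = p * 0.5 * (r_in + r_out) / (r_out - r_in)
    _, hoop = hoop_component(sol)
    assert hoop.mean() == pytest.approx(laplace, rel=0.05)


def test_three_layer_matches_cylinder_oracle(registry, solved_concentric):
    mesh, sol = solved_concentric
    oracle = axisym_cylinder_oracle(
        [1.5, 1.8, 2.0, 2.3],
        [registry["intima"], registry["media"], registry["adventitia"]],
        100 * MMHG_TO_KPA, 1.05)
    r, hoop = hoop_component(sol)
    ref = oracle.hoop_at(r)
    peak = np.abs(oracle.sigma_theta).max()
    assert np.abs(hoop - ref).max() / peak < 0.05


def test_multilayer_equals_single_layer_when_materials_identical(three_layer_slice):
    """Layer-machinery degeneracy: with intima parameters assigned to all
    three layers the multilayer and single-layer solves on the same mesh
    must coincide node-wise (the layer split is purely notational)."""
    base = default_registry()
    intima = base["intima"]
    reg = MaterialRegistry({
        "intima": intima,
        "media": replace(intima, name="media"),
        "adventitia": replace(intima, name="adventitia"),
        "lipid": base["lipid"], "calcification": base["calcification"],
    }, single_layer_material="intima")
    mesh = build_mesh(three_layer_slice, n_rays=36, n_radial_per_layer=2)
    p = 100 * MMHG_TO_KPA
    sol_multi = solve_inflation(mesh, reg, p, 1.05, layer_mode="multi")
    sol_single = solve_inflation(mesh, reg, p, 1.05, layer_mode="single")
    assert np.abs(sol_multi.displacements - sol_single.displacements).max() < 1e-8
    assert np.abs(sol_multi.sigma_max - sol_single.sigma_max).max() < 1e-6


def test_objectivity_under_rigid_rotation(registry):
    """Rotating the slice by a right angle (which maps both the contour
    sampling and the ray set onto themselves) rotates the solution fields
    exactly."""
    spec = SyntheticCohortSpec(seed=13, lipid_probability=0.0,
                               calcification_probability=0.0)
    slc = generate_synthetic_slice(spec, 0, 0)
    from dataclasses import replace as drep
    R = np.array([[0.0, -1.0], [1.0, 0.0]])

    def rot(c):
        return drep(c, points=c.points @ R.T)

    slc_rot = drep(slc, lumen=rot(slc.lumen), iem=rot(slc.iem),
                   eem=rot(slc.eem), adv=rot(slc.adv))
    p = 90 * MMHG_TO_KPA
    opts = dict(n_rays=36, n_radial_per_layer=1)
    sol_a = solve_inflation(build_mesh(slc, **opts), registry, p, 1.05)
    sol_b = solve_inflation(build_mesh(slc_rot, **opts), registry, p, 1.05)
    # ray k of the rotated mesh sees what ray k - 9 (90 deg) saw originally
    ring_a = sol_a.sigma_max[sol_a.mesh.inner_ring]
    ring_b = sol_b.sigma_max[sol_b.mesh.inner_ring]
    shift = 9  # 90 degrees / (360/36)
    assert np.abs(np.roll(ring_a, shift) - ring_b).max() < 1e-6 * np.abs(ring_a).max()


def test_mesh_convergence_study_terminates(registry, three_layer_slice):
    opts, report, sol = mesh_convergence_study(
        three_layer_slice, registry, 100 * MMHG_TO_KPA, 1.05,
        base_options=dict(n_rays=32, n_radial_per_layer=2, n_slabs=1))
    assert report[-1]["diff"] < 0.02
    assert all(r["diff"] is None or r["diff"] >= 0 for r in report)
    # accepted solution is within 5% of the semi-analytic oracle profile
    oracle = axisym_cylinder_oracle(
        [1.5, 1.8, 2.0, 2.3],
        [registry["intima"], registry["media"], registry["adventitia"]],
        100 * MMHG_TO_KPA, 1.05)
    r, hoop = hoop_component(sol)
    assert np.abs(hoop - oracle.hoop_at(r)).max() / np.abs(oracle.sigma_theta).max() < 0.05


def test_negative_pressure_rejected(registry, three_layer_slice):
    mesh = build_mesh(three_layer_slice, n_rays=36, n_radial_per_layer=1)
    with pytest.raises(ValueError):
        solve_inflation(mesh, registry, -1.0)
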