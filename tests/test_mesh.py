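import numpy as np
import pytest

from plaquemech.contours import Contour, VesselSliceContours, merge_to_single_layer
from plaquemech.mesh import MeshingError, build_mesh
from plaquemech.synthetic import SyntheticCohortSpec, generate_synthetic_slice

from conftest import circle_contour, concentric_slice


def test_element_count_formula(three_layer_slice):
    mesh = build_mesh(three_layer_slice, n_rays=100, n_radial_per_layer=3, n_slabs=2)
    assert mesh.n_elements == 100 * 9 * 2
    assert mesh.n_nodes == 100 * 10 * 3


def test_all_jacobians_positive_on_random_slices():
    spec = SyntheticCohortSpec(seed=21)
    for k in range(5):
        slc = generate_synthetic_slice(spec, 2, k)
        mesh = build_mesh(slc, n_rays=36, n_radial_per_layer=2)
        assert np.all(mesh.element_volumes() > 0)


def test_region_volumes_sum_to_slab_volume(three_layer_slice):
    mesh = build_mesh(three_layer_slice, n_rays=100, n_radial_per_layer=3)
    total = mesh.element_volumes().sum()
    expected = three_layer_slice.wall_area * mesh.thickness
    assert total == pytest.approx(expected, rel=0.005)


def test_layer_band_volumes_match_annuli(three_layer_slice):
    mesh = build_mesh(three_layer_slice, n_rays=100, n_radial_per_layer=3)
    vols = mesh.element_volumes()
    areas = three_layer_slice.layer_areas
    for name in ("intima", "media", "adventitia"):
        v = vols[mesh.region.astype(str) == name].sum()
        assert v == pytest.approx(areas[name] * mesh.thickness, rel=0.005)


def test_lipid_volume_close_to_contour_area():
    """Lipid-labeled element volume tracks the pool contour area; the
    centroid relabeling quantizes to element size, so individual slices may
    deviate by one element band while the slice-averaged ratio is unbiased."""
    spec = SyntheticCohortSpec(seed=5)
    ratios = []
    for k in range(6):
        slc = generate_synthetic_slice(spec, 1, k)
        lipid_area = sum(c.area for c in slc.components if c.label == "lipid")
        assert lipid_area > 0
        mesh = build_mesh(slc, n_rays=144, n_radial_per_layer=5)
        v = mesh.element_volumes()[mesh.region.astype(str) == "lipid"].sum()
        ratios.append(v / (lipid_area * mesh.thickness))
    assert np.abs(np.array(ratios) - 1.0).max() < 0.15
    assert abs(np.mean(ratios) - 1.0) < 0.10


def test_single_layer_mode_labels_and_node_parity(three_layer_slice):
    merged = merge_to_single_layer(three_layer_slice)
    m_multi = build_mesh(three_layer_slice, n_rays=48, n_radial_per_layer=2)
    m_single = build_mesh(merged, n_rays=48, n_radial_per_layer=2)
    assert set(m_single.region.astype(str)) == {"wall"}
    assert m_single.n_nodes == m_multi.n_nodes
    assert m_single.layer_mode == "single"


def test_material_frames_are_orthonormal(three_layer_slice):
    mesh = build_mesh(three_layer_slice, n_rays=48, n_radial_per_layer=2)
    F = mesh.frames
    eye = np.einsum("eij,eik->ejk", F, F)
    assert np.abs(eye - np.eye(3)).max() < 1e-12
    # circumferential column is tangent: orthogonal to the radial direction
    cen = mesh.nodes[mesh.elements][:, :, :2].mean(axis=1) - mesh.centroid
    radial = np.column_stack([cen, np.zeros(len(cen))])
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    assert np.abs(np.einsum("ei,ei->e", F[:, :, 0], radial)).max() < 1e-12


def test_non_star_shaped_slice_raises():
    # horseshoe "lumen": occupies only -120..120 degrees, so rays near 180
    # degrees cross it zero or two times
    th1 = np.linspace(-2.0, 2.0, 24)
    outer = np.column_stack([2 * np.cos(th1), 2 * np.sin(th1)])
    inner = np.column_stack([np.cos(th1), np.sin(th1)])[::-1]
    horseshoe = Contour(np.vstack([outer, inner]), "lumen")
    slc = VesselSliceContours(horseshoe, circle_contour(3.0, "IEM"),
                              circle_contour(3.3, "EEM"), circle_contour(3.6, "ADV"))
    with pytest.raises(MeshingError, match="star-shaped"):
        build_mesh(slc, n_rays=36, n_radial_per_layer=1)


def test_minimum_ray_count_enforced(three_layer_slice):
    with pytest.raises(ValueError, match="n_rays"):
        build_mesh(three_layer_slice, n_rays=16)
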