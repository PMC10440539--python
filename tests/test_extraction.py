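import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plaquemech.contours import Contour
from plaquemech.extraction import (cohort_average, identify_cap_nodes,
                                   patient_max, patient_mean, quarter_divide,
                                   relative_difference)
from plaquemech.synthetic import SyntheticCohortSpec, generate_synthetic_slice

from conftest import circle_contour, concentric_slice


class TestQuarterDivide:
    def test_concentric_pairing_is_radial(self):
        slc = concentric_slice()
        sets = quarter_divide(slc.lumen, slc.adv)
        mism = np.abs(np.angle(np.exp(1j * (sets.lumen_angles - sets.outwall_angles))))
        assert mism.max() < 1e-6

    def test_quarter_sizes_are_25(self):
        slc = concentric_slice()
        sets = quarter_divide(slc.lumen, slc.adv)
        assert sets.n == 100
        np.testing.assert_array_equal(np.bincount(sets.quarter), [25, 25, 25, 25])

    def test_pairing_is_a_bijection(self):
        spec = SyntheticCohortSpec(seed=17)
        slc = generate_synthetic_slice(spec, 0, 0)
        sets = quarter_divide(slc.lumen, slc.adv)
        assert len(np.unique(sets.lumen_points, axis=0)) == sets.n
        assert len(np.unique(sets.outwall_points, axis=0)) == sets.n

    def test_paired_nodes_share_quarter_on_eccentric_slice(self):
        spec = SyntheticCohortSpec(seed=17)
        slc = generate_synthetic_slice(spec, 1, 2)
        sets = quarter_divide(slc.lumen, slc.adv)
        # recompute each out-wall node's quarter from its own angle
        q_out = np.floor(sets.outwall_angles / (np.pi / 2)).astype(int) % 4
        np.testing.assert_array_equal(q_out, sets.quarter)

    def test_anchor_rotates_quarters(self):
        slc = concentric_slice()
        a = quarter_divide(slc.lumen, slc.adv, anchor_deg=0.0)
        b = quarter_divide(slc.lumen, slc.adv, anchor_deg=45.0)
        assert not np.allclose(a.lumen_points, b.lumen_points)

    def test_non_star_shaped_raises(self):
        th1 = np.linspace(-2.0, 2.0, 24)
        outer = np.column_stack([2 * np.cos(th1), 2 * np.sin(th1)])
        inner = np.column_stack([np.cos(th1), np.sin(th1)])[::-1]
        horseshoe = Contour(np.vstack([outer, inner]), "lumen")
        with pytest.raises(ValueError, match="star-shaped"):
            quarter_divide(horseshoe, circle_contour(3.0, "ADV"),
                           centroid=np.array([1.2, 0.0]))


class TestCapNodes:
    def test_no_components_empty_cap(self):
        slc = concentric_slice()
        sets = quarter_divide(slc.lumen, slc.adv)
        assert identify_cap_nodes(sets, slc).sum() == 0

    def test_calcification_does_not_define_a_cap(self):
        from dataclasses import replace
        slc = concentric_slice()
        calc = circle_contour(0.06, "calcification", 16, center=(1.9, 0.0))
        slc = replace(slc, components=(calc,))
        sets = quarter_divide(slc.lumen, slc.adv)
        assert identify_cap_nodes(sets, slc).sum() == 0

    def test_lipid_arc_controls_cap_count(self):
        """Annular-sector lipid pool on a concentric slice: pairing is
        radial, so the cap nodes are exactly the lumen nodes whose angle
        falls in the pool's arc (geometric containment oracle)."""
        from dataclasses import replace
        slc = concentric_slice()
        half = np.deg2rad(45.0)
        th = np.linspace(-half, half, 20)
        inner, outer = 1.65, 1.75
        pts = np.vstack([np.column_stack([inner * np.cos(th), inner * np.sin(th)]),
                         np.column_stack([outer * np.cos(th), outer * np.sin(th)])[::-1]])
        lipid = Contour(pts, "lipid")
        slc = replace(slc, components=(lipid,))
        sets = quarter_divide(slc.lumen, slc.adv)
        mask = identify_cap_nodes(sets, slc)
        ang = np.angle(np.exp(1j * sets.lumen_angles))
        expected = np.abs(ang) <= half
        # the 20-point polygonal arc is slightly inside the true arc, so
        # allow disagreement only for nodes hugging the arc ends
        interior = np.abs(np.abs(ang) - half) > 0.05
        np.testing.assert_array_equal(mask[interior], expected[interior])
        assert 20 <= mask.sum() <= 30   # ~25 nodes over a 90-degree arc


class TestScalars:
    def test_patient_max_examples(self):
        assert patient_max([1, 5, 3]) == 5
        assert patient_max(np.full(10, 2.5)) == 2.5
        rng = np.random.default_rng(0)
        v = rng.normal(size=1000)
        assert patient_max(v) == max(list(v))

    def test_patient_mean_examples(self):
        assert patient_mean([1, 5, 3]) == 3
        assert patient_mean(np.full(7, 4.2)) == pytest.approx(4.2)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            patient_max([])
        with pytest.raises(ValueError):
            patient_mean([])

    def test_relative_difference_examples(self):
        assert relative_difference(467.36, 279.88) == pytest.approx(66.99, abs=0.01)
        assert relative_difference(5.0, 5.0) == 0.0
        assert relative_difference(100.0, 80.0) == 25.0
        with pytest.raises(ZeroDivisionError):
            relative_difference(1.0, 0.0)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.1, 1e3), st.floats(0.1, 1e3))
    def test_relative_difference_antisymmetry_identity(self, a, b):
        lhs = relative_difference(a, b)
        rhs = -relative_difference(b, a) * a / b
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_cohort_average(self):
        m, sd = cohort_average([1.0, 3.0])
        assert m == 2.0
        assert sd == pytest.approx(np.sqrt(2.0))
        with pytest.raises(ValueError):
            cohort_average([1.0])
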