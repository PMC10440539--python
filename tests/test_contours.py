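import numpy as np
import pytest

from plaquemech.contours import (
    Contour, ContourParseError, ContourValidationError, VesselSliceContours,
    merge_to_single_layer, point_in_polygon_winding, read_contours,
    resample_contour, write_contours,
)
from plaquemech.synthetic import SyntheticCohortSpec, generate_synthetic_slice

from conftest import circle_contour, concentric_slice


def octagon(r, label):
    th = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    return Contour(np.column_stack([r * np.cos(th), r * np.sin(th)]), label)


class TestValidation:
    def test_concentric_octagons_are_valid(self):
        slc = VesselSliceContours(octagon(1.5, "lumen"), octagon(1.8, "IEM"),
                                  octagon(2.0, "EEM"), octagon(2.3, "ADV"))
        slc.validate()

    def test_nesting_violation_names_contours(self):
        slc = VesselSliceContours(octagon(1.5, "lumen"), octagon(2.1, "IEM"),
                                  octagon(2.0, "EEM"), octagon(2.3, "ADV"))
        with pytest.raises(ContourValidationError, match="nesting"):
            slc.validate()

    def test_too_few_points_rejected(self):
        th = np.linspace(0, 2 * np.pi, 5, endpoint=False)
        c = Contour(np.column_stack([np.cos(th), np.sin(th)]), "lumen")
        with pytest.raises(ContourValidationError, match="8 points"):
            c.validate()

    def test_clockwise_orientation_rejected(self):
        c = Contour(octagon(1.0, "lumen").points[::-1], "lumen")
        with pytest.raises(ContourValidationError, match="counter-clockwise"):
            c.validate()

    def test_self_intersecting_rejected(self):
        pts = np.array([[0, 0], [2, 2], [2, 0], [0, 2], [0.1, 1.5],
                        [-0.5, 1.2], [-0.6, 0.7], [-0.3, 0.2]], dtype=float)
        with pytest.raises(ContourValidationError):
            Contour(pts, "lumen").validate()

    def test_validator_is_idempotent(self):
        slc = concentric_slice()
        before = slc.lumen.points.copy()
        slc.validate()
        slc.validate()
        np.testing.assert_array_equal(slc.lumen.points, before)

    def test_nesting_agrees_with_winding_number_oracle(self):
        spec = SyntheticCohortSpec(seed=3)
        rng = np.random.default_rng(0)
        for k in range(20):
            slc = generate_synthetic_slice(spec, 0, k)
            for inner, outer in [(slc.lumen, slc.iem), (slc.iem, slc.eem),
                                 (slc.eem, slc.adv)]:
                idx = rng.choice(len(inner.points), 10, replace=False)
                for p in inner.points[idx]:
                    assert point_in_polygon_winding(p, outer.points)
            # a point well outside is rejected by the oracle too
            assert not point_in_polygon_winding(
                slc.adv.centroid + [10.0, 0.0], slc.adv.points)


class TestIO:
    def test_json_round_trip_exact(self, tmp_path):
        slc = concentric_slice()
        path = tmp_path / "slice.json"
        write_contours(slc, path)
        back = read_contours(path)
        for a, b in [(slc.lumen, back.lumen), (slc.adv, back.adv)]:
            np.testing.assert_allclose(a.points, b.points, atol=1e-9)
        assert back.components == ()

    def test_empty_components_serialize_as_empty(self, tmp_path):
        import json
        path = tmp_path / "s.json"
        write_contours(concentric_slice(), path)
        doc = json.loads(path.read_text())
        assert [c["label"] for c in doc["contours"]] == ["lumen", "IEM", "EEM", "ADV"]

    def test_unknown_label_rejected_on_write(self, tmp_path):
        slc = concentric_slice()
        bad = VesselSliceContours(slc.lumen, slc.iem, slc.eem, slc.adv,
                                  components=(circle_contour(1.9, "lumen", 16),))
        with pytest.raises(ContourValidationError):
            write_contours(bad, tmp_path / "bad.json")

    def test_malformed_json_names_problem(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"slice_id": "x"}')
        with pytest.raises(ContourParseError, match="contours"):
            read_contours(path)

    def test_csv_import(self, tmp_path):
        slc = concentric_slice(n=32)
        rows = ["slice_id,label,idx,x,y"]
        for label, c in [("lumen", slc.lumen), ("IEM", slc.iem),
                         ("EEM", slc.eem), ("ADV", slc.adv)]:
            rows += [f"s1,{label},{i},{x:.12g},{y:.12g}" for i, (x, y) in enumerate(c.points)]
        path = tmp_path / "s.csv"
        path.write_text("\n".join(rows))
        back = read_contours(path)
        np.testing.assert_allclose(back.lumen.points, slc.lumen.points, atol=1e-9)


class TestResample:
    def test_circle_equal_arc_gaps(self):
        c = circle_contour(1.0, "lumen", 1000)
        r = resample_contour(c, 100)
        d = np.diff(np.vstack([r.points, r.points[:1]]), axis=0)
        gaps = np.hypot(d[:, 0], d[:, 1])
        assert len(r.points) == 100
        assert gaps.max() - gaps.min() < 1e-6

    def test_square_perimeter_preserved(self):
        sq = Contour(np.array([[1, 1], [-1, 1], [-1, -1], [1, -1.]]), "lumen")
        r = resample_contour(sq, 8)
        assert r.perimeter == pytest.approx(8.0, rel=0.005)

    def test_identity_on_already_equal_spacing(self):
        c = circle_contour(1.3, "lumen", 64)
        r = resample_contour(c, 64)
        np.testing.assert_allclose(r.points, c.points, atol=1e-9)

    def test_degenerate_contour_raises(self):
        c = Contour(np.zeros((10, 2)), "lumen")
        with pytest.raises(ContourValidationError, match="zero-length"):
            resample_contour(c, 16)

    def test_perimeter_and_area_converge_with_n(self):
        spec = SyntheticCohortSpec(seed=11)
        for k in range(5):
            slc = generate_synthetic_slice(spec, 1, k)
            c = slc.adv
            errs = []
            for n in (25, 50, 100):
                r = resample_contour(c, n)
                errs.append(abs(r.perimeter - c.perimeter) + abs(r.area - c.area))
            assert errs[0] >= errs[1] >= errs[2]


class TestMerge:
    def test_merged_slice_keeps_wall_envelope(self):
        slc = concentric_slice()
        merged = merge_to_single_layer(slc)
        assert merged.single_layer
        np.testing.assert_array_equal(merged.lumen.points, slc.lumen.points)
        np.testing.assert_array_equal(merged.adv.points, slc.adv.points)

    def test_merged_wall_area_equals_layer_sum(self):
        spec = SyntheticCohortSpec(seed=5)
        slc = generate_synthetic_slice(spec, 0, 0)
        merged = merge_to_single_layer(slc)
        assert merged.wall_area == pytest.approx(sum(slc.layer_areas.values()),
                                                 rel=1e-6)

    def test_components_preserved(self):
        spec = SyntheticCohortSpec(seed=5)
        slc = generate_synthetic_slice(spec, 0, 0)
        assert any(c.label == "lipid" for c in slc.components)
        merged = merge_to_single_layer(slc)
        assert len(merged.components) == len(slc.components)
        np.testing.assert_array_equal(merged.components[0].points,
                                      slc.components[0].points)
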