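"""Colony morphometry, coordinate transforms, selection, XML export."""

import numpy as np
import pytest

from liftscan import (
    ColonyXMLError,
    ImageFrame,
    LabelImage,
    LabelingError,
    SelectionRules,
    check_stitch_tolerance,
    extract_colonies,
    pixel_to_stage,
    read_colony_xml,
    select_targets,
    stage_to_pixel,
    synth_label_image,
    write_colony_xml,
)


def _disk_image(radius=50, center=(100, 100), shape=(200, 200)):
    img, truth = synth_label_image(
        [{"kind": "disk", "class": "colony", "center": center, "radius": radius}],
        image_shape=shape,
    )
    return img, truth[0]


class TestExtractColonies:
    def test_disk_circularity_near_one_and_full_colony_percent(self):
        img, _ = _disk_image()
        (rec,) = extract_colonies(img)
        assert 0.9 <= rec.roundness <= 1.1
        assert rec.colonyPercent == 100.0
        assert rec.childrenSize == 0

    def test_thin_line_has_low_circularity(self):
        img, _ = synth_label_image(
            [{"kind": "line", "class": "colony", "start": (50, 10), "end": (50, 109)}],
            image_shape=(100, 130),
        )
        (rec,) = extract_colonies(img)
        assert rec.size == 100
        assert rec.roundness < 0.1

    def test_enclosed_inclusion_counts_as_children(self):
        # a dead-cell hole inside the colony: 10x10 = 100 px^2
        arr = np.zeros((120, 120), dtype=np.uint8)
        rr, cc = np.mgrid[0:120, 0:120]
        disk = (rr - 60) ** 2 + (cc - 60) ** 2 <= 45**2
        arr[disk] = 1
        arr[55:65, 55:65] = 5  # dead class
        (rec,) = extract_colonies(LabelImage(arr))
        assert rec.childrenSize == 100
        assert rec.colonyPercent == pytest.approx(100.0 * rec.size / (rec.size + 100))

    def test_background_holes_do_not_count_as_children(self):
        arr = np.zeros((120, 120), dtype=np.uint8)
        rr, cc = np.mgrid[0:120, 0:120]
        arr[(rr - 60) ** 2 + (cc - 60) ** 2 <= 45**2] = 1
        arr[55:65, 55:65] = 0  # plain background hole
        (rec,) = extract_colonies(LabelImage(arr))
        assert rec.childrenSize == 0

    def test_area_conservation(self):
        img, truths = synth_label_image(
            [
                {"kind": "disk", "class": "colony", "center": (60, 60), "radius": 25},
                {"kind": "disk", "class": "colony", "center": (200, 200), "radius": 40},
                {"kind": "ellipse", "class": "colony", "center": (90, 220),
                 "r_radius": 15, "c_radius": 30},
            ],
            image_shape=(300, 300),
        )
        recs = extract_colonies(img)
        assert sum(r.size for r in recs) == int(np.sum(img.data == 1))

    def test_records_numbered_in_raster_scan_order(self):
        img, _ = synth_label_image(
            [
                {"kind": "disk", "class": "colony", "center": (200, 30), "radius": 10},
                {"kind": "disk", "class": "colony", "center": (30, 200), "radius": 10},
            ],
            image_shape=(256, 256),
        )
        recs = extract_colonies(img)
        # the component whose first pixel appears first in raster order gets id 1
        assert recs[0].id == 1 and recs[0].centerY < recs[1].centerY

    def test_centroid_matches_generator_ground_truth(self):
        img, truth = _disk_image(radius=30, center=(80, 120), shape=(200, 200))
        (rec,) = extract_colonies(img)
        assert abs(rec.centerX - truth.centroid[0]) < 0.5
        assert abs(rec.centerY - truth.centroid[1]) < 0.5
        assert rec.size == truth.area

    def test_translation_equivariance(self):
        img_a, _ = _disk_image(radius=30, center=(70, 70), shape=(220, 220))
        img_b, _ = _disk_image(radius=30, center=(110, 130), shape=(220, 220))
        (a,), (b,) = extract_colonies(img_a), extract_colonies(img_b)
        assert (b.centerY - a.centerY, b.centerX - a.centerX) == pytest.approx((40, 60), abs=1e-9)
        assert b.size == a.size
        assert b.length == pytest.approx(a.length)
        assert b.roundness == pytest.approx(a.roundness)

    def test_scale_behavior_of_disk(self):
        img_a, _ = _disk_image(radius=25, center=(60, 60), shape=(130, 130))
        img_b, _ = _disk_image(radius=50, center=(110, 110), shape=(260, 260))
        (a,), (b,) = extract_colonies(img_a), extract_colonies(img_b)
        assert b.size / a.size == pytest.approx(4.0, rel=0.05)
        assert b.length / a.length == pytest.approx(2.0, rel=0.05)
        assert b.roundness == pytest.approx(a.roundness, rel=0.05)

    def test_literal_roundness_formula_switch(self):
        img, _ = _disk_image()
        (sq,) = extract_colonies(img)
        (lit,) = extract_colonies(img, roundness_formula="literal")
        assert lit.roundness == pytest.approx(sq.roundness * sq.length)

    def test_undeclared_class_value_rejected(self):
        arr = np.full((10, 10), 9, dtype=np.uint8)
        with pytest.raises(LabelingError):
            LabelImage(arr)


class TestPixelToStage:
    def test_origin_pixel_maps_to_well_origin(self):
        frame = ImageFrame(section_offset=(0, 0), pixel_pitch=1.3, well_origin=(12.5, 7.25))
        assert pixel_to_stage((0, 0), frame) == pytest.approx((12.5, 7.25))

    def test_thousand_pixels_at_1p3um_is_1p3mm(self):
        frame = ImageFrame(section_offset=(0, 0), pixel_pitch=1.3, well_origin=(0.0, 0.0))
        x, y = pixel_to_stage((1000, 0), frame)
        assert x == pytest.approx(1.3)
        assert y == pytest.approx(0.0)

    def test_round_trip_identity(self):
        frame = ImageFrame(section_offset=(512, 1024), pixel_pitch=1.3, well_origin=(3.5, 8.0))
        rng = np.random.default_rng(5)
        for sx, sy in rng.uniform(0, 120, (100, 2)):
            px = stage_to_pixel((sx, sy), frame)
            bx, by = pixel_to_stage(px, frame)
            assert abs(bx - sx) < 1e-9 and abs(by - sy) < 1e-9

    def test_invalid_pitch_rejected(self):
        with pytest.raises(ValueError):
            ImageFrame(pixel_pitch=-1.3)


class TestStitchTolerance:
    @pytest.mark.parametrize("shift,tol,ok", [(10, 50, True), (50, 50, True), (60, 50, False)])
    def test_shift_against_lift_tolerance(self, shift, tol, ok):
        assert check_stitch_tolerance(shift, tol) is ok

    def test_negative_shift_rejected(self):
        with pytest.raises(ValueError):
            check_stitch_tolerance(-1.0)


class TestSelectTargets:
    @pytest.fixture()
    def disk_and_line_records(self):
        img, _ = synth_label_image(
            [
                {"kind": "disk", "class": "colony", "center": (60, 60), "radius": 30},
                {"kind": "line", "class": "colony", "start": (200, 10), "end": (200, 209)},
            ],
            image_shape=(256, 256),
        )
        return extract_colonies(img)

    def test_empty_rules_select_everything(self, disk_and_line_records):
        frame = ImageFrame()
        out = select_targets(disk_and_line_records, None, frame)
        assert [t.id for t in out] == [r.id for r in disk_and_line_records]

    def test_impossible_bound_selects_nothing(self, disk_and_line_records):
        rules = SelectionRules(min_size=10**9)
        assert select_targets(disk_and_line_records, rules, ImageFrame()) == []

    def test_roundness_rule_keeps_disk_drops_line(self, disk_and_line_records):
        rules = SelectionRules(min_roundness=0.8)
        out = select_targets(disk_and_line_records, rules, ImageFrame())
        assert len(out) == 1
        disk = max(disk_and_line_records, key=lambda r: r.roundness)
        assert out[0].id == disk.id

    def test_selected_positions_are_stage_coordinates(self, disk_and_line_records):
        frame = ImageFrame(section_offset=(100, 200), pixel_pitch=1.3,
                           well_origin=(5.0, 3.0), well_index=2)
        (t, *_) = select_targets(disk_and_line_records, None, frame)
        rec = disk_and_line_records[0]
        ex, ey = pixel_to_stage((rec.centerX, rec.centerY), frame)
        assert (t.x, t.y) == pytest.approx((ex, ey))
        assert t.well_index == 2

    def test_contradictory_bounds_rejected(self):
        with pytest.raises(ValueError, match="size"):
            SelectionRules(min_size=100, max_size=10)


class TestColonyXML:
    def test_round_trip_of_synthetic_records(self, tmp_path):
        img, _ = synth_label_image(
            [{"kind": "disk", "class": "colony",
              "center": (40 + 45 * i, 40 + 37 * (i % 5)), "radius": 8 + i % 7}
             for i in range(10)],
            image_shape=(512, 512),
        )
        recs = extract_colonies(img)
        path = tmp_path / "colonies.xml"
        write_colony_xml(recs, path)
        assert read_colony_xml(path) == recs

    def test_canonical_field_names_serialized(self, tmp_path):
        from liftscan.targeting import ColonyRecord

        rec = ColonyRecord(221, 10.0, 20.0, 500, 80.0, 0.98, 25, 95.24)
        path = tmp_path / "one.xml"
        write_colony_xml([rec], path)
        text = path.read_text()
        for field in ("centerX", "centerY", "size", "length", "roundness",
                      "childrenSize", "colonyPercent"):
            assert field in text
        assert 'id="221"' in text

    def test_empty_record_list(self, tmp_path):
        path = tmp_path / "none.xml"
        write_colony_xml([], path)
        assert read_colony_xml(path) == []

    def test_missing_field_names_it(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text('<colonies><colony id="1" centerX="1.0"/></colonies>')
        with pytest.raises(ColonyXMLError, match="centerY"):
            read_colony_xml(path)


class TestSynthLabelImage:
    def test_overlapping_classes_rejected(self):
        with pytest.raises(LabelingError):
            synth_label_image(
                [
                    {"kind": "disk", "class": "colony", "center": (50, 50), "radius": 20},
                    {"kind": "disk", "class": "dead", "center": (55, 55), "radius": 10},
                ],
                image_shape=(100, 100),
            )

    def test_deterministic_raster(self):
        spec = [{"kind": "disk", "class": "colony", "center": (50, 50), "radius": 20}]
        a, _ = synth_label_image(spec, image_shape=(100, 100), seed=1)
        b, _ = synth_label_image(spec, image_shape=(100, 100), seed=1)
        assert np.array_equal(a.data, b.data)
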