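"""Plate-image fixtures, segmentation, qualification, pick lists."""

import math

import numpy as np
import pandas as pd
import pytest

from shearpick.vision import (
    ColonyRecord,
    PlateImage,
    QualificationRules,
    generate_plate_image,
    make_picklist,
    qualify_colonies,
    read_image,
    segment_colonies,
    write_image,
)

# scaled-down fixture parameters used throughout: 1024 px frame (3.3 mm well),
# small colonies, and rules scaled to match
SMALL = dict(shape=(1024, 1024), radius_range=(80.0, 160.0))
SMALL_RULES = QualificationRules(
    min_area_um2=5e3, max_area_um2=5e5, footprint_radius=250.0, clearance=100.0, edge_margin=150.0
)


def match_to_truth(records, truth):
    """Greedy nearest-centroid matching; returns (record index, truth index) pairs."""
    pairs = []
    used = set()
    for i, rec in enumerate(records):
        d = np.hypot(truth["x_px"] - rec.centroid_px[0], truth["y_px"] - rec.centroid_px[1])
        j = int(d.idxmin())
        if j not in used and d[j] < 10.0:
            pairs.append((i, j))
            used.add(j)
    return pairs


class TestGeneratePlateImage:
    def test_empty_plate(self):
        img, truth = generate_plate_image(n_colonies=0, seed=1, **SMALL)
        assert truth.empty
        assert img.intensity.shape == (1024, 1024)

    def test_same_seed_identical_bytes(self):
        a, _ = generate_plate_image(n_colonies=3, seed=2, **SMALL)
        b, _ = generate_plate_image(n_colonies=3, seed=2, **SMALL)
        assert np.array_equal(a.intensity, b.intensity)

    def test_colonies_brighter_than_background(self):
        img, truth = generate_plate_image(n_colonies=3, seed=3, **SMALL)
        yy, xx = np.mgrid[0 : img.intensity.shape[0], 0 : img.intensity.shape[1]]
        inside = np.zeros(img.intensity.shape, bool)
        for _, row in truth.iterrows():
            inside |= np.hypot(xx - row.x_px, yy - row.y_px) < row.radius_um / img.pixel_size
        assert img.intensity[inside].mean() > img.intensity[~inside].mean()

    def test_impossible_packing_raises(self):
        with pytest.raises(RuntimeError):
            generate_plate_image(
                n_colonies=40, seed=4, min_edge_separation_um=1500.0, **SMALL
            )

    def test_image_io_round_trip(self, tmp_path):
        img, _ = generate_plate_image(n_colonies=2, seed=5, **SMALL)
        for name in ("plate.png", "plate.tif"):
            write_image(img, tmp_path / name)
            back = read_image(tmp_path / name, pixel_size=img.pixel_size)
            assert np.array_equal(back.intensity, img.intensity)


class TestSegmentColonies:
    def test_blank_plate_yields_nothing(self):
        img, _ = generate_plate_image(n_colonies=0, seed=6, **SMALL)
        assert segment_colonies(img) == []

    def test_single_disc_geometry(self):
        """Centroid within 1 px and area within 5% of the true disc."""
        img, truth = generate_plate_image(n_colonies=1, seed=7, shape=(1024, 1024),
                                          radius_range=(120.0, 120.0))
        records = segment_colonies(img)
        assert len(records) == 1
        rec, row = records[0], truth.iloc[0]
        assert math.hypot(rec.centroid_px[0] - row.x_px, rec.centroid_px[1] - row.y_px) < 1.0
        assert rec.area_um2 == pytest.approx(math.pi * row.radius_um**2, rel=0.05)

    @pytest.mark.parametrize("seed", [8, 9, 10])
    def test_separated_discs_all_found(self, seed):
        """Precision = recall = 1 for well-separated colonies (oracle match)."""
        img, truth = generate_plate_image(
            n_colonies=4, seed=seed, min_edge_separation_um=500.0, **SMALL
        )
        records = segment_colonies(img)
        assert len(records) == len(truth)
        assert len(match_to_truth(records, truth)) == len(truth)

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError):
            PlateImage(intensity=np.zeros((4, 4, 3), dtype=np.uint16))


def overlapping_pair_image(gap_factor=1.9, r_px=80):
    """Two equal discs whose centres sit gap_factor * r apart (fused blob)."""
    img, _ = generate_plate_image(n_colonies=0, seed=99, **SMALL)
    a = img.intensity.astype(float)
    yy, xx = np.mgrid[0:1024, 0:1024]
    for cx in (420, 420 + int(gap_factor * r_px)):
        a += 14000 * np.clip((r_px - np.hypot(xx - cx, yy - 512)) / 2 + 0.5, 0, 1)
    img.intensity = np.clip(a, 0, 65535).astype(np.uint16)
    return img


class TestQualifyColonies:
    def test_two_distant_colonies_qualify(self):
        img, truth = generate_plate_image(
            n_colonies=2, seed=11, min_edge_separation_um=1000.0, **SMALL
        )
        records = qualify_colonies(segment_colonies(img), img, SMALL_RULES)
        # both clear the 2*250+100 um proximity rule by construction
        assert all("proximity" not in r.reasons for r in records)

    def test_fused_pair_flagged_merged(self):
        img = overlapping_pair_image()
        records = segment_colonies(img)
        assert len(records) == 1  # one fused component
        records = qualify_colonies(records, img, SMALL_RULES)
        assert records[0].qualified is False
        assert "merged" in records[0].reasons

    def test_area_bounds_flagged(self):
        img, _ = generate_plate_image(n_colonies=1, seed=12, **SMALL)
        records = segment_colonies(img)
        tight = QualificationRules(
            min_area_um2=1e9, max_area_um2=2e9, footprint_radius=250.0,
            clearance=100.0, edge_margin=150.0
        )
        records = qualify_colonies(records, img, tight)
        assert "area-small" in records[0].reasons

    def test_inconsistent_well_rejected(self):
        img, _ = generate_plate_image(n_colonies=0, seed=13, **SMALL)
        with pytest.raises(ValueError):
            qualify_colonies([], img, QualificationRules(footprint_radius=5000.0))

    @pytest.mark.parametrize("seed", [14, 15, 16])
    def test_qualification_matches_geometric_oracle(self, seed):
        """Decisions equal a brute-force oracle computed from ground truth."""
        img, truth = generate_plate_image(
            n_colonies=6, seed=seed, min_edge_separation_um=150.0, **SMALL
        )
        records = qualify_colonies(segment_colonies(img), img, SMALL_RULES)
        pairs = match_to_truth(records, truth)
        assert len(pairs) == len(records)  # every component maps to a truth disc

        wx = img.well_center_px[0] * img.pixel_size
        wy = img.well_center_px[1] * img.pixel_size
        for i, j in pairs:
            row = truth.iloc[j]
            # oracle proximity: edge gap to every other truth disc
            ok = True
            for jj, other in truth.iterrows():
                if jj == j:
                    continue
                gap = (
                    math.hypot(row.x_um - other.x_um, row.y_um - other.y_um)
                    - row.radius_um
                    - other.radius_um
                )
                if gap < 2 * SMALL_RULES.footprint_radius + SMALL_RULES.clearance:
                    ok = False
            edge = (
                img.well_radius_um
                - math.hypot(row.x_um - wx, row.y_um - wy)
                - row.radius_um
            )
            if edge < SMALL_RULES.edge_margin:
                ok = False
            area = math.pi * row.radius_um**2
            if not SMALL_RULES.min_area_um2 <= area <= SMALL_RULES.max_area_um2:
                ok = False
            assert records[i].qualified == ok, (seed, j, records[i].reasons)


class TestMakePicklist:
    def make_record(self, label, x_px, y_px, pixel_size=3.25):
        return ColonyRecord(
            label=label,
            centroid_px=(x_px, y_px),
            centroid_um=(x_px * pixel_size, y_px * pixel_size),
            area_um2=1e5,
            equivalent_diameter_um=300.0,
            solidity=0.99,
            qualified=True,
        )

    def blank(self):
        img, _ = generate_plate_image(n_colonies=0, seed=17, **SMALL)
        return img

    def test_pixel_to_stage_arithmetic(self):
        img = self.blank()
        pl = make_picklist([self.make_record(1, 100.0, 200.0)], img)
        row = pl.targets.iloc[0]
        assert row.x_um == pytest.approx(325.0, abs=1e-9)
        assert row.y_um == pytest.approx(650.0, abs=1e-9)

    def test_stage_offset_applied(self):
        img = self.blank()
        pl = make_picklist([self.make_record(1, 100.0, 200.0)], img, stage_offset=(10.0, -5.0))
        assert pl.targets.iloc[0].x_um == pytest.approx(335.0, abs=1e-9)
        assert pl.targets.iloc[0].y_um == pytest.approx(645.0, abs=1e-9)

    def test_empty_picklist_written_with_header(self, tmp_path):
        path = tmp_path / "empty.csv"
        make_picklist([], self.blank(), path=path)
        back = pd.read_csv(path, comment="#")
        assert list(back.columns) == ["id", "x_um", "y_um"]
        assert back.empty

    def test_serpentine_ordering(self):
        """y bands non-decreasing; x alternates direction per band (brute-force check)."""
        img = self.blank()
        rng = np.random.default_rng(0)
        records = [
            self.make_record(i, float(rng.uniform(50, 950)), float(rng.uniform(50, 950)))
            for i in range(12)
        ]
        pl = make_picklist(records, img, band_height_um=800.0)
        t = pl.targets
        bands = np.floor(t.y_um.to_numpy() / 800.0).astype(int)
        assert (np.diff(bands) >= 0).all()
        for b in np.unique(bands):
            xs = t.x_um.to_numpy()[bands == b]
            if b % 2 == 0:
                assert (np.diff(xs) >= 0).all()
            else:
                assert (np.diff(xs) <= 0).all()

    def test_unqualified_records_excluded(self):
        img = self.blank()
        bad = self.make_record(2, 300.0, 300.0)
        bad.qualified = False
        pl = make_picklist([self.make_record(1, 100.0, 100.0), bad], img)
        assert pl.targets["id"].tolist() == [1]
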