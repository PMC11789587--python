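"""Segmentation, artifact removal, CTCF computation, and tile summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dogscreen as dg
from dogscreen.synth_screen import CellTruth, GroundTruthTile, sample_cells
from dogscreen.segment_quant import match_to_ground_truth


def _tile_with_cells(positions, nucleus_r=6.0, cell_r=15.0, total=50000.0, size=512.0):
    cells = tuple(
        CellTruth(x, y, nucleus_r, cell_r,
                  {"nuclei": 20000.0, "asma": total, "col1": 0.6 * total})
        for x, y in positions
    )
    return GroundTruthTile(0, 0, size, size, 0.0, {"asma": total, "col1": 0.6 * total}, cells)


def _grid_positions(n, size=512.0, spacing=96.0, offset=64.0):
    pts = []
    per_row = int((size - 2 * offset) // spacing) + 1
    for i in range(n):
        pts.append((offset + (i % per_row) * spacing, offset + (i // per_row) * spacing))
    return pts


class TestSegmentNuclei:
    def test_empty_image_gives_empty_labels(self):
        labels = dg.segment_nuclei(np.zeros((128, 128)), 1.0)
        assert labels.max() == 0

    def test_recovers_well_separated_nuclei(self, quiet_optics, rng):
        gt = _tile_with_cells(_grid_positions(20))
        img = dg.render_tile(gt, quiet_optics, rng)
        labels = dg.segment_nuclei(img[0], 1.0)
        assert labels.max() == 20
        # centroids within 1 px of planted positions
        for lab in range(1, 21):
            ys, xs = np.nonzero(labels == lab)
            cx, cy = xs.mean() + 0.5, ys.mean() + 0.5
            d = min((cx - x) ** 2 + (cy - y) ** 2 for x, y in _grid_positions(20))
            assert np.sqrt(d) <= 1.0

    def test_declumps_overlapping_pair(self, quiet_optics, rng):
        # two large nuclei whose spots merge into one blob above max area
        gt = _tile_with_cells([(100.0, 100.0), (120.4, 100.0)], nucleus_r=12.0, size=256.0)
        img = dg.render_tile(gt, quiet_optics, rng)
        config = dg.SegmentationConfig(
            min_nucleus_area_um2=50.0, max_nucleus_area_um2=600.0,
            artifact_max_area_um2=5000.0,
        )
        labels = dg.segment_nuclei(img[0], 1.0, config)
        assert labels.max() == 2


class TestRemoveArtifacts:
    def test_identity_when_nothing_large(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[5:10, 5:10] = 1
        labels[30:36, 30:36] = 2
        out = dg.remove_artifacts(labels, 1000.0, 1.0)
        assert np.array_equal(out, labels)

    def test_large_blob_removed_survivors_keep_ids(self):
        labels = np.zeros((200, 200), dtype=np.int32)
        labels[:150, :150] = 7  # 22500 um^2 blob
        for i, off in enumerate(range(160, 195, 8)):
            labels[off : off + 5, 160:165] = 10 + i
        out = dg.remove_artifacts(labels, 5000.0, 1.0)
        assert 7 not in out
        for i in range(5):
            assert (out == 10 + i).sum() == (labels == 10 + i).sum()

    def test_threshold_below_everything_warns_and_empties(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[5:15, 5:15] = 1
        with pytest.warns(UserWarning, match="artifact"):
            out = dg.remove_artifacts(labels, 10.0, 1.0)
        assert out.max() == 0


def _brute_force_ctcf(img, labels, px, lab):
    cell = labels == lab
    bg = img[labels == 0].mean()
    area = cell.sum() * px * px
    integrated = area * img[cell].mean()
    return integrated - area * bg


class TestComputeCtcf:
    def test_four_pixel_example(self):
        img = np.full((4, 4), 2.0)
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[1:3, 1:3] = 1  # 4-px cell
        img[1:3, 1:3] = 10.0
        res = dg.compute_ctcf(img, labels, 1.0)
        assert res.loc[1, "integrated_density"] == pytest.approx(40.0)
        assert res.loc[1, "ctcf"] == pytest.approx(32.0)
        # halving the pixel size scales areas (and hence CTCF) by 1/4
        res_half = dg.compute_ctcf(img, labels, 0.5)
        assert res_half.loc[1, "integrated_density"] == pytest.approx(10.0)
        assert res_half.loc[1, "ctcf"] == pytest.approx(8.0)

    def test_cell_at_background_level_has_zero_ctcf(self):
        img = np.full((8, 8), 5.0)
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[2:5, 2:5] = 1
        res = dg.compute_ctcf(img, labels, 1.3)
        assert res.loc[1, "ctcf"] == pytest.approx(0.0, abs=1e-9)

    def test_empty_background_is_an_error(self):
        labels = np.ones((4, 4), dtype=np.int32)
        with pytest.raises(ValueError, match="background"):
            dg.compute_ctcf(np.ones((4, 4)), labels, 1.0)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), px=st.sampled_from([0.5, 0.65, 1.0, 2.0]))
    def test_matches_per_pixel_brute_force(self, seed, px):
        r = np.random.default_rng(seed)
        img = r.uniform(0, 1000, size=(24, 24))
        labels = r.integers(0, 4, size=(24, 24)).astype(np.int32)
        if not (labels == 0).any():
            labels[0, 0] = 0
        res = dg.compute_ctcf(img, labels, px)
        for lab in np.unique(labels):
            if lab == 0:
                continue
            expected = _brute_force_ctcf(img, labels, px, lab)
            assert res.loc[lab, "ctcf"] == pytest.approx(expected, rel=1e-6)


class TestSegmentCells:
    def test_zero_marker_falls_back_to_dilation(self):
        nuclei = np.zeros((100, 100), dtype=np.int32)
        nuclei[48:53, 48:53] = 1
        config = dg.SegmentationConfig(dilation_radius_um=8.0)
        cells = dg.segment_cells([np.zeros((100, 100))] * 2, nuclei, 1.0, config)
        from scipy import ndimage as ndi

        dist = ndi.distance_transform_edt(nuclei == 0)
        assert np.array_equal(cells > 0, dist <= 8)
        assert np.all(cells[cells > 0] == 1)

    def test_cells_disjoint_and_contain_their_nucleus(self, quiet_optics, rng):
        gt = _tile_with_cells(_grid_positions(12))
        img = dg.render_tile(gt, quiet_optics, rng)
        nuclei = dg.segment_nuclei(img[0], 1.0)
        cells = dg.segment_cells([img[1], img[2]], nuclei, 1.0)
        assert np.all(cells[nuclei > 0] == nuclei[nuclei > 0])

    def test_isolated_cell_areas_match_planted_disks(self, quiet_optics, rng):
        """With the dilation floor below the planted radius, the watershed body
        follows the marker signal and recovers the planted disk area."""
        gt = _tile_with_cells(_grid_positions(9, spacing=128.0), cell_r=15.0)
        img = dg.render_tile(gt, quiet_optics, rng)
        config = dg.SegmentationConfig(dilation_radius_um=8.0)
        nuclei = dg.segment_nuclei(img[0], 1.0, config)
        cells = dg.segment_cells([img[1], img[2]], nuclei, 1.0, config)
        planted = np.pi * 15.0**2
        for lab in range(1, cells.max() + 1):
            area = (cells == lab).sum()
            assert area == pytest.approx(planted, rel=0.10)


class TestSummaries:
    def test_density_arithmetic(self):
        records = pd.DataFrame(
            {"ctcf_asma": np.ones(100), "ctcf_col1": np.ones(100),
             "background_asma": np.ones(100), "background_col1": np.ones(100)}
        )
        s = dg.summarize_tile(records, 1742.0, 1298.0)
        assert s.density == pytest.approx(100 / 2.261116, rel=1e-6)

    def test_zero_cells_missing_medians(self):
        s = dg.summarize_tile(pd.DataFrame(columns=["ctcf_asma", "ctcf_col1"]), 1000.0, 1000.0)
        assert s.n_cells == 0 and s.density == 0.0
        assert np.isnan(s.median_ctcf_asma) and np.isnan(s.median_ctcf_col1)

    def test_median_of_three(self):
        records = pd.DataFrame(
            {"ctcf_asma": [1.0, 2.0, 3.0], "ctcf_col1": [4.0, 5.0, 6.0],
             "background_asma": [0.0] * 3, "background_col1": [0.0] * 3}
        )
        s = dg.summarize_tile(records, 1000.0, 1000.0)
        assert s.median_ctcf_asma == 2.0 and s.median_ctcf_col1 == 5.0


class TestQuantifyTile:
    def test_end_to_end_recovery_on_default_noise(self, model, cond_main):
        """Counts and tile medians recovered from rendered tiles with default noise."""
        optics = dg.OpticsConfig(pixel_size_um=1.0)
        p = dg.ParameterPoint(2.0, 80.0, 40.0)
        rng = np.random.default_rng(42)
        gt = sample_cells(model, p, cond_main, rng, 700, 700)
        img = dg.render_tile(gt, optics, rng)
        records, summary = dg.quantify_tile(img, 1.0, tile_width_um=700, tile_height_um=700)
        assert summary.n_cells == pytest.approx(gt.n_cells, abs=max(2, 0.05 * gt.n_cells))
        samp_med = np.median([c.totals["asma"] for c in gt.cells])
        assert summary.median_ctcf_asma == pytest.approx(samp_med, rel=0.10)
        m = match_to_ground_truth(
            records[["centroid_x_um", "centroid_y_um"]].to_numpy(),
            np.array([(c.x_um, c.y_um) for c in gt.cells]),
        )
        assert m["precision"] >= 0.95 and m["recall"] >= 0.95

    def test_background_coverage_partition(self, quiet_optics, rng):
        """Every pixel is either background or belongs to exactly one cell."""
        gt = _tile_with_cells(_grid_positions(10))
        img = dg.render_tile(gt, quiet_optics, rng)
        nuclei = dg.segment_nuclei(img[0], 1.0)
        cells = dg.segment_cells([img[1], img[2]], nuclei, 1.0)
        assert ((cells >= 0).sum()) == cells.size  # labels partition the tile


class TestMatching:
    def test_empty_cases(self):
        assert match_to_ground_truth(np.empty((0, 2)), np.empty((0, 2)))["precision"] == 1.0
        out = match_to_ground_truth(np.array([[1.0, 1.0]]), np.empty((0, 2)))
        assert out["precision"] == 0.0 and out["recall"] == 1.0

    def test_one_to_one_matching(self):
        true = np.array([[10.0, 10.0], [50.0, 50.0]])
        pred = np.array([[11.0, 10.0], [49.0, 51.0], [200.0, 200.0]])
        out = match_to_ground_truth(pred, true, max_dist_um=5.0)
        assert out["n_matched"] == 2
        assert out["precision"] == pytest.approx(2 / 3)
        assert out["recall"] == 1.0
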