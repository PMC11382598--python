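"""Report rendering: montage slice selection, alpha thresholding, grayplots,
edge overlays, assembly, and ratings round trips."""

import json

import numpy as np
import pytest
from scipy import stats as sstats

from fmriqc.io import Dataset3D
from fmriqc.report import (QC_BLOCKS, RatingRecord, RenderSpec,
                           apply_alpha_threshold, assemble_report, ratings_io,
                           render_edge_overlay, render_grayplot,
                           select_montage_slices)
from fmriqc.synthetic import make_phantom_anat
from fmriqc.warns import WarnItem, WarnLevel
from tests.conftest import make_3d, make_4d, make_mask


class TestMontageSlices:
    def test_uniform_volume_spans_full_axis(self):
        vol = make_3d(np.ones((10, 10, 12)))
        idx, labels = select_montage_slices(vol, axis=2, n_slices=4)
        assert idx[0] == 0 and idx[-1] == 11
        assert len(labels) == len(idx)

    def test_slices_confined_to_occupied_middle_half(self):
        vals = np.zeros((10, 10, 16))
        vals[:, :, 4:12] = 50.0
        idx, _ = select_montage_slices(make_3d(vals), axis=2, n_slices=5)
        assert idx.min() >= 4 and idx.max() <= 11

    def test_single_slice_is_extent_midpoint(self):
        vals = np.zeros((10, 10, 16))
        vals[:, :, 4:13] = 50.0
        idx, _ = select_montage_slices(make_3d(vals), axis=2, n_slices=1)
        assert idx.tolist() == [8]


class TestAlphaThreshold:
    def test_quadratic_falloff_below_threshold(self):
        vol = np.full((4, 4, 2), 0.5)
        alpha, boxed = apply_alpha_threshold(vol, 1.0)
        np.testing.assert_allclose(alpha, 0.25)
        assert not boxed.any()

    def test_suprathreshold_is_opaque_and_outlined(self):
        vol = np.zeros((8, 8, 4))
        vol[2:6, 2:6, 1:3] = 5.0
        alpha, boxed = apply_alpha_threshold(vol, 1.0)
        assert (alpha[2:6, 2:6, 1:3] == 1.0).all()
        assert boxed[2, 2, 1] and not boxed.all()

    def test_default_t_threshold_matches_distribution_oracle(self):
        spec = RenderSpec()
        df = 226
        assert spec.t_threshold(df) == pytest.approx(
            sstats.t.ppf(1 - 0.0005, df), abs=1e-12)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            apply_alpha_threshold(np.ones((2, 2, 2)), 0.0)


class TestGrayplot:
    def test_z_clip_value(self):
        assert RenderSpec().grayplot_z() == pytest.approx(3.2905, abs=1e-4)

    def test_rows_sorted_by_pc1_similarity_oracle(self, rng):
        data = rng.standard_normal((6, 5, 2, 40))
        data[:3] += 2.0 * rng.standard_normal(40)  # shared component
        img, order = render_grayplot(make_4d(data), make_mask(np.ones((6, 5, 2))))
        # independent oracle: z-score, explicit PC1, |corr| must be
        # non-increasing down the returned ordering
        raw = data[np.ones((6, 5, 2), dtype=bool)]
        z = (raw - raw.mean(axis=1, keepdims=True)) / raw.std(axis=1,
                                                              keepdims=True)
        w, v = np.linalg.eigh(z.T @ z)
        pc = v[:, -1]
        ac = np.abs(z @ pc) / np.sqrt((z ** 2).sum(axis=1))
        assert (np.diff(ac[order]) <= 1e-12).all()

    def test_dominant_cluster_occupies_top_rows(self, rng):
        T = 60
        shared = rng.standard_normal(T)
        data = 0.3 * rng.standard_normal((8, 4, 1, T))
        membership = np.zeros((8, 4, 1), dtype=int)
        membership[:4] = 1
        data[:4] += 3.0 * shared  # one strong cluster, rest is noise
        img, order = render_grayplot(make_4d(data), make_mask(np.ones((8, 4, 1))))
        member_flat = membership[np.ones((8, 4, 1), dtype=bool)]
        n_cluster = member_flat.sum()
        # all cluster voxels rank above every pure-noise voxel
        assert member_flat[order][:n_cluster].all()

    def test_reordering_preserves_pixel_multiset(self, rng):
        data = rng.standard_normal((6, 6, 2, 30))
        img, order = render_grayplot(make_4d(data), make_mask(np.ones((6, 6, 2))))
        raw = data[np.ones((6, 6, 2), dtype=bool)]
        z = (raw - raw.mean(axis=1, keepdims=True)) / raw.std(axis=1, keepdims=True)
        z = np.clip(z, -RenderSpec().grayplot_z(), RenderSpec().grayplot_z())
        assert np.allclose(np.sort(img.ravel()), np.sort(z.ravel()))

    def test_constant_dataset_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            render_grayplot(make_4d(np.full((4, 4, 2, 20), 3.0)),
                            make_mask(np.ones((4, 4, 2))))


class TestEdgeOverlay:
    def test_uniform_volume_has_no_edges(self):
        vol = make_3d(np.full((8, 8, 6), 7.0))
        assert not render_edge_overlay(vol, vol).any()

    def test_ellipsoid_boundary_recovered_within_one_voxel(self, small_spec):
        from scipy.ndimage import binary_dilation
        anat, mask = make_phantom_anat(small_spec)
        edges = render_edge_overlay(anat, anat)
        # every outer-boundary voxel of the mask is within 1 voxel of an edge
        boundary = mask.values & ~binary_dilation(~mask.values, iterations=1)
        shell = mask.values ^ binary_dilation(mask.values, iterations=1)
        near_edge = binary_dilation(edges, iterations=1)
        frac = (near_edge & shell).sum() / shell.sum()
        assert frac > 0.95

    def test_deterministic(self, small_phantom):
        anat = small_phantom["anat"]
        e1 = render_edge_overlay(anat, anat)
        e2 = render_edge_overlay(anat, anat)
        np.testing.assert_array_equal(e1, e2)


class TestAssembleAndRatings:
    def _build(self, tmp_path, warn_items=None):
        from fmriqc.io import ReviewDict
        review = ReviewDict({"subject ID": "sub-9", "TSNR average": 120.0})
        return assemble_report(tmp_path / "QC", "sub-9", {},
                               review=review, warn_items=warn_items or [])

    def test_all_block_anchors_present_in_order(self, tmp_path):
        index = self._build(tmp_path)
        html = index.read_text()
        positions = [html.index(f"<div class='block' id='{b}'")
                     for b in QC_BLOCKS]
        assert positions == sorted(positions)

    def test_severe_warning_styles_warns_label(self, tmp_path):
        index = self._build(tmp_path, [WarnItem("flip check",
                                                WarnLevel.severe, "boom")])
        html = index.read_text()
        menu = html.split("<div class='block'")[0]
        assert WarnLevel.severe.color in menu

    def test_report_is_relocatable_no_absolute_paths(self, tmp_path):
        index = self._build(tmp_path)
        html = index.read_text()
        assert str(tmp_path) not in html
        assert "file://" not in html

    def test_ratings_round_trip(self, tmp_path):
        report_dir = self._build(tmp_path).parent
        rec = RatingRecord(ratings={"mot": "bad", "FINAL": "good"})
        ratings_io(report_dir, "sub-9", rec)
        back = ratings_io(report_dir, "sub-9")
        assert back.ratings["mot"] == "bad"
        assert back.ratings["FINAL"] == "good"

    def test_symbol_input_translates_to_word(self, tmp_path):
        report_dir = self._build(tmp_path).parent
        ratings_io(report_dir, "sub-9", RatingRecord(ratings={"regr": "X"}))
        assert ratings_io(report_dir, "sub-9").ratings["regr"] == "bad"

    def test_comment_on_unrated_block_becomes_other(self, tmp_path):
        report_dir = self._build(tmp_path).parent
        ratings_io(report_dir, "sub-9",
                   RatingRecord(comments={"vorig": "odd banding"}))
        back = ratings_io(report_dir, "sub-9")
        assert back.ratings["vorig"] == "other"

    def test_unknown_block_rejected(self, tmp_path):
        report_dir = self._build(tmp_path).parent
        with pytest.raises(KeyError):
            ratings_io(report_dir, "sub-9",
                       RatingRecord(ratings={"bogus": "good"}))

    def test_final_bad_rating_drives_group_filtering(self, tmp_path):
        from fmriqc.io import read_review_dict
        from fmriqc.tables import Criterion, build_group_table, filter_report
        report_dir = self._build(tmp_path).parent
        ratings_io(report_dir, "sub-9", RatingRecord(ratings={"FINAL": "bad"}))
        rd = read_review_dict(report_dir / "out.ss_review.sub-9.json", "json")
        assert rd["FINAL rating"] == "bad"
        other = read_review_dict(report_dir / "out.ss_review.sub-9.json", "json")
        table = build_group_table([rd, other], subject_ids=["sub-9", "sub-x"])
        table.df.loc[1, "FINAL rating"] = "good"
        rep = filter_report(table, [Criterion.parse("'FINAL rating' EQ 'bad'")])
        assert rep.subjects == ["sub-9"]

    def test_generation_is_deterministic(self, tmp_path):
        i1 = self._build(tmp_path / "one")
        i2 = self._build(tmp_path / "two")
        assert i1.read_text() == i2.read_text()
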