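import numpy as np
import pytest

from radadapt import VolumeROI, quantize
from radadapt.data_io import InputError
from radadapt.lbptop import (LBP_CONFIGS, LBP_FEATURE_NAMES, LBP_STAT_NAMES,
                             LBPConfig, LBPHistogram, lbp_code, lbp_summary,
                             lbp_top_histogram, lbptop_features, mapping_table)

from .oracles import lbp_plane_code_brute, lbp_top_hist_brute, mapping_brute


class TestMappingTables:
    @pytest.mark.parametrize("mapping,bins", [
        ("basic", 256), ("u2", 59), ("ri", 36), ("riu2", 10),
    ])
    def test_bin_cardinalities(self, mapping, bins):
        t = mapping_table(8, mapping)
        assert int(t.max()) + 1 == bins
        assert len(np.unique(t)) == bins

    @pytest.mark.parametrize("mapping", ["basic", "u2", "ri", "riu2"])
    def test_tables_match_independent_construction(self, mapping):
        np.testing.assert_array_equal(mapping_table(8, mapping), mapping_brute(mapping))

    def test_u2_catch_all_pools_nonuniform_codes(self):
        t = mapping_table(8, "u2")
        # 0b01010101 has 8 transitions -> catch-all; 0b00001111 has 2 -> own bin
        assert t[0b01010101] == 58
        assert (t == 58).sum() == 256 - 58


class TestCode:
    def test_constant_plane_codes_255(self):
        plane = np.full((7, 7), 3.0)
        assert lbp_code(plane, (3, 3), R=1) == 255
        assert lbp_code(plane, (3, 3), R=3) == 255

    def test_strict_center_maximum_codes_0(self):
        plane = np.zeros((5, 5))
        plane[2, 2] = 10.0
        assert lbp_code(plane, (2, 2), R=1) == 0

    def test_step_edge_sets_exactly_bright_side_bits(self):
        # dark half 0, bright half 5, center raised to 1: only the three
        # neighbors on (or interpolated toward) the bright side compare >=
        plane = np.zeros((5, 5))
        plane[:, 3:] = 5.0
        plane[2, 2] = 1.0
        code = lbp_code(plane, (2, 2), R=1)
        assert code == lbp_plane_code_brute(plane, 2, 2, R=1)
        assert code == (1 << 1) | (1 << 2) | (1 << 3)

    def test_codes_match_interpolation_oracle_on_random_planes(self, rng):
        for _ in range(3):
            plane = rng.integers(0, 6, size=(9, 9)).astype(float)
            for R in (1, 2, 3):
                for r0 in range(R, 9 - R):
                    for c0 in range(R, 9 - R):
                        assert lbp_code(plane, (r0, c0), R=R) == \
                            lbp_plane_code_brute(plane, r0, c0, R)

    def test_out_of_bounds_circle_rejected(self):
        with pytest.raises(InputError):
            lbp_code(np.zeros((5, 5)), (0, 2), R=1)


class TestHistogram:
    def test_constant_roi_three_bins_one_per_plane(self):
        roi = VolumeROI("t", np.zeros((6, 6, 6)), np.ones((6, 6, 6)))
        q = quantize(roi, G=8)
        h = lbp_top_histogram(q, LBPConfig(R=1, mapping="basic"))
        nz = np.where(h.h > 0)[0]
        assert len(nz) == 3
        np.testing.assert_allclose(h.h[nz], 1 / 3)
        # all mass sits in code 255's bin within each plane block
        assert set(nz % 256) == {255}

    def test_histogram_sums_to_one(self, cube_roi):
        q = quantize(cube_roi, G=8)
        for cfg in LBP_CONFIGS:
            h = lbp_top_histogram(q, cfg)
            assert abs(h.h.sum() - 1.0) < 1e-12

    def test_matches_per_voxel_oracle_all_configs(self, cube_roi, rng):
        """Exhaustive per-voxel, per-plane enumeration on an 8^3 textured ROI."""
        q = quantize(cube_roi, G=8)
        # also punch holes in the mask to exercise ROI selection
        q.source.mask[rng.random((8, 8, 8)) < 0.2] = False
        for cfg in LBP_CONFIGS:
            mine = lbp_top_histogram(q, cfg)
            ref_h, ref_n = lbp_top_hist_brute(q.levels, q.mask, cfg.R, cfg.mapping)
            assert mine.sample_count == ref_n
            np.testing.assert_allclose(mine.h, ref_h, atol=1e-12)

    def test_volume_too_small_for_circle_is_degenerate(self):
        roi = VolumeROI("t", np.random.default_rng(0).normal(size=(3, 3, 3)),
                        np.ones((3, 3, 3)))
        q = quantize(roi, G=4)
        h = lbp_top_histogram(q, LBPConfig(R=3, mapping="u2"))
        assert h.degenerate
        assert all(v == 0.0 for v in lbp_summary(h).values())

    def test_ri_histogram_invariant_under_plane_rotation(self, rng):
        plane = rng.integers(0, 5, size=(10, 10)).astype(float)
        table = mapping_table(8, "ri")

        def ri_hist(pl):
            codes = [table[lbp_code(pl, (r, c), R=1)]
                     for r in range(1, pl.shape[0] - 1)
                     for c in range(1, pl.shape[1] - 1)]
            return np.bincount(codes, minlength=36)

        np.testing.assert_array_equal(ri_hist(plane), ri_hist(np.rot90(plane)))


class TestSummary:
    def test_unit_mass_single_bin(self):
        h = np.zeros(30)
        h[5] = 1.0
        s = lbp_summary(LBPHistogram(config=LBPConfig(R=1, mapping="riu2"), h=h,
                                     sample_count=10))
        assert s["mean"] == 5 and s["std"] == 0 and s["energy"] == 1
        assert s["range"] == 1 and s["argmax"] == 5

    def test_hand_built_histogram_formulas(self):
        h = np.array([0.5, 0, 0.25, 0, 0.125, 0.125])
        s = lbp_summary(LBPHistogram(config=LBPConfig(R=1, mapping="riu2"), h=h,
                                     sample_count=8))
        assert np.isclose(s["entropy"], -(0.5 * np.log2(0.5) + 0.25 * np.log2(0.25)
                                          + 2 * 0.125 * np.log2(0.125)))
        i = np.arange(6)
        mean = (i * h).sum()
        m2 = ((i - mean) ** 2 * h).sum()
        m3 = ((i - mean) ** 3 * h).sum()
        assert np.isclose(s["mean"], mean)
        assert np.isclose(s["skewness"], m3 / m2 ** 1.5)
        assert s["range"] == 4 and s["maxVal"] == 0.5

    def test_constant_roi_range_is_three(self):
        roi = VolumeROI("t", np.zeros((6, 6, 6)), np.ones((6, 6, 6)))
        q = quantize(roi, G=8)
        s = lbp_summary(lbp_top_histogram(q, LBPConfig(R=1, mapping="u2")))
        assert s["range"] == 3


def test_feature_inventory_and_layout(small_roi):
    assert len(LBP_CONFIGS) == 10
    assert len(LBP_FEATURE_NAMES) == 100
    assert len(set(LBP_FEATURE_NAMES)) == 100
    for fig3_name in ("lbp_range_LBP3_ri", "lbp_mean_LBP3_u",
                      "lbp_range_LBP3", "lbp_skewness_LBP3_u"):
        assert fig3_name in LBP_FEATURE_NAMES
    feats = lbptop_features(quantize(small_roi, G=8))
    assert list(feats) == LBP_FEATURE_NAMES
    assert len(LBP_STAT_NAMES) == 10
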