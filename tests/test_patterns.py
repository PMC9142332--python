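import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pfv3d.patterns import (CORNER_CELLS, GROUP_NAMES, build_vocabulary,
                            cell_to_zyx, corner_offsets, extract_pfv,
                            extract_pfv_2d, match_window, match_window_2d,
                            pfv_to_feature)
from pfv3d.synthetic import plant_patterns
from pfv3d.volumes import BinaryVolume

from conftest import pfv_oracle, pfv_oracle_2d

VOCAB = build_vocabulary()


class TestCellNumbering:
    def test_center_is_cell_14(self):
        assert cell_to_zyx(14) == (1, 1, 1)

    def test_corner_cells_are_window_corners(self):
        for cell in CORNER_CELLS:
            assert all(c in (0, 2) for c in cell_to_zyx(cell))

    def test_window_has_26_neighbors_of_center(self):
        cells = {cell_to_zyx(c) for c in range(1, 28)}
        assert len(cells) == 27
        assert len(cells - {(1, 1, 1)}) == 26


class TestVocabulary:
    def test_exactly_256_patterns_with_unique_ids(self):
        assert len(VOCAB) == 256
        assert sorted(p.id for p in VOCAB) == list(range(256))

    def test_group_sizes_are_binomial_coefficients(self):
        assert VOCAB.group_sizes() == {
            "P": 1, "Q": 8, "R": 28, "S": 56, "T": 70, "U": 56, "V": 28,
            "W": 8, "X": 1,
        }

    def test_group_letter_tracks_absent_count(self):
        for p in VOCAB:
            assert p.group == GROUP_NAMES[len(p.absent_corners)]

    def test_named_patterns_from_catalogue(self):
        r13 = VOCAB.by_name("R{1,3}")
        assert r13.present_corners == frozenset({7, 9, 19, 21, 25, 27})
        assert VOCAB.by_name("P1").present_corners == frozenset(CORNER_CELLS)
        assert VOCAB.by_name("Q1").absent_corners == frozenset({1})
        x = [p for p in VOCAB if p.group == "X"][0]
        assert x.present_corners == frozenset()

    def test_id_is_occupancy_bitmask(self):
        for p in VOCAB:
            expected = sum(
                1 << k for k, cell in enumerate(CORNER_CELLS)
                if cell in p.present_corners
            )
            assert p.id == expected

    def test_index_assignment_stable_across_builds(self):
        again = build_vocabulary()
        assert [p.name for p in VOCAB] == [p.name for p in again]


class TestMatchWindow:
    def test_all_foreground_matches_p1(self):
        assert VOCAB[match_window(np.ones((3, 3, 3), np.uint8))].name == "P1"

    def test_all_background_matches_x(self):
        pid = match_window(np.zeros((3, 3, 3), np.uint8))
        assert VOCAB[pid].group == "X"

    def test_missing_corner_one_matches_q1(self):
        w = np.ones((3, 3, 3), np.uint8)
        w[cell_to_zyx(1)] = 0
        assert VOCAB[match_window(w)].name == "Q1"

    def test_non_corner_cells_ignored(self, rng):
        corners_only = VOCAB[137].render_window()
        noisy = corners_only.copy()
        for cell in range(1, 28):
            if cell not in CORNER_CELLS and cell != 14:
                noisy[cell_to_zyx(cell)] = rng.integers(0, 2)
        assert match_window(noisy) == match_window(corners_only) == 137

    def test_render_then_match_is_identity_for_all_256(self):
        for p in VOCAB:
            assert match_window(p.render_window()) == p.id

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="3x3x3"):
            match_window(np.ones((3, 3), np.uint8))


class TestExtractPfv:
    def test_single_all_foreground_window(self):
        pfv = extract_pfv(np.ones((3, 3, 3), np.uint8))
        assert pfv.n_windows == 1
        assert pfv.counts[255] == 1 and pfv.counts.sum() == 1

    def test_nine_cubed_all_foreground(self):
        pfv = extract_pfv(np.ones((9, 9, 9), np.uint8))
        assert pfv.counts[255] == 27
        assert pfv.counts.sum() == 27

    def test_matches_brute_force_oracle_on_random_masks(self, rng):
        for _ in range(30):
            shape = tuple(rng.integers(3, 16, size=3))
            m = (rng.random(shape) < rng.uniform(0.2, 0.8)).astype(np.uint8)
            pfv = extract_pfv(m)
            np.testing.assert_array_equal(pfv.counts, pfv_oracle(m))

    @pytest.mark.parametrize("stride", [1, 2, 3, 4])
    def test_conservation_across_strides(self, stride, rng):
        shape = tuple(rng.integers(4, 14, size=3))
        m = (rng.random(shape) < 0.5).astype(np.uint8)
        pfv = extract_pfv(m, stride=stride)
        padded = [s + (-s) % 3 for s in shape]
        expected_windows = int(np.prod([(p - 3) // stride + 1 for p in padded]))
        assert pfv.counts.sum() == pfv.n_windows == expected_windows
        np.testing.assert_array_equal(pfv.counts, pfv_oracle(m, stride=stride))

    def test_pad_value_one_fills_edges_with_foreground(self):
        m = np.ones((4, 4, 4), np.uint8)
        pfv = extract_pfv(m, pad_value=1)
        assert pfv.padded_shape == (6, 6, 6)
        assert pfv.counts[255] == pfv.n_windows == 8

    def test_translation_by_one_stride_step_preserves_pfv(self, rng):
        placements = [(137, (0, 0, 0)), (42, (1, 1, 1))]
        mask_a, _ = plant_patterns((9, 9, 9), placements)
        shifted = [(137, (1, 0, 0)), (42, (2, 1, 1))]
        mask_b, _ = plant_patterns((9, 9, 9), shifted)
        np.testing.assert_array_equal(
            extract_pfv(mask_a).counts, extract_pfv(mask_b).counts
        )

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            extract_pfv(np.full((3, 3, 3), 2))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_property_oracle_equivalence_and_conservation(self, seed):
        r = np.random.default_rng(seed)
        shape = tuple(r.integers(3, 13, size=3))
        m = (r.random(shape) < r.uniform(0.1, 0.9)).astype(np.uint8)
        pfv = extract_pfv(m)
        assert pfv.counts.sum() == pfv.n_windows
        np.testing.assert_array_equal(pfv.counts, pfv_oracle(m))


class TestExtractPfv2d:
    def test_all_foreground_single_window(self):
        pfv = extract_pfv_2d(np.ones((3, 3), np.uint8))
        assert pfv.counts[255] == 1 and pfv.counts.sum() == 1

    def test_all_background_single_window(self):
        pfv = extract_pfv_2d(np.zeros((3, 3), np.uint8))
        assert pfv.counts[0] == 1 and pfv.counts.sum() == 1

    def test_matches_2d_oracle_on_random_slices(self, rng):
        for _ in range(20):
            m = (rng.random((9, 9)) < 0.5).astype(np.uint8)
            np.testing.assert_array_equal(extract_pfv_2d(m).counts, pfv_oracle_2d(m))

    def test_center_ignored_in_2d(self):
        w = np.zeros((3, 3), np.uint8)
        w[1, 1] = 1
        assert match_window_2d(w) == 0


class TestPfvToFeature:
    def test_l1_of_unit_mass(self):
        pfv = extract_pfv(np.ones((3, 3, 3), np.uint8))
        feat = pfv_to_feature(pfv, "l1")
        assert feat[255] == 1.0 and feat.sum() == 1.0

    def test_l1_of_uniform_counts_gives_uniform_feature(self):
        from pfv3d.patterns import PatternFrequencyVector

        pfv = PatternFrequencyVector(np.full(256, 4), stride=3,
                                     padded_shape=(3, 3, 3), n_windows=1024)
        np.testing.assert_allclose(pfv_to_feature(pfv, "l1"), 1 / 256)

    def test_l2_on_three_four_counts(self):
        from pfv3d.patterns import PatternFrequencyVector

        counts = np.zeros(256, dtype=np.int64)
        counts[0], counts[1] = 3, 4
        pfv = PatternFrequencyVector(counts, stride=3, padded_shape=(3, 3, 3),
                                     n_windows=7)
        feat = pfv_to_feature(pfv, "l2")
        np.testing.assert_allclose(feat[:2], [0.6, 0.8])

    def test_unknown_normalization_rejected(self):
        pfv = extract_pfv(np.ones((3, 3, 3), np.uint8))
        with pytest.raises(ValueError, match="normalize"):
            pfv_to_feature(pfv, "max")
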