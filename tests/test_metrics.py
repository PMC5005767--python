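import numpy as np
import pytest

from chemolipid.errors import DegenerateDataError, RoiBoundsError
from chemolipid.masks import BinaryMask
from chemolipid.metrics import (
    COLOUR_ORDER,
    block_chemogram,
    classify_block,
    lcbi_total,
    max_lcbi_window,
    max_lipid_arc,
    valid_mask_from,
)


def _mask(arr, label="lipid_combined"):
    return BinaryMask(np.asarray(arr, dtype=bool), label)


def _all_valid(shape):
    return _mask(np.ones(shape, dtype=bool), "valid")


class TestLcbiTotal:
    def test_all_lipid_is_1000(self):
        shape = (10, 20)
        assert lcbi_total(
            _mask(np.ones(shape)), _all_valid(shape), (0, 20)
        ) == pytest.approx(1000.0)

    def test_no_lipid_is_0(self):
        shape = (10, 20)
        assert lcbi_total(
            _mask(np.zeros(shape)), _all_valid(shape), (0, 20)
        ) == pytest.approx(0.0)

    def test_fraction_arithmetic(self):
        # 300 lipid of 1200 valid pixels -> 250
        lip = np.zeros((30, 40), dtype=bool)
        lip.ravel()[:300] = True
        assert lcbi_total(_mask(lip), _all_valid((30, 40)), (0, 40)) == pytest.approx(
            250.0
        )

    def test_zero_valid_pixels_is_an_error(self):
        shape = (5, 5)
        with pytest.raises(DegenerateDataError):
            lcbi_total(
                _mask(np.ones(shape)),
                _mask(np.zeros(shape), "valid"),
                (0, 5),
            )

    def test_row_rotation_invariance(self, rng):
        lip = rng.random((24, 30)) < 0.3
        val = rng.random((24, 30)) < 0.9
        base = lcbi_total(_mask(lip), _mask(val, "valid"), (0, 30))
        for s in (5, 13):
            rolled = lcbi_total(
                _mask(np.roll(lip, s, axis=0)),
                _mask(np.roll(val, s, axis=0), "valid"),
                (0, 30),
            )
            assert rolled == pytest.approx(base)

    def test_valid_mask_policies(self):
        art = np.zeros((6, 6), dtype=bool)
        art[0:3, 0:3] = True
        hid = np.zeros((6, 6), dtype=bool)
        hid[0, 0] = True
        reclaim = valid_mask_from(_mask(art, "artifact"), _mask(hid, "lipid_hidden"))
        strict = valid_mask_from(
            _mask(art, "artifact"), _mask(hid, "lipid_hidden"), policy="strict"
        )
        assert reclaim.area == 36 - 9 + 1
        assert strict.area == 36 - 9


class TestMaxLcbiWindow:
    def test_lipid_inside_one_tile_saturates_both_modes(self):
        # 10 mm ROI at 1 mm/col; lipid fills columns 4..8 = tile [4, 8)
        lip = np.zeros((10, 10), dtype=bool)
        lip[:, 4:8] = True
        args = (_mask(lip), _all_valid((10, 10)), (0, 10), 1.0, 4.0)
        for mode in ("blocked", "sliding"):
            v, start = max_lcbi_window(*args, mode=mode)
            assert v == pytest.approx(1000.0)
            assert start == pytest.approx(4.0)

    def test_boundary_straddling_splits_blocked_mode(self):
        # 2 mm of solid lipid centred on a 2 mm tile boundary: a sliding
        # window captures it whole (1000), blocked tiles see half each (500)
        lip = np.zeros((10, 16), dtype=bool)
        lip[:, 3:5] = True
        args = (_mask(lip), _all_valid((10, 16)), (0, 16), 1.0, 2.0)
        v_sl, _ = max_lcbi_window(*args, mode="sliding")
        v_bl, _ = max_lcbi_window(*args, mode="blocked")
        assert v_sl == pytest.approx(1000.0)
        assert v_bl == pytest.approx(500.0)

    def test_uniform_fraction_ties_to_roi_start(self):
        lip = np.zeros((10, 12), dtype=bool)
        lip[:5, :] = True  # fraction 0.5 in every column
        v, start = max_lcbi_window(
            _mask(lip), _all_valid((10, 12)), (0, 12), 1.0, 4.0, mode="sliding"
        )
        assert v == pytest.approx(500.0)
        assert start == pytest.approx(0.0)

    def test_window_longer_than_roi_rejected(self):
        with pytest.raises(RoiBoundsError):
            max_lcbi_window(
                _mask(np.zeros((4, 4))), _all_valid((4, 4)), (0, 4), 1.0, 8.0
            )

    def test_sliding_dominates_blocked_on_random_scenes(self, rng):
        # blocked windows are a subset of sliding windows, so the sliding
        # maximum can never be smaller
        for _ in range(100):
            lip = rng.random((12, 24)) < rng.uniform(0.05, 0.6)
            args = (_mask(lip), _all_valid((12, 24)), (0, 24), 0.5, 4.0)
            v_sl, _ = max_lcbi_window(*args, mode="sliding")
            v_bl, _ = max_lcbi_window(*args, mode="blocked")
            assert v_sl >= v_bl - 1e-9


class TestClassifyBlock:
    @pytest.mark.parametrize(
        "p,cls",
        [
            (0.50, "red"),
            (0.569, "red"),
            (0.57, "orange"),
            (0.84, "orange"),  # overlapping boundary -> lower class
            (0.841, "tan"),
            (0.98, "tan"),  # overlapping boundary -> lower class
            (0.99, "yellow"),
            (0.0, "red"),
            (1.0, "yellow"),
        ],
    )
    def test_published_scheme(self, p, cls):
        assert classify_block(p) == cls

    def test_out_of_range_rejected(self):
        for p in (-0.1, 1.1, float("nan")):
            with pytest.raises(ValueError):
                classify_block(p)

    def test_monotone_in_probability(self):
        grid = np.arange(0, 1.0005, 0.001)
        ranks = [COLOUR_ORDER.index(classify_block(float(p))) for p in grid]
        assert all(b >= a for a, b in zip(ranks, ranks[1:]))


class TestBlockChemogram:
    def test_constant_tile_value(self):
        p = np.full((10, 8), 0.7)
        bc = block_chemogram(p, (0, 8), mm_per_column=0.5, block_mm=2.0)
        assert len(bc.blocks) == 2
        for b in bc.blocks:
            assert b.value == pytest.approx(0.7)
            assert b.colour_class == "orange"

    def test_90th_percentile_of_known_values(self):
        # one 2 mm tile of 100 pixels valued 1..100 (as probabilities /100)
        vals = (np.arange(1, 101, dtype=float) / 100).reshape(25, 4)
        bc = block_chemogram(vals, (0, 4), mm_per_column=0.5, block_mm=2.0)
        expected = np.percentile(vals, 90, method="linear")
        assert bc.blocks[0].value == pytest.approx(expected)

    def test_trailing_partial_block_flagged(self):
        p = np.full((6, 10), 0.2)
        bc = block_chemogram(p, (0, 10), mm_per_column=0.5, block_mm=2.0)
        # 5 mm ROI -> blocks at 0, 2 mm plus a 1 mm partial at 4 mm
        assert [b.start_mm for b in bc.blocks] == [0.0, 2.0, 4.0]
        assert [b.partial for b in bc.blocks] == [False, False, True]
        assert bc.blocks[-1].colour_class is None

    def test_nan_pixels_ignored(self):
        p = np.full((4, 4), 0.9)
        p[:2, :] = np.nan
        bc = block_chemogram(p, (0, 4), mm_per_column=0.5, block_mm=2.0)
        assert bc.blocks[0].value == pytest.approx(0.9)


class TestMaxLipidArc:
    def test_full_column_is_360(self):
        lip = np.zeros((36, 4), dtype=bool)
        lip[:, 1] = True
        arcs = max_lipid_arc(_mask(lip), (0, 4), 10.0, 0.5, block_mm=2.0)
        assert arcs[0][1] == pytest.approx(360.0)

    def test_contiguous_run_scales_with_degrees_per_row(self):
        lip = np.zeros((360, 4), dtype=bool)
        lip[100:190, 2] = True
        arcs = max_lipid_arc(_mask(lip), (0, 4), 1.0, 0.5, block_mm=2.0)
        assert arcs[0][1] == pytest.approx(90.0)

    def test_run_wrapping_seam_is_single(self):
        lip = np.zeros((360, 4), dtype=bool)
        lip[350:, 0] = True
        lip[:20, 0] = True
        arcs = max_lipid_arc(_mask(lip), (0, 4), 1.0, 0.5, block_mm=2.0)
        assert arcs[0][1] == pytest.approx(30.0)

    def test_empty_lipid_is_zero(self):
        arcs = max_lipid_arc(
            _mask(np.zeros((36, 8))), (0, 8), 10.0, 0.5, block_mm=2.0
        )
        assert all(a == 0.0 for _, a in arcs)
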