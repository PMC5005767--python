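import itertools

import numpy as np
import pytest
from scipy import stats as sps

from chemolipid.errors import DegenerateDataError
from chemolipid.stats import (
    agreement,
    bland_altman,
    icc,
    paired_wilcoxon,
    summarize,
)


def signed_rank_p_by_enumeration(d):
    """Exhaustive oracle: enumerate all 2^n sign assignments of |d| and
    count assignments with a W+ at least as extreme (two-sided, doubled
    smaller tail, capped at 1)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.asarray(ws)
    lower = np.mean(ws <= w_obs + 1e-9)
    upper = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(lower, upper))


class TestPairedWilcoxon:
    def test_identical_vectors_give_p_one(self):
        assert paired_wilcoxon([1, 2, 3], [1, 2, 3]) == 1.0

    def test_doubling_pairs_match_enumeration(self):
        m1 = [1, 2, 3, 4, 5]
        m2 = [2, 4, 6, 8, 10]
        expected = signed_rank_p_by_enumeration(np.subtract(m1, m2))
        assert paired_wilcoxon(m1, m2) == pytest.approx(expected)

    def test_single_pair_is_one(self):
        assert paired_wilcoxon([1.0], [2.0]) == pytest.approx(1.0)

    def test_matches_enumeration_on_small_samples(self, rng):
        # every n <= 8, random data with occasional ties in |d|
        for n in range(2, 9):
            for _ in range(10):
                d = rng.integers(-5, 6, size=n)
                base = rng.integers(0, 50, size=n)  # exact float subtraction
                m1, m2 = (base + d).astype(float), base.astype(float)
                expected = signed_rank_p_by_enumeration(d.astype(float))
                got = paired_wilcoxon(m1, m2)
                if (d == 0).all():
                    assert got == 1.0
                else:
                    assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_exact_when_tie_free(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 15))
            m1 = rng.normal(size=n)
            m2 = rng.normal(size=n)
            ref = sps.wilcoxon(m1, m2, method="exact").pvalue
            assert paired_wilcoxon(m1, m2) == pytest.approx(ref, abs=1e-10)

    def test_symmetric_under_swap(self, rng):
        m1, m2 = rng.normal(size=12), rng.normal(size=12)
        assert paired_wilcoxon(m1, m2) == pytest.approx(paired_wilcoxon(m2, m1))

    def test_large_n_uses_valid_approximation(self, rng):
        m1 = rng.normal(size=60)
        m2 = m1 + rng.normal(0.5, 1, size=60)
        p = paired_wilcoxon(m1, m2)
        ref = sps.wilcoxon(m1, m2, method="approx", correction=False).pvalue
        assert p == pytest.approx(ref)


class TestIcc:
    def test_perfect_agreement(self):
        v = [1.0, 2.0, 3.0, 4.0, 5.0]
        est, lo, hi = icc(v, v)
        assert est == pytest.approx(1.0)

    def test_offset_penalised_by_absolute_agreement(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        est_abs, _, _ = icc(v, v + 10.0)
        est_con, _, _ = icc(v, v + 10.0, form="ICC3")
        assert est_abs < est_con
        assert est_con == pytest.approx(1.0)

    def test_independent_noise_has_low_icc(self, rng):
        hits = 0
        for _ in range(100):
            a, b = rng.normal(size=50), rng.normal(size=50)
            est, _, _ = icc(a, b)
            hits += abs(est) < 0.3
        assert hits >= 95

    def test_scale_invariance(self, rng):
        a = rng.normal(10, 3, size=20)
        b = a + rng.normal(0, 0.5, size=20)
        e1, _, _ = icc(a, b)
        e2, _, _ = icc(3.7 * a, 3.7 * b)
        assert e1 == pytest.approx(e2, abs=1e-9)

    def test_matches_direct_anova_computation(self):
        # ICC(2,1) from two-way ANOVA mean squares on a fixed 5-pair table
        a = np.array([9.0, 8.0, 7.0, 6.0, 5.0])
        b = np.array([8.0, 7.5, 6.0, 6.5, 4.0])
        n, k = 5, 2
        table = np.c_[a, b]
        grand = table.mean()
        ms_rows = k * ((table.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        ms_cols = n * ((table.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        resid = table - table.mean(axis=1)[:, None] - table.mean(axis=0) + grand
        ms_err = (resid**2).sum() / ((n - 1) * (k - 1))
        expected = (ms_rows - ms_err) / (
            ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
        )
        est, _, _ = icc(a, b)
        assert est == pytest.approx(expected, abs=1e-9)

    def test_constant_data_flagged(self):
        with pytest.raises(DegenerateDataError):
            icc([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError):
            icc([1.0, 2.0], [1.0, 2.0])


class TestBlandAltman:
    def test_identical_vectors(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba["mean_diff"] == 0.0
        assert ba["loa_low"] == ba["loa_high"] == 0.0

    def test_two_point_hand_computation(self):
        # diffs {-1, +1}: mean 0, sample SD sqrt(2), limits +/- 2*sqrt(2)
        ba = bland_altman([0.0, 2.0], [1.0, 1.0])
        assert ba["mean_diff"] == pytest.approx(0.0)
        assert ba["loa_high"] == pytest.approx(2 * np.sqrt(2))
        assert ba["loa_low"] == pytest.approx(-2 * np.sqrt(2))

    def test_constant_offset(self):
        ba = bland_altman([5.0, 6.0, 7.0], [2.0, 3.0, 4.0])
        assert ba["mean_diff"] == pytest.approx(3.0)
        assert ba["loa_low"] == ba["loa_high"] == pytest.approx(3.0)

    def test_limits_widen_with_variance(self, rng):
        a = rng.normal(size=30)
        narrow = bland_altman(a, a + rng.normal(0, 0.1, size=30))
        wide = bland_altman(a, a + rng.normal(0, 2.0, size=30))
        assert (wide["loa_high"] - wide["loa_low"]) > (
            narrow["loa_high"] - narrow["loa_low"]
        )

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestSummarize:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 2, 3, 4, 5], (3.0, 2.0, 4.0)),
            ([23], (23.0, 23.0, 23.0)),
            ([9, 23, 97], (23.0, 16.0, 60.0)),  # linear interpolation
        ],
    )
    def test_median_and_quartiles(self, values, expected):
        assert summarize(values) == pytest.approx(expected)


def test_agreement_panel_self_comparison():
    v = [10.0, 25.0, 40.0, 55.0, 70.0]
    res = agreement(v, v)
    assert res.wilcoxon_p == 1.0
    assert res.icc_estimate == pytest.approx(1.0)
    assert res.mean_diff == 0.0
    assert res.loa_low <= res.mean_diff <= res.loa_high
    assert res.median_1 == res.median_2 == 40.0


def test_bland_altman_plot_writes_file(tmp_path, rng):
    from chemolipid.stats import bland_altman_plot

    a = rng.normal(100, 20, size=15)
    b = a + rng.normal(0, 5, size=15)
    out = tmp_path / "ba.png"
    bland_altman_plot(a, b, out)
    assert out.stat().st_size > 0
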