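"""Method-agreement statistics for paired LCBI measurements.

Agreement between two measurement methods (e.g. this pipeline vs a
commercial console, or pipeline vs synthetic ground truth) is assessed the
way method-comparison studies conventionally do: a paired Wilcoxon
signed-rank test for systematic shift, the intraclass correlation
coefficient ICC(2,1) (two-way random effects, absolute agreement, single
measures) with its 95% F-based confidence interval, and Bland-Altman limits
of agreement at mean +/- 2 standard deviations of the differences.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError

__all__ = [
    "AgreementResult",
    "paired_wilcoxon",
    "icc",
    "bland_altman",
    "summarize",
    "agreement",
    "bland_altman_plot",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgreementResult:
    wilcoxon_p: float
    icc_estimate: float
    icc_ci_low: float
    icc_ci_high: float
    mean_diff: float
    loa_low: float
    loa_high: float
    median_1: float
    q1_1: float
    q3_1: float
    median_2: float
    q1_2: float
    q3_2: float
    n: int


def _paired(m1, m2) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(m1, dtype=np.float64)
    b = np.asarray(m2, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired measurements must be equal-length 1-D vectors")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("paired measurements must be finite")
    return a, b


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic under H0.

    Under the null each pair's sign is an independent fair coin, so the
    distribution of W+ is the convolution of {0, r_i} point masses.  Ranks
    are midranks; doubling makes them integers so the distribution can be
    built by dynamic programming over 2*W+.
    """
    r2 = np.round(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2 * w_plus))
    lower = dist[: w2 + 1].sum()
    upper = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def paired_wilcoxon(m1, m2, exact_limit: int = 25) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped before ranking (the classic signed-rank
    convention); if every difference is zero the methods are
    indistinguishable and p = 1 is returned with a log flag.  With at most
    ``exact_limit`` non-zero pairs the p-value is exact (sign-flip
    enumeration, midranks handle ties); beyond that the normal approximation
    with tie correction is used.
    """
    a, b = _paired(m1, m2)
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        log.info("paired_wilcoxon: all differences zero, p = 1")
        return 1.0
    if n <= exact_limit:
        ranks = sps.rankdata(np.abs(d))
        w_plus = float(ranks[d > 0].sum())
        return _exact_signed_rank_p(ranks, w_plus)
    return float(
        sps.wilcoxon(d, zero_method="wilcox", method="approx", correction=False).pvalue
    )


def icc(m1, m2, form: str = "ICC2") -> tuple[float, float, float]:
    """Intraclass correlation between two raters; returns (est, lo, hi).

    Default form ICC2 = two-way random effects, absolute agreement, single
    measures — the right form when asking whether two methods are
    interchangeable (a constant offset between methods is penalised).
    Requires n >= 3 pairs; zero total variance leaves the ICC undefined.
    """
    a, b = _paired(m1, m2)
    n = a.size
    if n < 3:
        raise ValueError(f"ICC requires n >= 3 pairs, got {n}")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        raise DegenerateDataError("zero total variance; ICC undefined")
    import pingouin as pg

    # McGraw & Wong labels used by pingouin: A = absolute agreement (two-way
    # random), C = consistency (two-way mixed), 1 = one-way random.
    label = {"ICC1": "ICC(1,1)", "ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)"}[form]
    df = pd.DataFrame(
        {
            "targets": np.tile(np.arange(n), 2),
            "raters": np.repeat(["m1", "m2"], n),
            "scores": np.concatenate([a, b]),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        # perfect agreement gives MSE = 0; the F ratio overflow is benign
        table = pg.intraclass_corr(
            data=df, targets="targets", raters="raters", ratings="scores"
        ).set_index("Type")
    row = table.loc[label]
    lo, hi = row["CI95"]
    return float(row["ICC"]), float(lo), float(hi)


def bland_altman(m1, m2) -> dict:
    """Bland-Altman agreement of method1 vs method2.

    Differences are ``method1 - method2``; limits of agreement are
    ``mean_diff +/- 2 * SD`` with the sample (n-1) standard deviation.
    Returns the per-pair means and differences too, for plotting.
    """
    a, b = _paired(m1, m2)
    if a.size < 2:
        raise ValueError("Bland-Altman requires n >= 2 pairs")
    diffs = a - b
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return {
        "mean_diff": mean_diff,
        "loa_low": mean_diff - 2.0 * sd,
        "loa_high": mean_diff + 2.0 * sd,
        "means": (a + b) / 2.0,
        "diffs": diffs,
    }


def summarize(values) -> tuple[float, float, float]:
    """Median with first and third quartiles (linear interpolation)."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 1:
        raise ValueError("summarize requires at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def agreement(m1, m2) -> AgreementResult:
    """Full agreement panel for one metric: Wilcoxon, ICC, Bland-Altman."""
    a, b = _paired(m1, m2)
    est, lo, hi = icc(a, b)
    ba = bland_altman(a, b)
    med1, q11, q31 = summarize(a)
    med2, q12, q32 = summarize(b)
    return AgreementResult(
        wilcoxon_p=paired_wilcoxon(a, b),
        icc_estimate=est,
        icc_ci_low=lo,
        icc_ci_high=hi,
        mean_diff=ba["mean_diff"],
        loa_low=ba["loa_low"],
        loa_high=ba["loa_high"],
        median_1=med1,
        q1_1=q11,
        q3_1=q31,
        median_2=med2,
        q1_2=q12,
        q3_2=q32,
        n=a.size,
    )


def bland_altman_plot(m1, m2, path, title: str = "Bland-Altman") -> None:
    """Write a difference-vs-mean plot with mean and +/- 2 SD lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = bland_altman(m1, m2)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba["means"], ba["diffs"], s=18, color="k")
    ax.axhline(ba["mean_diff"], color="C0", label="mean diff.")
    for y in (ba["loa_low"], ba["loa_high"]):
        ax.axhline(y, color="C0", linestyle="--")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (method1 - method2)")
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
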