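"""MRR aggregation and the paired significance machinery.

Each masking experiment yields, per relation (or per gene), fifteen paired
runs on the base and the augmented knowledge graph, paired by seed.  The
comparison reports mean +/- SD of the per-run MRRs and two two-tailed paired
tests — Student's t on the differences and the Wilcoxon signed-rank test —
each Bonferroni-adjusted over the experiment family (7 relations, or the
gene list).

The Wilcoxon implementation follows the signed-rank convention: zero
differences are dropped, absolute differences ranked with mid-ranks on ties,
statistic = the smaller signed-rank sum; the two-tailed p-value is exact
(full sign-flip enumeration, computed by dynamic programming) for effective
n <= 25 and a normal approximation with continuity and tie correction above.
Benjamini–Hochberg is the step-up q-value construction used by the omics
stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_WILCOXON_MAX_N = 25


class DegenerateDataError(ValueError):
    pass


def mean_reciprocal_rank(reciprocal_ranks) -> float:
    """Arithmetic mean of per-positive reciprocal ranks (entries in (0, 1])."""
    rr = np.asarray(reciprocal_ranks, dtype=float)
    if rr.size == 0:
        raise ValueError("cannot average an empty list of reciprocal ranks")
    if np.any(rr <= 0) or np.any(rr > 1):
        raise ValueError("reciprocal ranks must lie in (0, 1]")
    return float(rr.mean())


def paired_t_test(x, y) -> tuple[float, float]:
    """Two-tailed paired t-test: one-sample t on differences, n-1 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.allclose(d, d[0]) and np.isclose(np.var(d), 0.0):
        raise DegenerateDataError("all differences equal; variance is zero")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def _signed_rank_sums(d: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(W+, W-, ranks of |d|) after dropping zero differences."""
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateDataError("all differences are zero")
    ranks = sps.rankdata(np.abs(d), method="average")
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    return w_plus, w_minus, ranks


def _exact_wilcoxon_cdf_p(ranks: np.ndarray, w_small: float) -> float:
    """Exact two-tailed p by DP over all 2^n equally likely sign vectors.

    Mid-ranks can be half-integers, so ranks are doubled to integers and the
    distribution of 2*W+ is built by convolution.  The null distribution of
    W+ is symmetric about S/2 (S = sum of ranks), hence the two-tailed
    p-value is 2 * P(W+ <= w_small), capped at 1.
    """
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    threshold = int(np.rint(2.0 * w_small))
    p = 2.0 * counts[: threshold + 1].sum()
    return float(min(1.0, p))


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Two-tailed Wilcoxon signed-rank test on paired samples.

    Returns (statistic, p) with statistic = min(W+, W-).  Exact null
    distribution for effective n <= 25, else normal approximation with
    continuity correction and the tie correction to the null variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    w_plus, w_minus, ranks = _signed_rank_sums(x - y)
    w = min(w_plus, w_minus)
    n_eff = ranks.size
    if n_eff <= EXACT_WILCOXON_MAX_N:
        p = _exact_wilcoxon_cdf_p(ranks, w)
    else:
        mean = n_eff * (n_eff + 1) / 4.0
        var = n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= np.sum(tie_counts**3 - tie_counts) / 48.0
        z = (w - mean + 0.5) / np.sqrt(var)  # continuity-corrected lower tail
        p = float(min(1.0, 2.0 * sps.norm.cdf(z)))
    return float(w), p


def bonferroni_adjust(p: float, m: int) -> float:
    """min(1, m * p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up BH q-values, returned in the input order.

    q_(i) = min_{j >= i} m * p_(j) / j over the ascending order statistics,
    capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


@dataclass
class ComparisonRow:
    label: str
    mean_base: float
    sd_base: float
    mean_augmented: float
    sd_augmented: float
    t_statistic: float
    t_p: float
    t_p_bonferroni: float
    wilcoxon_statistic: float
    wilcoxon_p: float
    wilcoxon_p_bonferroni: float
    degenerate: bool = False


def summarize_comparison(
    runs_base: dict[str, np.ndarray],
    runs_augmented: dict[str, np.ndarray],
    m_corrections: int | None = None,
) -> pd.DataFrame:
    """Per-label MRR summary table with paired tests and Bonferroni adjustment.

    ``runs_base`` and ``runs_augmented`` map each experiment label (relation
    or gene) to its per-run MRR vector; runs must be paired by seed, equal
    counts per label.  Sample SDs use the n-1 denominator.  Labels whose
    paired differences are all zero are flagged degenerate (p-values NaN)
    rather than erroring, since identical arms carry no evidence either way.
    """
    if set(runs_base) != set(runs_augmented):
        raise ValueError("base and augmented runs must cover the same labels")
    m = m_corrections if m_corrections is not None else len(runs_base)
    rows: list[ComparisonRow] = []
    for label in sorted(runs_base):
        base = np.asarray(runs_base[label], dtype=float)
        aug = np.asarray(runs_augmented[label], dtype=float)
        if base.shape != aug.shape:
            raise ValueError(f"label {label!r}: unpaired run counts")
        try:
            t_stat, t_p = paired_t_test(aug, base)
            w_stat, w_p = wilcoxon_signed_rank(aug, base)
            degenerate = False
        except DegenerateDataError:
            t_stat = t_p = w_stat = w_p = float("nan")
            degenerate = True
        rows.append(
            ComparisonRow(
                label=label,
                mean_base=float(base.mean()),
                sd_base=float(base.std(ddof=1)),
                mean_augmented=float(aug.mean()),
                sd_augmented=float(aug.std(ddof=1)),
                t_statistic=t_stat,
                t_p=t_p,
                t_p_bonferroni=bonferroni_adjust(t_p, m) if not degenerate else float("nan"),
                wilcoxon_statistic=w_stat,
                wilcoxon_p=w_p,
                wilcoxon_p_bonferroni=(
                    bonferroni_adjust(w_p, m) if not degenerate else float("nan")
                ),
                degenerate=degenerate,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
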