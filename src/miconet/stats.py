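"""Cohort statistics: bootstrap mean tests, paired Wilcoxon, Pearson
correlation, and fold-change / percent-change summaries.

The bootstrap mean test compares two groups of metric values under the
shifted-null: both groups are translated to the pooled mean, resampled
with replacement within groups, and the two-sided p-value of the observed
(studentized) mean difference is taken with the +1/(B+1) small-sample
correction.

The paired Wilcoxon signed-rank test drops zero differences (Wilcoxon's
rule; Pratt's variant available), mid-ranks ties, and uses the exact null
distribution of the signed-rank sum for n <= 25 (computed by dynamic
programming over the observed rank multiset) and a tie-corrected normal
approximation above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from ._rng import child_rng


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_resamples: int | None = None
    group_sizes: tuple[int, ...] = ()
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass
class ChangeSummary:
    """Post-vs-baseline change of a mean quantity."""

    baseline_mean: float
    followup_mean: float

    @property
    def fold_change(self) -> float:
        return self.followup_mean / self.baseline_mean

    @property
    def percent_change(self) -> float:
        return 100.0 * (self.followup_mean - self.baseline_mean) / self.baseline_mean

    # presentation-layer rounding used in reports
    @property
    def fold_change_2dp(self) -> float:
        return round(self.fold_change, 2)

    @property
    def percent_change_int(self) -> int:
        return int(round(self.percent_change))


def change_summary(baseline_mean: float, followup_mean: float) -> ChangeSummary:
    if baseline_mean <= 0:
        raise ValueError("baseline mean must be positive")
    return ChangeSummary(float(baseline_mean), float(followup_mean))


def bootstrap_mean_test(
    values_a,
    values_b,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Two-sided bootstrap test for a difference in group means.

    Statistic is mean(a) - mean(b). Under the null both groups are shifted
    to the pooled mean and resampled with replacement within groups; the
    comparison is studentized (the usual textbook two-sample bootstrap
    test), which calibrates the test at small n where the raw
    mean-difference version is anti-conservative;
    p = (1 + #{|t*| >= |t_obs|}) / (B + 1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 3 or nb < 3:
        raise ValueError("each group needs at least 3 values")
    obs = a.mean() - b.mean()
    se_obs = np.sqrt(a.var(ddof=1) / na + b.var(ddof=1) / nb)
    if se_obs == 0:
        p = 1.0 if obs == 0 else 1.0 / (n_resamples + 1)
        return TestResult(
            statistic=float(obs),
            p_value=p,
            method="bootstrap mean difference (shifted null, studentized)",
            n_resamples=n_resamples,
            group_sizes=(na, nb),
        )
    t_obs = obs / se_obs
    pooled = np.concatenate([a, b]).mean()
    a0 = a - a.mean() + pooled
    b0 = b - b.mean() + pooled
    rng = child_rng(seed, "bootstrap_mean_test")
    ra = a0[rng.integers(0, na, size=(n_resamples, na))]
    rb = b0[rng.integers(0, nb, size=(n_resamples, nb))]
    diff = ra.mean(axis=1) - rb.mean(axis=1)
    se = np.sqrt(ra.var(axis=1, ddof=1) / na + rb.var(axis=1, ddof=1) / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.where(diff == 0, 0.0, np.inf))
    extreme = int((np.abs(t) >= abs(t_obs) - 1e-12).sum())
    p = (1 + extreme) / (n_resamples + 1)
    return TestResult(
        statistic=float(obs),
        p_value=min(1.0, p),
        method="bootstrap mean difference (shifted null, studentized)",
        n_resamples=n_resamples,
        group_sizes=(na, nb),
    )


def _signed_rank_exact_pmf(double_ranks: np.ndarray) -> np.ndarray:
    """Null pmf of W+ over doubled (hence integer) mid-ranks, by DP."""
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in double_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    return counts / counts.sum()


def paired_wilcoxon(
    before, after, zero_method: str = "wilcox", exact_max_n: int = 25
) -> TestResult:
    """Paired Wilcoxon signed-rank test on after - before.

    Exact two-sided p (respecting ties via mid-ranks) for n <= exact_max_n;
    tie-corrected normal approximation otherwise. All-zero differences give
    p = 1 with a flag.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after must have equal length")
    d = after - before
    if zero_method == "wilcox":
        d = d[d != 0]
    elif zero_method != "pratt":
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")
    if len(d) == 0:
        return TestResult(
            statistic=0.0,
            p_value=1.0,
            method="wilcoxon signed-rank (all differences zero)",
            group_sizes=(len(before),),
            extra={"flag": "all differences zero"},
        )
    ranks = sps.rankdata(np.abs(d))
    if zero_method == "pratt":
        nonzero = d != 0
        w_plus = float(ranks[nonzero & (d > 0)].sum())
        ranks_used = ranks[nonzero]
        n_eff = int(nonzero.sum())
    else:
        w_plus = float(ranks[d > 0].sum())
        ranks_used = ranks
        n_eff = len(d)
    if n_eff < 5:
        raise ValueError("need at least 5 non-zero differences")

    if n_eff <= exact_max_n:
        dbl = np.rint(2 * ranks_used).astype(int)
        pmf = _signed_rank_exact_pmf(dbl)
        w2 = int(round(2 * w_plus))
        cdf = pmf[: w2 + 1].sum()
        sf = pmf[w2:].sum()
        p = min(1.0, 2 * min(cdf, sf))
        method = "wilcoxon signed-rank (exact)"
    else:
        mu = ranks_used.sum() / 2
        var = (ranks_used**2).sum() / 4  # tie-corrected: sum of squared ranks
        z = (w_plus - mu) / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
        method = "wilcoxon signed-rank (normal approximation)"
    return TestResult(
        statistic=w_plus,
        p_value=p,
        method=method,
        group_sizes=(len(before),),
        extra={"n_effective": n_eff},
    )


def pearson_correlation(x, y) -> TestResult:
    """Pearson r with the Student-t two-sided p on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return TestResult(statistic=r, p_value=0.0, method="pearson", group_sizes=(n,))
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return TestResult(
        statistic=r, p_value=p, method="pearson", group_sizes=(n,), extra={"t": float(t)}
    )
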