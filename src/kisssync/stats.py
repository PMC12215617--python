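"""Nonparametric and parametric tests with the reporting conventions of the
pulse-generator analyses.

The rank tests report the statistics as they appear in the source analyses:
the Wilcoxon matched-pairs statistic W is the *absolute sum of signed ranks*
(so six paired observations all changing in one direction give W = 21), the
Mann-Whitney statistic is U = min(U1, U2), and two-group comparisons carry the
difference of group mean ranks on the pooled ranking ("mean rank delta").
Exact p-values are computed by full enumeration at desk scale (Wilcoxon
n <= 25; Mann-Whitney n1 + n2 <= 20) and by a normal approximation with
midrank tie correction beyond that.  Family-wise adjustment uses the
step-down Holm-Sidak procedure.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "PairedSample",
    "TwoGroupSample",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "holm_sidak_adjust",
    "paired_t",
    "unpaired_t",
    "rm_one_way_anova",
    "leave_one_animal_out",
    "percent_reduction",
]

# enumeration cutoffs; beyond these a tie-corrected normal approximation is used
WILCOXON_EXACT_MAX_N = 25
MANNWHITNEY_EXACT_MAX_N = 20


@dataclass
class TestResult:
    """One test outcome with the fields the analyses print."""

    statistic_name: str
    statistic_value: float
    p_raw: float
    method: str
    df: Optional[tuple] = None
    mean_rank_delta: Optional[float] = None
    p_adjusted: Optional[float] = None
    family_size: Optional[int] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0):
            raise ValueError(f"p_raw outside [0, 1]: {self.p_raw}")
        if self.p_adjusted is not None and self.p_adjusted < self.p_raw - 1e-12:
            raise ValueError("p_adjusted below p_raw")


@dataclass
class PairedSample:
    before: Sequence[float]
    after: Sequence[float]
    unit_ids: Optional[Sequence] = None

    def __post_init__(self) -> None:
        if len(self.before) != len(self.after):
            raise ValueError("paired sample requires equal lengths")
        if self.unit_ids is not None and len(self.unit_ids) != len(self.before):
            raise ValueError("unit_ids length mismatch")


@dataclass
class TwoGroupSample:
    group1: Sequence[float]
    group2: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.group1) == 0 or len(self.group2) == 0:
            raise ValueError("both groups must be non-empty")


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


# ---------------------------------------------------------------------------
# Wilcoxon matched-pairs signed-rank test
# ---------------------------------------------------------------------------

def _wilcoxon_exact_p(signed_sum: float, ranks: np.ndarray) -> float:
    """Two-sided P(|sum of +/- ranks| >= |signed_sum|) over all 2^n sign
    assignments, via a subset-sum count on doubled (integer) midranks."""
    d = np.round(2 * ranks).astype(int)  # midranks are half-integers
    total = int(d.sum())
    # counts[t] = number of positive-subsets with doubled rank-sum t
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for di in d:
        counts[di:] += counts[: total + 1 - di]
    # signed sum for subset t is (2t - total)/2 in original units
    t_grid = np.arange(total + 1)
    signed = (2 * t_grid - total) / 2.0
    hits = counts[np.abs(signed) >= abs(signed_sum) - 1e-9].sum()
    return float(hits) / float(2 ** len(d))


def wilcoxon_signed_rank(sample: PairedSample) -> TestResult:
    """Two-tailed Wilcoxon matched-pairs signed-rank test.

    W is the absolute value of the sum of signed ranks of the non-zero
    differences (after - before); zero differences are dropped.  Exact p by
    full enumeration for n <= 25 non-zero pairs, else normal approximation
    with midrank tie handling.
    """
    before = np.asarray(sample.before, dtype=float)
    after = np.asarray(sample.after, dtype=float)
    diffs = after - before
    diffs = diffs[diffs != 0.0]
    n = diffs.size
    if n < 2:
        raise ValueError("need at least two non-zero differences")
    ranks = _midranks(np.abs(diffs))
    signed_sum = float(np.sum(np.sign(diffs) * ranks))
    w = abs(signed_sum)
    if n <= WILCOXON_EXACT_MAX_N:
        p = _wilcoxon_exact_p(signed_sum, ranks)
        method = f"wilcoxon signed-rank, exact enumeration (n={n})"
    else:
        sigma = math.sqrt(float(np.sum(ranks**2)))
        z = signed_sum / sigma
        p = 2.0 * sps.norm.sf(abs(z))
        method = f"wilcoxon signed-rank, normal approximation (n={n})"
    return TestResult(
        statistic_name="W",
        statistic_value=w,
        p_raw=min(p, 1.0),
        method=method,
        extras={"n": n, "signed_rank_sum": signed_sum},
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U test
# ---------------------------------------------------------------------------

def _mann_whitney_exact_p(pooled_ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided P(min(U1, U2) <= u_obs) over all group-1 index choices,
    on the observed pooled midranks (exact under the permutation null)."""
    n = pooled_ranks.size
    n2 = n - n1
    hits = 0
    total = 0
    base = n1 * (n1 + 1) / 2.0
    for combo in itertools.combinations(range(n), n1):
        r1 = pooled_ranks[list(combo)].sum()
        u1 = r1 - base
        u = min(u1, n1 * n2 - u1)
        if u <= u_obs + 1e-9:
            hits += 1
        total += 1
    return hits / total


def mann_whitney(sample: TwoGroupSample) -> TestResult:
    """Two-tailed Mann-Whitney U test with mean-rank-difference reporting.

    U = min(U1, U2).  mean_rank_delta = mean rank of group 2 minus mean rank
    of group 1 on the pooled midranking; under complete separation of the
    groups this equals +/-(n1 + n2)/2 and U = 0.  Exact p by enumeration of
    all group assignments for n1 + n2 <= 20.
    """
    g1 = np.asarray(sample.group1, dtype=float)
    g2 = np.asarray(sample.group2, dtype=float)
    n1, n2 = g1.size, g2.size
    pooled = np.concatenate([g1, g2])
    ranks = _midranks(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    delta = float(ranks[n1:].mean() - ranks[:n1].mean())
    if n1 + n2 <= MANNWHITNEY_EXACT_MAX_N:
        p = _mann_whitney_exact_p(ranks, n1, u)
        method = f"mann-whitney, exact enumeration (n1={n1}, n2={n2})"
    else:
        nn = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (nn * (nn - 1))
        var = n1 * n2 / 12.0 * ((nn + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (u - n1 * n2 / 2.0) / math.sqrt(var)
            p = 2.0 * sps.norm.sf(abs(z))
        method = f"mann-whitney, normal approximation (n1={n1}, n2={n2})"
    return TestResult(
        statistic_name="U",
        statistic_value=float(u),
        p_raw=min(p, 1.0),
        method=method,
        mean_rank_delta=delta,
        extras={"U1": u1, "U2": u2, "n1": n1, "n2": n2},
    )


# ---------------------------------------------------------------------------
# Holm-Sidak step-down adjustment
# ---------------------------------------------------------------------------

def holm_sidak_adjust(p_values: Sequence[float], family_size: Optional[int] = None) -> list[float]:
    """Step-down Holm-Sidak adjusted p-values.

    Sorted ascending, the i-th smallest raw p (1-based) is adjusted to
    1 - (1 - p)^(k - i + 1) with k the family size, then monotonicity is
    enforced.  family_size may exceed the number of p-values supplied (tests
    belonging to the family but not reported here).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size if family_size is None else int(family_size)
    if k < p.size:
        raise ValueError("family_size smaller than number of p-values")
    order = np.argsort(p, kind="stable")
    adj = np.empty_like(p)
    running = 0.0
    for i, idx in enumerate(order):  # i is 0-based
        a = 1.0 - (1.0 - p[idx]) ** (k - i)
        running = max(running, a)
        adj[idx] = min(running, 1.0)
    return adj.tolist()


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

def paired_t(sample: PairedSample) -> TestResult:
    before = np.asarray(sample.before, dtype=float)
    after = np.asarray(sample.after, dtype=float)
    if before.size < 2:
        raise ValueError("need n >= 2 pairs")
    diffs = after - before
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs, 0.0):
            return TestResult("t", 0.0, 1.0, "paired t-test",
                              df=(before.size - 1,), extras={"n": before.size})
        raise ValueError("zero-variance non-zero differences: t undefined")
    res = sps.ttest_rel(after, before)
    return TestResult(
        statistic_name="t",
        statistic_value=float(res.statistic),
        p_raw=float(res.pvalue),
        method="paired t-test",
        df=(before.size - 1,),
        extras={"n": before.size, "mean_diff": float(diffs.mean())},
    )


def unpaired_t(sample: TwoGroupSample) -> TestResult:
    """Two-sided unpaired t-test; variance homogeneity is screened with a
    two-sided F-test at alpha = 0.05 and the outcome recorded (Welch used
    when homogeneity is rejected)."""
    g1 = np.asarray(sample.group1, dtype=float)
    g2 = np.asarray(sample.group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("need n >= 2 per group")
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        if g1.mean() == g2.mean():
            return TestResult("t", 0.0, 1.0, "unpaired t-test",
                              df=(g1.size + g2.size - 2,))
        raise ValueError("zero variance in both groups: t undefined")
    if v2 > 0:
        f = v1 / v2
        p_f = 2.0 * min(sps.f.cdf(f, g1.size - 1, g2.size - 1),
                        sps.f.sf(f, g1.size - 1, g2.size - 1))
    else:
        f, p_f = math.inf, 0.0
    equal_var = p_f >= 0.05
    res = sps.ttest_ind(g1, g2, equal_var=equal_var)
    df = (g1.size + g2.size - 2,) if equal_var else (float(res.df),)
    return TestResult(
        statistic_name="t",
        statistic_value=float(res.statistic),
        p_raw=float(res.pvalue),
        method="unpaired t-test" + ("" if equal_var else " (Welch)"),
        df=df,
        extras={"f_statistic": f, "f_test_p": p_f, "equal_var": equal_var},
    )


# ---------------------------------------------------------------------------
# One-way repeated-measures ANOVA with Holm-Sidak post hoc contrasts
# ---------------------------------------------------------------------------

def rm_one_way_anova(matrix: np.ndarray) -> TestResult:
    """One-way repeated-measures ANOVA on a complete units x conditions matrix.

    F has (k - 1, (k - 1)(n - 1)) degrees of freedom.  No sphericity
    correction is applied by default.  Pairwise condition contrasts are
    paired t-tests adjusted by Holm-Sidak; they are returned in
    ``extras["posthoc"]`` as {(i, j): TestResult}.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 units and >= 2 conditions")
    if np.any(np.isnan(m)):
        raise ValueError("missing cells are not supported (no imputation)")
    n, k = m.shape
    grand = m.mean()
    ss_cond = n * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    scale = max(ss_total, 1.0)
    if ss_cond / scale < 1e-14:  # no condition effect at all
        f_stat, p = 0.0, 1.0
    elif ss_err / scale < 1e-14:
        f_stat, p = math.inf, 0.0
    else:
        f_stat = (ss_cond / df_cond) / (ss_err / df_err)
        p = float(sps.f.sf(f_stat, df_cond, df_err))
    pairs = list(itertools.combinations(range(k), 2))
    raw = []
    posthoc = {}
    for i, j in pairs:
        t_res = paired_t(PairedSample(m[:, i], m[:, j]))
        posthoc[(i, j)] = t_res
        raw.append(t_res.p_raw)
    adjusted = holm_sidak_adjust(raw, family_size=len(pairs)) if pairs else []
    for (key, a) in zip(pairs, adjusted):
        posthoc[key].p_adjusted = a
        posthoc[key].family_size = len(pairs)
    return TestResult(
        statistic_name="F",
        statistic_value=float(f_stat),
        p_raw=p,
        method="one-way repeated-measures ANOVA",
        df=(df_cond, df_err),
        extras={"posthoc": posthoc, "ss_condition": float(ss_cond),
                "ss_error": float(ss_err)},
    )


# ---------------------------------------------------------------------------
# Leave-one-animal-out sensitivity analysis
# ---------------------------------------------------------------------------

def leave_one_animal_out(
    values_by_animal: Mapping[object, Sequence],
    test: Callable[[Sequence], TestResult],
    min_n: int = 2,
) -> dict:
    """Re-run ``test`` on the pooled data excluding each animal's full set of
    observations in turn.

    ``test`` receives the concatenated observations of the retained animals.
    Exclusions leaving fewer than ``min_n`` observations are skipped and map
    to None.  Requires >= 3 animals.
    """
    animals = list(values_by_animal)
    if len(animals) < 3:
        raise ValueError("leave-one-animal-out requires >= 3 animals")
    results: dict = {}
    for excluded in animals:
        retained: list = []
        for a in animals:
            if a != excluded:
                retained.extend(values_by_animal[a])
        if len(retained) < min_n:
            results[excluded] = None
            continue
        try:
            results[excluded] = test(retained)
        except ValueError:
            results[excluded] = None
    return results


def percent_reduction(pre: float, post: float) -> float:
    """100 * (pre - post) / pre; for signed response amplitudes pass
    magnitudes.  pre must be non-zero."""
    if pre == 0:
        raise ValueError("percent reduction undefined for pre = 0")
    return 100.0 * (pre - post) / pre
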