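"""Group summaries, comparisons and the modulus-conversion utility.

Quantities are reported as mean ± SEM. Two groups are compared with an
unpaired Student's t-test (Welch available by flag); more than two with
one-way ANOVA followed by a Tukey HSD post-test. Significance is flagged
at α = 0.001, matching the ``***`` convention of the source experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

DEFAULT_ALPHA = 0.001


@dataclass
class GroupSummary:
    group_name: str
    n: int
    mean: float
    sem: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")

    def __str__(self) -> str:
        return f"{self.group_name}: {self.mean:.2f} ± {self.sem:.2f} (n={self.n})"


@dataclass
class ComparisonResult:
    test: str  # 't' | 'anova' | 'anova_posthoc'
    p_value: float
    significant: bool
    groups: tuple = ()
    percent_reduction: float | None = None
    statistic: float | None = None


@dataclass
class ElasticModuli:
    """Storage modulus G' (Pa), Poisson ratio ν and Young's modulus E (Pa)."""

    g_prime_pa: float
    nu: float
    e_pa: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.nu <= 0.5:
            raise ValueError("nu must lie in [0, 0.5]")
        if not math.isclose(self.e_pa, 2.0 * self.g_prime_pa * (1.0 + self.nu)):
            raise ValueError("E must equal 2 G'(1+nu)")


def summarize(values, group_name: str = "") -> GroupSummary:
    """Mean and SEM (= sd/√n, sample sd) of one group."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty group")
    n = values.size
    sem = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return GroupSummary(group_name=group_name, n=n, mean=float(values.mean()), sem=sem)


def percent_reduction(treated_mean: float, control_mean: float) -> float:
    """100·(1 − treated/control); defined only for a positive control."""
    if control_mean <= 0:
        raise ValueError("control mean must be > 0")
    return 100.0 * (1.0 - treated_mean / control_mean)


def compare_groups(
    groups: dict,
    *,
    control: str | None = None,
    alpha: float = DEFAULT_ALPHA,
    welch: bool = False,
) -> list[ComparisonResult]:
    """Compare named groups of values.

    Two groups: unpaired Student's t-test (Welch correction off by
    default). More than two: one-way ANOVA followed by Tukey HSD on every
    pair. When ``control`` names a group, each result against it carries
    the percent reduction of the other group's mean. Degenerate (zero
    total variance) inputs report an indeterminate p (NaN), never 0.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("at least two groups are required")
    arrays = {k: np.asarray(list(v), dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs n >= 2")

    def reduction(a: str, b: str) -> float | None:
        if control is None or control not in (a, b):
            return None
        ctrl, other = (a, b) if a == control else (b, a)
        cm = arrays[ctrl].mean()
        return percent_reduction(arrays[other].mean(), cm) if cm > 0 else None

    if len(names) == 2:
        a, b = names
        if arrays[a].std() == 0 and arrays[b].std() == 0:
            return [
                ComparisonResult(
                    test="t", p_value=float("nan"), significant=False,
                    groups=(a, b), percent_reduction=reduction(a, b),
                )
            ]
        t, p = sps.ttest_ind(arrays[a], arrays[b], equal_var=not welch)
        return [
            ComparisonResult(
                test="t", p_value=float(p), significant=bool(p < alpha),
                groups=(a, b), percent_reduction=reduction(a, b),
                statistic=float(t),
            )
        ]

    f, p_anova = sps.f_oneway(*arrays.values())
    results = [
        ComparisonResult(
            test="anova", p_value=float(p_anova),
            significant=bool(p_anova < alpha), groups=tuple(names),
            statistic=float(f),
        )
    ]
    values = np.concatenate([arrays[k] for k in names])
    labels = np.concatenate([[k] * arrays[k].size for k in names])
    tk = pairwise_tukeyhsd(values, labels, alpha=0.05)
    from itertools import combinations

    for (a, b), p in zip(combinations(tk.groupsunique, 2), tk.pvalues):
        results.append(
            ComparisonResult(
                test="anova_posthoc", p_value=float(p),
                significant=bool(p < alpha), groups=(str(a), str(b)),
                percent_reduction=reduction(str(a), str(b)),
            )
        )
    return results


def permutation_t_pvalue(a, b, rng=None, n_max_exact: int = 20000) -> float:
    """Two-sided permutation p-value for the difference of means.

    Exact enumeration when the number of splits is small (n ≤ 8 per
    group); otherwise a seeded Monte-Carlo approximation. Serves as the
    independent oracle for the parametric t-test.
    """
    from itertools import combinations

    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    pooled = np.concatenate([a, b])
    n_a = a.size
    observed = abs(a.mean() - b.mean())
    n_comb = math.comb(pooled.size, n_a)
    if n_comb <= n_max_exact:
        count = 0
        idx = np.arange(pooled.size)
        total = pooled.sum()
        for comb in combinations(idx, n_a):
            sa = pooled[list(comb)].sum()
            diff = abs(sa / n_a - (total - sa) / b.size)
            if diff >= observed - 1e-12:
                count += 1
        return count / n_comb
    rng = np.random.default_rng(rng)
    count = 0
    n_iter = 20000
    for _ in range(n_iter):
        perm = rng.permutation(pooled)
        diff = abs(perm[:n_a].mean() - perm[n_a:].mean())
        if diff >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_iter + 1)


def youngs_from_shear(g_prime_pa: float, nu: float) -> float:
    """Young's modulus from storage modulus: E = 2 G'(1+ν)."""
    if g_prime_pa < 0:
        raise ValueError("G' must be >= 0")
    if not 0.0 <= nu <= 0.5:
        raise ValueError("nu must lie in [0, 0.5]")
    return 2.0 * g_prime_pa * (1.0 + nu)
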