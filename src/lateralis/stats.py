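"""Statistical comparison helpers shared across stages.

Two-group comparisons use Wilcoxon tests (signed-rank when paired,
exact rank-sum otherwise); three or more groups use one-way ANOVA with
Tukey's HSD post hoc, or Kruskal-Wallis with Dunn's post hoc when a
nonparametric design is requested. Adjusted pairwise p-values are
reported; no additional false-discovery layer is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class StatResult:
    """Outcome of a hypothesis test, with the effect size alongside p."""

    test: str
    statistic: float
    pvalue: float
    effect: float | None = None
    n: tuple[int, ...] | None = None
    pairwise: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "test": self.test,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
        }
        if self.effect is not None:
            d["effect"] = self.effect
        if self.n is not None:
            d["n"] = list(self.n)
        if self.pairwise:
            d["pairwise"] = self.pairwise
        return d


def two_group(
    a: Sequence[float], b: Sequence[float], paired: bool = False
) -> StatResult:
    """Wilcoxon two-group comparison.

    Signed-rank on paired differences, or exact rank-sum (Mann-Whitney)
    for independent samples. The effect reported is the difference of
    medians (of the paired differences' median, when paired).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2 or (paired and len(a) != len(b)):
        raise ValueError("need >= 2 observations per group (equal n when paired)")
    if paired:
        diff = a - b
        if np.all(diff == 0):
            return StatResult("wilcoxon signed-rank", 0.0, 1.0, 0.0, (len(a), len(b)))
        res = stats.wilcoxon(a, b, mode="auto")
        return StatResult(
            "wilcoxon signed-rank",
            float(res.statistic),
            float(res.pvalue),
            float(np.median(diff)),
            (len(a), len(b)),
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return StatResult(
        "wilcoxon rank-sum",
        float(res.statistic),
        float(res.pvalue),
        float(np.median(a) - np.median(b)),
        (len(a), len(b)),
    )


def dunn_test(
    groups: Sequence[Sequence[float]], adjust: str = "holm"
) -> list[dict]:
    """Dunn's rank-based pairwise post hoc test with tie correction.

    For groups i, j the statistic is
    z = (Rbar_i - Rbar_j) / sqrt(S * (1/n_i + 1/n_j)), with
    S = N(N+1)/12 - sum(t^3 - t)/(12(N-1)) over tied ranks. Two-sided
    p-values are adjusted across all pairs (Holm by default).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrs)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    s2 = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks, sizes = [], []
    offset = 0
    for arr in arrs:
        mean_ranks.append(float(ranks[offset : offset + arr.size].mean()))
        sizes.append(arr.size)
        offset += arr.size

    pairs, pvals = [], []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            se = np.sqrt(s2 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            pairs.append({"groups": (i, j), "statistic": float(z)})
            pvals.append(p)
    adj = multipletests(pvals, method=adjust)[1]
    for d, p_raw, p_adj in zip(pairs, pvals, adj):
        d["pvalue_raw"] = float(p_raw)
        d["pvalue"] = float(p_adj)
    return pairs


def stats_compare(
    groups: Sequence[Sequence[float]],
    parametric: bool = True,
    paired: bool = False,
) -> StatResult:
    """Route a comparison by design: 2 groups -> Wilcoxon; k >= 3 groups ->
    one-way ANOVA + Tukey HSD (parametric) or Kruskal-Wallis + Dunn.

    Returns the omnibus result; pairwise post hoc entries ride along in
    ``pairwise`` with adjusted p-values.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs n >= 2")
    if len(arrs) == 2:
        return two_group(arrs[0], arrs[1], paired=paired)

    if parametric:
        f, p = stats.f_oneway(*arrs)
        tk = stats.tukey_hsd(*arrs)
        pairwise = [
            {
                "groups": (i, j),
                "statistic": float(tk.statistic[i, j]),
                "pvalue": float(tk.pvalue[i, j]),
            }
            for i in range(len(arrs))
            for j in range(i + 1, len(arrs))
        ]
        return StatResult(
            "one-way ANOVA + Tukey HSD",
            float(f),
            float(p),
            n=tuple(a.size for a in arrs),
            pairwise=pairwise,
        )
    h, p = stats.kruskal(*arrs)
    return StatResult(
        "Kruskal-Wallis + Dunn",
        float(h),
        float(p),
        n=tuple(a.size for a in arrs),
        pairwise=dunn_test(arrs),
    )
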