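"""Statistics layer for comparing classification conditions.

Covers the tests used to report the experiment grid: a one-tailed Welch
t-test of fold accuracies against the shuffled-label chance run, one-way
ANOVA across the four feature-set conditions with a Tukey-Kramer post hoc
(studentized-range distribution, which handles unequal group sizes) and
Bonferroni correction over the three genotype tasks, t-based 95% confidence
intervals for fold means, and a Pearson chi-squared homogeneity test (no
continuity correction) for cohort composition tables such as subtype by
scanner field strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class StatReport:
    test_name: str
    statistic: float
    df: float | tuple
    p_value: float
    adjusted_p: Optional[float] = None
    raw_adjusted_p: Optional[float] = None  # Bonferroni product before capping
    pairwise: Optional[list[dict]] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")
        if self.adjusted_p is not None:
            if not (self.p_value <= self.adjusted_p <= 1.0):
                raise ValueError("adjusted_p must lie in [p, 1]")


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or np.any(self.counts < 0):
            raise ValueError("counts must be a nonnegative 2D table")
        if self.counts.sum() == 0:
            raise ValueError("table total must be positive")


def welch_one_tailed(sample_a: Sequence[float], sample_b: Sequence[float]) -> StatReport:
    """Welch's t-test with Satterthwaite df; one-tailed for mean(a) > mean(b)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return StatReport("welch_one_tailed", 0.0, float(a.size + b.size - 2), 0.5)
        # degenerate separation: direction decides
        p = 0.0 if a.mean() > b.mean() else 1.0
        stat = np.inf if a.mean() > b.mean() else -np.inf
        return StatReport("welch_one_tailed", stat, float(a.size + b.size - 2), p)
    res = sps.ttest_ind(a, b, equal_var=False, alternative="greater")
    return StatReport(
        "welch_one_tailed", float(res.statistic), float(res.df), float(res.pvalue)
    )


def anova_tukey(
    groups: Sequence[Sequence[float]], n_comparisons: int = 3
) -> StatReport:
    """One-way ANOVA with Tukey-Kramer post hoc and Bonferroni adjustment.

    The ANOVA p-value is Bonferroni-multiplied by ``n_comparisons`` (the
    number of classification tasks, default 3) and capped at 1; the raw
    product is kept alongside.  Pairwise p-values come from the studentized
    range distribution with the Tukey-Kramer unequal-n standard error.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    g = len(gs)
    n = sum(x.size for x in gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(x.size * (x.mean() - grand) ** 2 for x in gs)
    ssw = sum(((x - x.mean()) ** 2).sum() for x in gs)
    dfb, dfw = g - 1, n - g
    if ssw == 0:
        F = 0.0 if ssb == 0 else np.inf
        p = 1.0 if ssb == 0 else 0.0
    else:
        F = (ssb / dfb) / (ssw / dfw)
        p = float(sps.f.sf(F, dfb, dfw))
    msw = ssw / dfw if dfw > 0 else 0.0
    pairwise = []
    for i in range(g):
        for j in range(i + 1, g):
            se = np.sqrt(msw / 2.0 * (1.0 / gs[i].size + 1.0 / gs[j].size))
            if se == 0:
                p_ij = 1.0 if gs[i].mean() == gs[j].mean() else 0.0
            else:
                q = abs(gs[i].mean() - gs[j].mean()) / se
                p_ij = float(sps.studentized_range.sf(q, g, dfw))
            pairwise.append({"pair": (i, j), "p": min(max(p_ij, 0.0), 1.0)})
    raw_adj = p * n_comparisons
    return StatReport(
        "anova_tukey",
        float(F),
        (dfb, dfw),
        p,
        adjusted_p=min(raw_adj, 1.0),
        raw_adjusted_p=raw_adj,
        pairwise=pairwise,
    )


def chi_squared(table: ContingencyTable) -> StatReport:
    """Pearson chi-squared homogeneity test, no continuity correction."""
    obs = np.asarray(table.counts, dtype=float)
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero marginal in contingency table")
    total = obs.sum()
    expected = np.outer(rows, cols) / total
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return StatReport("chi_squared", stat, float(df), p)


def ci95(values: Sequence[float]) -> float:
    """t-based 95% CI half-width: t(0.975, n-1) * sd / sqrt(n), sample sd."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    return float(sps.t.ppf(0.975, v.size - 1) * v.std(ddof=1) / np.sqrt(v.size))
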