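"""Nonparametric cohort statistics.

The validation workflow for the perfusion-vector metrics: an omnibus
Kruskal-Wallis test across patient groups per metric, pairwise two-sided
Mann-Whitney tests of each abnormal group against the normal reference (run
only when the omnibus test is significant at 0.05), Bonferroni-corrected at
0.05 / k for k pairwise tests (0.0125 for four groups, 0.025 for two), and a
Spearman rank correlation between defect extent and vector magnitude.

Tests are two-sided throughout. Small samples use exact enumeration
(Mann-Whitney when n_a + n_b <= 12 without ties; Spearman when n <= 7);
larger samples use the standard tie-corrected asymptotic approximations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, SchemaError

__all__ = [
    "MannWhitneyResult",
    "KruskalWallisResult",
    "SpearmanResult",
    "PairwiseComparison",
    "GroupComparisonReport",
    "mann_whitney",
    "kruskal_wallis",
    "spearman_correlation",
    "compare_groups",
    "GROUP_LABELS",
]

#: Group vocabulary for cohort tables.
GROUP_LABELS = (
    "normal", "apical", "inferior", "anterior", "lateral", "ischemia", "infarction",
)

_MW_EXACT_MAX_N = 12
_SPEARMAN_EXACT_MAX_N = 7


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str  # "exact" or "asymptotic"


@dataclass(frozen=True)
class KruskalWallisResult:
    h: float
    p_value: float


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    method: str  # "exact" or "t-approximation"


def mann_whitney(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    Returns the U statistic of the first sample. The exact null distribution
    is enumerated when the combined size is at most 12 and there are no ties;
    otherwise the tie-corrected normal approximation (with continuity
    correction) is used. The branch taken is reported in ``method``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    small = a.size + b.size <= _MW_EXACT_MAX_N
    if small and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return MannWhitneyResult(float(res.statistic), float(res.pvalue), "exact")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), "asymptotic")


def kruskal_wallis(groups) -> KruskalWallisResult:
    """Kruskal-Wallis omnibus test with tie correction.

    p comes from the chi-square approximation with k - 1 degrees of freedom.
    When every observation is identical the statistic is 0 and p is 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise InsufficientDataError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return KruskalWallisResult(0.0, 1.0)
    res = sps.kruskal(*groups)
    return KruskalWallisResult(float(res.statistic), float(res.pvalue))


def _exact_spearman_p(x_ranks: np.ndarray, y_ranks: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all rank permutations (n <= 7)."""
    n = x_ranks.size
    xc = x_ranks - x_ranks.mean()
    denom_x = np.sqrt((xc**2).sum())
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        yp = y_ranks[list(perm)]
        yc = yp - yp.mean()
        denom = denom_x * np.sqrt((yc**2).sum())
        rho = (xc * yc).sum() / denom if denom > 0 else 0.0
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_correlation(x, y) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    For n <= 7 the two-sided p is exact by permutation enumeration; for
    larger n the usual t approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InsufficientDataError("samples must have equal length")
    if x.size < 3:
        raise InsufficientDataError("need at least 3 pairs")
    rho = float(sps.spearmanr(x, y).statistic)
    if x.size <= _SPEARMAN_EXACT_MAX_N:
        xr = sps.rankdata(x)
        yr = sps.rankdata(y)
        p = _exact_spearman_p(xr, yr, rho)
        return SpearmanResult(rho, float(p), "exact")
    p = float(sps.spearmanr(x, y).pvalue)
    return SpearmanResult(rho, p, "t-approximation")


@dataclass(frozen=True)
class PairwiseComparison:
    group: str
    u: float
    p_value: float
    threshold: float
    significant: bool
    method: str


@dataclass(frozen=True)
class GroupComparisonReport:
    """Omnibus + gated pairwise comparison of abnormal groups vs a reference."""

    metric: str
    reference: str
    omnibus: KruskalWallisResult
    omnibus_alpha: float
    bonferroni_threshold: float
    pairwise: tuple[PairwiseComparison, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "reference": self.reference,
            "kruskal_wallis": {"H": self.omnibus.h, "p": self.omnibus.p_value},
            "omnibus_alpha": self.omnibus_alpha,
            "bonferroni_threshold": self.bonferroni_threshold,
            "pairwise": [
                {
                    "group": c.group,
                    "U": c.u,
                    "p": c.p_value,
                    "threshold": c.threshold,
                    "significant": c.significant,
                    "method": c.method,
                }
                for c in self.pairwise
            ],
        }


def compare_groups(
    cohort: pd.DataFrame,
    metric: str,
    reference: str = "normal",
    group_col: str = "group",
    omnibus_alpha: float = 0.05,
) -> GroupComparisonReport:
    """Compare each abnormal group against the reference on one metric.

    Kruskal-Wallis runs across all groups (reference included). Pairwise
    Mann-Whitney tests of each non-reference group against the reference run
    only when the omnibus p falls below ``omnibus_alpha``; each is judged at
    the Bonferroni threshold ``omnibus_alpha / k`` for k pairwise tests. The
    output is independent of row order and of group label ordering.
    """
    if metric not in cohort.columns:
        raise SchemaError(f"metric column {metric!r} not in cohort table")
    if group_col not in cohort.columns:
        raise SchemaError(f"group column {group_col!r} not in cohort table")
    labels = sorted(cohort[group_col].astype(str).unique())
    if reference not in labels:
        raise SchemaError(f"reference group {reference!r} not present")
    others = [g for g in labels if g != reference]
    if not others:
        raise SchemaError("need at least one non-reference group")

    samples = {g: cohort.loc[cohort[group_col] == g, metric].to_numpy() for g in labels}
    omnibus = kruskal_wallis([samples[g] for g in labels])
    threshold = omnibus_alpha / len(others)

    pairwise: list[PairwiseComparison] = []
    if omnibus.p_value < omnibus_alpha:
        for g in others:
            mw = mann_whitney(samples[g], samples[reference])
            pairwise.append(
                PairwiseComparison(
                    group=g,
                    u=mw.u,
                    p_value=mw.p_value,
                    threshold=threshold,
                    significant=mw.p_value < threshold,
                    method=mw.method,
                )
            )
    return GroupComparisonReport(
        metric=metric,
        reference=reference,
        omnibus=omnibus,
        omnibus_alpha=omnibus_alpha,
        bonferroni_threshold=threshold,
        pairwise=tuple(pairwise),
    )
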