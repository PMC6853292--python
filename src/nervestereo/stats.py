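"""Group comparisons and summary quantities on morphometry tables.

Surface-to-volume ratios are compared with a two-tailed Student's t-test
(pooled variance by default, Welch behind a flag); basal-lamina pore sizes
with a Mann-Whitney U test whose p-value comes from full enumeration of the
permutation distribution for combined n ≤ 20 (ties handled via midranks)
and from the tie-corrected normal approximation above that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, UndefinedEstimateError
from .estimators import MorphometryResult, Phenotype

EXACT_MAX_N = 20  # combined sample size up to which the exact U distribution is enumerated

__all__ = [
    "GroupComparison",
    "compare_sv",
    "compare_pores",
    "fusion_frequency",
    "volume_fraction",
    "mann_whitney_exact",
]


@dataclass
class GroupComparison:
    group_names: tuple[str, str]
    n_per_group: tuple[int, int]
    means: tuple[float, float]
    sems: tuple[float, float]
    statistic_name: str  # "student_t_two_tailed" | "mann_whitney_u"
    statistic_value: float
    p_value: float
    alpha: float = 0.05
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha

    def to_dict(self) -> dict:
        return {
            "group_names": list(self.group_names),
            "n_per_group": list(self.n_per_group),
            "means": list(self.means),
            "sems": list(self.sems),
            "statistic_name": self.statistic_name,
            "statistic_value": self.statistic_value,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "significant": self.significant,
            **self.extra,
        }


def _summaries(x: np.ndarray) -> tuple[float, float]:
    sem = float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0
    return float(np.mean(x)), sem


def compare_sv(
    pen, fus, alpha: float = 0.05, welch: bool = False,
    group_names: tuple[str, str] = ("penetrating", "fusing"),
) -> GroupComparison:
    """Two-tailed Student's t-test between surface-to-volume ratio groups.

    Pooled-variance t with df = n₁ + n₂ − 2 (Welch with ``welch=True``).
    Two identical constant groups are reported as t = 0, p = 1.
    """
    x, y = np.asarray(pen, dtype=float), np.asarray(fus, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("each group needs n >= 2 for a t-test")
    if np.var(x) == 0 and np.var(y) == 0 and np.mean(x) == np.mean(y):
        t_val, p_val = 0.0, 1.0
    else:
        t_val, p_val = sps.ttest_ind(x, y, equal_var=not welch)
        t_val, p_val = float(t_val), float(p_val)
    df = len(x) + len(y) - 2
    mx, sx = _summaries(x)
    my, sy = _summaries(y)
    return GroupComparison(
        group_names=group_names,
        n_per_group=(len(x), len(y)),
        means=(mx, my),
        sems=(sx, sy),
        statistic_name="student_t_two_tailed",
        statistic_value=t_val,
        p_value=p_val,
        alpha=alpha,
        extra={"df": df, "welch": welch},
    )


def _u_statistic(ranks: np.ndarray, idx: np.ndarray, n1: int) -> float:
    return float(ranks[idx].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U test by full enumeration.

    Enumerates all C(n₁+n₂, n₁) group assignments of the pooled midranks and
    returns (U₁, p) with p the doubled smaller tail probability of the
    observed U₁, capped at 1.  Valid with ties (the permutation distribution
    is over the observed midranks).
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks for ties
    u_obs = _u_statistic(ranks, np.arange(n1), n1)
    total = 0
    le = ge = 0
    eps = 1e-9
    for idx in combinations(range(n1 + n2), n1):
        u = _u_statistic(ranks, np.array(idx), n1)
        total += 1
        if u <= u_obs + eps:
            le += 1
        if u >= u_obs - eps:
            ge += 1
    p = min(1.0, 2.0 * min(le, ge) / total)
    return u_obs, p


def compare_pores(
    pen, fus, alpha: float = 0.05,
    group_names: tuple[str, str] = ("penetrating", "fusing"),
) -> GroupComparison:
    """Mann-Whitney U (Wilcoxon rank-sum) test between pore-size groups.

    Exact enumeration for combined n ≤ 20, tie-corrected normal
    approximation (with continuity correction) above.  U₁ + U₂ = n₁·n₂.
    """
    x, y = np.asarray(pen, dtype=float), np.asarray(fus, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("each group needs n >= 2 for a Mann-Whitney test")
    if n1 + n2 <= EXACT_MAX_N:
        u1, p = mann_whitney_exact(x, y)
        method = "exact_enumeration"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        u1, p = float(res.statistic), float(res.pvalue)
        method = "normal_approximation_tie_corrected"
    mx, sx = _summaries(x)
    my, sy = _summaries(y)
    return GroupComparison(
        group_names=group_names,
        n_per_group=(n1, n2),
        means=(mx, my),
        sems=(sx, sy),
        statistic_name="mann_whitney_u",
        statistic_value=u1,
        p_value=p,
        alpha=alpha,
        extra={"U1": u1, "U2": n1 * n2 - u1, "method": method},
    )


def fusion_frequency(results) -> float:
    """Percentage of bundles classified fusing/mixed, to one decimal.

    Accepts MorphometryResult rows or phenotype values; rounding is
    half-away-from-zero (9 of 21 → 42.9).
    """
    items = list(results)
    if not items:
        raise InsufficientDataError("no bundles to summarize")
    phenos = [
        r.phenotype if isinstance(r, MorphometryResult) else Phenotype(r)
        for r in items
    ]
    frac = sum(p is Phenotype.FUSING_MIXED for p in phenos) / len(phenos)
    return float(
        Decimal(repr(100.0 * frac)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def volume_fraction(part: float, whole_parts) -> float:
    """``part`` / Σ(``whole_parts``); all volumes in μm³."""
    parts = [float(v) for v in whole_parts]
    if part < 0 or any(v < 0 for v in parts):
        raise UndefinedEstimateError("volumes must be >= 0")
    total = sum(parts)
    if total <= 0:
        raise UndefinedEstimateError("total volume is zero: fraction undefined")
    return float(part) / total
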