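"""Cycle-averaged group statistics.

Wilcoxon rank-sum (Mann-Whitney U) tests on the scalar gait-tube metrics,
Pearson correlation of ellipsoid volume with total variability within each
group, and a Fisher r-to-z comparison of the two independent correlations:

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))

with a two-sided standard-normal p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy import stats

from gaittube.core import SubjectSummary

__all__ = [
    "METRIC_NAMES",
    "MetricComparison",
    "CorrelationResult",
    "GroupComparison",
    "rank_sum_test",
    "pearson_with_p",
    "pearson_p_from_r",
    "fisher_compare",
    "normal_two_sided_p",
    "compare_groups",
]

METRIC_NAMES = (
    "mean_ellipsoid_volume",
    "var_ap",
    "var_ml",
    "var_vt",
    "total_variability",
)

#: Largest combined sample size for which the rank-sum null is enumerated
#: exactly (no ties).
EXACT_RANKSUM_MAX_N = 12


def rank_sum_test(x: NDArray, y: NDArray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null enumeration when n_x + n_y <= 12 and there are no ties;
    otherwise the normal approximation with midrank tie correction and
    continuity correction.  Returns (U statistic for x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= EXACT_RANKSUM_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def pearson_with_p(x: NDArray, y: NDArray) -> tuple[float, float]:
    """Pearson r with the two-sided t-based p (t = r sqrt(n-2)/sqrt(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson r at sample size n (t with n-2 df)."""
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"r must be in [-1, 1], got {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def normal_two_sided_p(z: float) -> float:
    """Two-sided standard-normal tail probability, 2 * (1 - Phi(|z|))."""
    if not np.isfinite(z):
        raise ValueError(f"z must be finite, got {z}")
    return float(2.0 * stats.norm.sf(abs(z)))


def fisher_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher r-to-z comparison of two independent Pearson correlations."""
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError(f"|r| must be < 1 for the Fisher transform, got {r}")
    for n in (n1, n2):
        if n < 4:
            raise ValueError(f"each group needs n >= 4 (n - 3 > 0), got {n}")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = float((np.arctanh(r1) - np.arctanh(r2)) / se)
    return z, normal_two_sided_p(z)


@dataclass
class MetricComparison:
    metric: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    statistic: float
    p: float
    significant: bool


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float


@dataclass
class GroupComparison:
    """All scalar group statistics for a control-vs-PAD style comparison."""

    metrics: dict[str, MetricComparison]
    correlation_a: CorrelationResult
    correlation_b: CorrelationResult
    fisher_z: float
    fisher_p: float
    alpha: float = 0.05
    group_names: tuple[str, str] = ("A", "B")
    n_a: int = 0
    n_b: int = 0
    raw: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "group_names": list(self.group_names),
            "n": {self.group_names[0]: self.n_a, self.group_names[1]: self.n_b},
            "alpha": self.alpha,
            "metrics": {
                m.metric: {
                    "mean_a": m.mean_a,
                    "mean_b": m.mean_b,
                    "sd_a": m.sd_a,
                    "sd_b": m.sd_b,
                    "statistic": m.statistic,
                    "p": m.p,
                    "significant": m.significant,
                }
                for m in self.metrics.values()
            },
            "correlation": {
                self.group_names[0]: vars(self.correlation_a),
                self.group_names[1]: vars(self.correlation_b),
            },
            "fisher": {"z": self.fisher_z, "p": self.fisher_p},
        }


def compare_groups(
    summariesA: list[SubjectSummary],
    summariesB: list[SubjectSummary],
    alpha: float = 0.05,
    group_names: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Assemble the full scalar comparison between two cohorts.

    Per metric: group means/SDs and a two-sided rank-sum test.  Per group:
    the Pearson correlation between each subject's mean ellipsoid volume and
    total variability.  Across groups: the Fisher r-to-z comparison of those
    two correlations.
    """
    if len(summariesA) < 4 or len(summariesB) < 4:
        raise ValueError("need at least 4 subjects per group")
    cols = {
        name: (
            np.array([getattr(s, name) for s in summariesA]),
            np.array([getattr(s, name) for s in summariesB]),
        )
        for name in METRIC_NAMES
    }
    metrics = {}
    for name, (a, b) in cols.items():
        stat, p = rank_sum_test(a, b)
        metrics[name] = MetricComparison(
            metric=name,
            mean_a=float(a.mean()),
            mean_b=float(b.mean()),
            sd_a=float(a.std(ddof=1)),
            sd_b=float(b.std(ddof=1)),
            statistic=stat,
            p=p,
            significant=bool(p <= alpha),
        )
    rA, pA = pearson_with_p(*[cols["mean_ellipsoid_volume"][0], cols["total_variability"][0]])
    rB, pB = pearson_with_p(*[cols["mean_ellipsoid_volume"][1], cols["total_variability"][1]])
    z, pz = fisher_compare(rA, len(summariesA), rB, len(summariesB))
    return GroupComparison(
        metrics=metrics,
        correlation_a=CorrelationResult(r=rA, n=len(summariesA), p=pA),
        correlation_b=CorrelationResult(r=rB, n=len(summariesB), p=pB),
        fisher_z=z,
        fisher_p=pz,
        alpha=alpha,
        group_names=group_names,
        n_a=len(summariesA),
        n_b=len(summariesB),
        raw={name: (a.tolist(), b.tolist()) for name, (a, b) in cols.items()},
    )
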