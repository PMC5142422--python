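"""Pooling per-observation-period kappa estimates into one summary.

A reliability study observed in g separate periods yields estimates
``kappa_m`` with variances ``V_m = SE(kappa_m)^2``.  Four summaries are
supported:

collapsed
    Kappa of the cellwise sum of all period tables.  Simple, but collapsing
    risks confounding by period effects when marginal profiles differ.
fixed
    Inverse-variance weighted mean with weights ``w_m = 1/V_m``; assumes one
    common true kappa across periods.  Cochran's heterogeneity statistic
    ``Q = sum w_m (kappa_m - kappa_fixed)^2`` on g-1 df tests that assumption.
random
    DerSimonian-Laird random-effects pooling: the between-period variance
    ``tau^2 = (Q - (g-1)) / (sum w_m - sum w_m^2 / sum w_m)`` (truncated at 0)
    enters the weights ``1/(V_m + tau^2)``; the pooled value estimates the
    mean of the distribution of kappa across periods.
averaged
    The unweighted mean of the period estimates, with
    ``SE = sqrt(sum V_m / g^2)``; the tau^2 -> infinity limit of the
    random-effects estimate.  It over-weights small periods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .kappa import (
    CrossTab,
    DegenerateAgreementError,
    EmptyTableError,
    KappaEstimate,
    tabulate_pairs,
    wald_ci,
    weighted_kappa,
)
from .weights import QUIS_SCALE, CategoryScale, WeightMatrix, named_scheme

__all__ = [
    "PeriodEstimate",
    "MetaResult",
    "StudyReport",
    "collapse_tables",
    "fixed_effect",
    "heterogeneity",
    "dl_tau2",
    "random_effect",
    "averaged",
    "analyze_study",
    "ZeroVarianceError",
    "InsufficientPeriodsError",
    "EmptyStudyError",
]

logger = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    """A period has zero estimated variance; inverse-variance weights blow up."""


class InsufficientPeriodsError(ValueError):
    """Meta-analytic pooling needs at least two periods."""


class EmptyStudyError(ValueError):
    """No period contributed a usable kappa estimate."""


@dataclass(frozen=True)
class PeriodEstimate:
    """One observation period's kappa estimate feeding the meta-analysis."""

    period_id: str
    kappa_wm: float
    V_wm: float
    n_m: int = 0

    def __post_init__(self) -> None:
        if self.V_wm < 0:
            raise ValueError(f"negative variance for period {self.period_id!r}")


@dataclass(frozen=True)
class MetaResult:
    """A pooled kappa estimate.

    ``meta_weights`` maps period id to its percentage weight within the
    method (summing to 100); heterogeneity fields and ``tau2`` are populated
    where the method defines them.
    """

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    alpha: float
    g: int
    chi2_het: float | None = None
    df: int | None = None
    het_p: float | None = None
    tau2: float | None = None
    meta_weights: dict[str, float] | None = None


def _with_ci(method: str, estimate: float, se: float, alpha: float,
             g: int, **extra) -> MetaResult:
    low, high = wald_ci(estimate, se, alpha)
    return MetaResult(
        method=method, estimate=estimate, se=se,
        ci_low=max(low, -1.0), ci_high=min(high, 1.0),
        alpha=alpha, g=g, **extra,
    )


def _validate(estimates: Sequence[PeriodEstimate], require_positive_var: bool,
              min_g: int) -> tuple[np.ndarray, np.ndarray]:
    if len(estimates) < min_g:
        raise InsufficientPeriodsError(
            f"pooling needs at least {min_g} periods, got {len(estimates)}"
        )
    k = np.array([e.kappa_wm for e in estimates])
    v = np.array([e.V_wm for e in estimates])
    if require_positive_var and np.any(v == 0):
        bad = [e.period_id for e, vi in zip(estimates, v) if vi == 0]
        raise ZeroVarianceError(
            f"zero estimated variance in period(s) {bad}; exclude them "
            "from inverse-variance pooling"
        )
    return k, v


def _percent_weights(estimates: Sequence[PeriodEstimate],
                     w: np.ndarray) -> dict[str, float]:
    total = w.sum()
    return {e.period_id: float(100.0 * wi / total)
            for e, wi in zip(estimates, w)}


def collapse_tables(tables: Iterable[CrossTab]) -> CrossTab:
    """Cellwise sum of per-period contingency tables."""
    tables = list(tables)
    if not tables:
        raise EmptyStudyError("no tables to collapse")
    scale = tables[0].scale
    for t in tables[1:]:
        if t.scale != scale:
            raise ValueError("cannot collapse tables on different scales")
    counts = np.sum([t.counts for t in tables], axis=0)
    return CrossTab(scale, counts)


def fixed_effect(estimates: Sequence[PeriodEstimate],
                 alpha: float = 0.05) -> MetaResult:
    """Inverse-variance fixed-effects pooled estimate with heterogeneity."""
    k, v = _validate(estimates, require_positive_var=True, min_g=2)
    w = 1.0 / v
    est = float(np.sum(w * k) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    chi2 = float(np.sum(w * (k - est) ** 2))
    df = len(estimates) - 1
    p = float(stats.chi2.sf(chi2, df))
    return _with_ci(
        "fixed", est, se, alpha, g=len(estimates),
        chi2_het=chi2, df=df, het_p=p,
        meta_weights=_percent_weights(estimates, w),
    )


def heterogeneity(estimates: Sequence[PeriodEstimate],
                  fixed: MetaResult | None = None) -> tuple[float, int, float]:
    """Cochran's chi-square heterogeneity test: (chi2, df, p).

    The conventional rejection rule compares chi2 with the 0.95 percentile
    of chi-square on g-1 degrees of freedom.
    """
    if fixed is None:
        fixed = fixed_effect(estimates)
    k, v = _validate(estimates, require_positive_var=True, min_g=2)
    w = 1.0 / v
    chi2 = float(np.sum(w * (k - fixed.estimate) ** 2))
    df = len(estimates) - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def dl_tau2(estimates: Sequence[PeriodEstimate]) -> float:
    """DerSimonian-Laird moment estimate of between-period variance tau^2.

    Truncated at zero when the heterogeneity statistic falls below its
    degrees of freedom.
    """
    k, v = _validate(estimates, require_positive_var=True, min_g=2)
    w = 1.0 / v
    chi2, df, _ = heterogeneity(estimates)
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if denom <= 0:
        return 0.0
    return max(0.0, (chi2 - df) / denom)


def random_effect(estimates: Sequence[PeriodEstimate],
                  alpha: float = 0.05) -> MetaResult:
    """DerSimonian-Laird random-effects pooled estimate.

    With tau^2 = 0 this coincides with the fixed-effects estimate; as tau^2
    grows the weights equalise and it approaches the simple average.
    """
    k, v = _validate(estimates, require_positive_var=True, min_g=2)
    tau2 = dl_tau2(estimates)
    chi2, df, p = heterogeneity(estimates)
    omega = 1.0 / (v + tau2)
    est = float(np.sum(omega * k) / np.sum(omega))
    se = float(np.sqrt(1.0 / np.sum(omega)))
    return _with_ci(
        "random", est, se, alpha, g=len(estimates),
        chi2_het=chi2, df=df, het_p=p, tau2=tau2,
        meta_weights=_percent_weights(estimates, omega),
    )


def averaged(estimates: Sequence[PeriodEstimate],
             alpha: float = 0.05) -> MetaResult:
    """Simple average of period estimates, SE = sqrt(sum V_m / g^2)."""
    k, v = _validate(estimates, require_positive_var=False, min_g=1)
    g = len(estimates)
    est = float(np.mean(k))
    se = float(np.sqrt(np.sum(v) / g**2))
    return _with_ci(
        "averaged", est, se, alpha, g=g,
        meta_weights={e.period_id: 100.0 / g for e in estimates},
    )


@dataclass
class StudyReport:
    """Complete single-scheme analysis of a multi-period reliability study."""

    scheme: str
    alpha: float
    scale: CategoryScale
    period_tables: dict[str, CrossTab]
    period_estimates: dict[str, KappaEstimate]
    excluded: dict[str, str]
    collapsed_table: CrossTab
    collapsed: KappaEstimate
    fixed: MetaResult | None
    random: MetaResult | None
    averaged: MetaResult | None
    messages: dict[str, str] = field(default_factory=dict)

    @property
    def estimates(self) -> list[PeriodEstimate]:
        return [
            PeriodEstimate(pid, est.kappa, est.se**2, est.n)
            for pid, est in self.period_estimates.items()
        ]


def analyze_study(
    pairs_by_period: Mapping[str, Sequence[tuple[str, str]]],
    scheme: str | WeightMatrix = "A4",
    alpha: float = 0.05,
    scale: CategoryScale = QUIS_SCALE,
) -> StudyReport:
    """Run the full pooling pipeline on per-period paired ratings.

    Periods whose kappa or SE is undefined (empty tables, degenerate
    agreement, zero variance) are excluded from fixed/random/averaged
    pooling with a logged warning, but still contribute to the collapsed
    table.  Fixed and random pooling additionally require at least two
    usable periods; when unavailable the corresponding report slots are
    ``None`` with an explanatory message.
    """
    if isinstance(scheme, WeightMatrix):
        W = scheme
        scale = W.scale
    else:
        W = named_scheme(scheme, scale)
    if not pairs_by_period:
        raise EmptyStudyError("study contains no observation periods")

    tables: dict[str, CrossTab] = {
        str(pid): tabulate_pairs(pairs, scale)
        for pid, pairs in pairs_by_period.items()
    }
    period_estimates: dict[str, KappaEstimate] = {}
    excluded: dict[str, str] = {}
    for pid, tab in tables.items():
        try:
            est = weighted_kappa(tab, W, alpha)
        except EmptyTableError:
            excluded[pid] = "no jointly rated interactions (n=0)"
            continue
        except DegenerateAgreementError:
            excluded[pid] = "expected weighted agreement is 1; kappa undefined"
            continue
        if est.se == 0.0:
            excluded[pid] = "zero estimated variance"
            continue
        period_estimates[pid] = est
    for pid, reason in excluded.items():
        logger.warning("period %s excluded from pooling: %s", pid, reason)

    collapsed_table = collapse_tables(tables.values())
    try:
        collapsed_est = weighted_kappa(collapsed_table, W, alpha)
    except (EmptyTableError, DegenerateAgreementError) as exc:
        raise EmptyStudyError(f"collapsed table unusable: {exc}") from exc

    if not period_estimates:
        raise EmptyStudyError("no period yields a defined kappa estimate")

    report = StudyReport(
        scheme=W.name or "custom",
        alpha=alpha,
        scale=scale,
        period_tables=tables,
        period_estimates=period_estimates,
        excluded=excluded,
        collapsed_table=collapsed_table,
        collapsed=collapsed_est,
        fixed=None,
        random=None,
        averaged=None,
    )
    ests = report.estimates
    report.averaged = averaged(ests, alpha)
    if len(ests) >= 2:
        report.fixed = fixed_effect(ests, alpha)
        report.random = random_effect(ests, alpha)
        if report.random.tau2 == 0.0:
            report.messages["tau2"] = (
                "DerSimonian-Laird tau^2 truncated at 0; random-effects "
                "pooling coincides with fixed-effects"
            )
            logger.warning(report.messages["tau2"])
    else:
        report.messages["pooling"] = (
            "fixed/random-effects pooling needs at least two usable "
            f"periods; only {len(ests)} available"
        )
        logger.warning(report.messages["pooling"])
    return report
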