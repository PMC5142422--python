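"""Weighted Cohen's kappa for a single cross-tabulation of paired ratings.

Two raters independently assign each of ``n`` items to one of ``k`` ordered
categories; the counts form a k-by-k contingency table with cell proportions
``p_ij`` and margins ``p_i.`` (rater 1) and ``p_.j`` (rater 2).  Given an
agreement-weight matrix ``w``:

* observed weighted agreement   ``p_o(w) = sum_ij w_ij p_ij``
* chance-expected agreement     ``p_e(w) = sum_ij w_ij p_i. p_.j``
* weighted kappa                ``k_w = (p_o(w) - p_e(w)) / (1 - p_e(w))``

The large-sample standard error follows Fleiss, Levin & Paik:

``SE = sqrt( sum_ij p_i. p_.j [w_ij - (wbar_i. + wbar_.j)]^2 - p_e(w)^2 )
       / ((1 - p_e(w)) sqrt(n))``

with ``wbar_i. = sum_j p_.j w_ij`` and ``wbar_.j = sum_i p_i. w_ij``, and a
Wald confidence interval ``k_w -/+ z_{a/2} SE``.  With identity weights all
of this reduces to ordinary (unweighted) Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .weights import CategoryScale, QUIS_SCALE, WeightMatrix

__all__ = [
    "CrossTab",
    "KappaEstimate",
    "tabulate_pairs",
    "observed_agreement",
    "expected_agreement",
    "weighted_kappa",
    "kappa_se",
    "wald_ci",
    "EmptyTableError",
    "DegenerateAgreementError",
    "UnknownLabelError",
]


class EmptyTableError(ValueError):
    """The cross-tabulation contains no rated interactions."""


class DegenerateAgreementError(ValueError):
    """Chance-expected weighted agreement is 1, so kappa is undefined."""


class UnknownLabelError(KeyError):
    """A rating label does not belong to the configured scale."""


@dataclass(frozen=True)
class CrossTab:
    """k-by-k contingency table of paired ratings.

    Rows index rater 1's category, columns rater 2's, in scale order.
    """

    scale: CategoryScale
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (self.scale.k, self.scale.k):
            raise ValueError(
                f"counts shape {counts.shape} does not match k={self.scale.k}"
            )
        if np.any(counts < 0):
            raise ValueError("negative cell counts")
        counts = counts.astype(np.int64).copy()
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        """Total number of jointly rated interactions."""
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        """Cell proportions p_ij (requires n >= 1)."""
        if self.n == 0:
            raise EmptyTableError("cross-tabulation is empty (n=0)")
        return self.counts / self.n

    @property
    def row_margins(self) -> np.ndarray:
        """Rater 1 marginal proportions p_i."""
        return self.proportions.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        """Rater 2 marginal proportions p_.j"""
        return self.proportions.sum(axis=0)

    def __add__(self, other: "CrossTab") -> "CrossTab":
        if self.scale != other.scale:
            raise ValueError("cannot add cross-tabs on different scales")
        return CrossTab(self.scale, self.counts + other.counts)


@dataclass(frozen=True)
class KappaEstimate:
    """Weighted-kappa point estimate with its SE and Wald interval.

    ``ci_low``/``ci_high`` are clipped to the parameter space [-1, 1] for
    reporting; the raw Wald limits are kept in ``ci_low_raw``/``ci_high_raw``.
    """

    kappa: float
    po_w: float
    pe_w: float
    se: float
    ci_low: float
    ci_high: float
    ci_low_raw: float
    ci_high_raw: float
    alpha: float
    n: int
    scheme: str | None = None

    def __str__(self) -> str:  # pragma: no cover - display convenience
        pct = 100 * (1 - self.alpha)
        return (
            f"kappa_w = {self.kappa:.2f} ({pct:g}% CI {self.ci_low:.2f} to "
            f"{self.ci_high:.2f}; SE {self.se:.3f}; n={self.n})"
        )


def tabulate_pairs(
    pairs: Iterable[tuple[str, str]],
    scale: CategoryScale = QUIS_SCALE,
) -> CrossTab:
    """Cross-tabulate (rater1, rater2) label pairs on ``scale``.

    Raises
    ------
    UnknownLabelError
        Naming the first offending pair if a label is not on the scale.
    """
    counts = np.zeros((scale.k, scale.k), dtype=np.int64)
    for row_no, (a, b) in enumerate(pairs, start=1):
        try:
            i, j = scale.index(a), scale.index(b)
        except KeyError as exc:
            raise UnknownLabelError(
                f"pair {row_no}: {exc.args[0]}"
            ) from None
        counts[i, j] += 1
    return CrossTab(scale, counts)


def _check_scales(tab: CrossTab, W: WeightMatrix) -> None:
    if tab.scale != W.scale:
        raise ValueError(
            f"weight matrix scale {W.scale.labels} does not match "
            f"table scale {tab.scale.labels}"
        )


def observed_agreement(tab: CrossTab, W: WeightMatrix) -> float:
    """Observed weighted agreement p_o(w) = sum_ij w_ij p_ij."""
    _check_scales(tab, W)
    return float(np.sum(W.w * tab.proportions))


def expected_agreement(tab: CrossTab, W: WeightMatrix) -> float:
    """Chance-expected weighted agreement p_e(w) = sum_ij w_ij p_i. p_.j."""
    _check_scales(tab, W)
    return float(tab.row_margins @ W.w @ tab.col_margins)


def kappa_se(tab: CrossTab, W: WeightMatrix) -> float:
    """Large-sample standard error of weighted kappa (Fleiss et al.)."""
    _check_scales(tab, W)
    p_row = tab.row_margins
    p_col = tab.col_margins
    pe = float(p_row @ W.w @ p_col)
    if pe >= 1.0:
        raise DegenerateAgreementError(
            "expected weighted agreement is 1; kappa and its SE are undefined"
        )
    wbar_row = W.w @ p_col          # wbar_i. = sum_j p_.j w_ij
    wbar_col = p_row @ W.w          # wbar_.j = sum_i p_i. w_ij
    dev = W.w - (wbar_row[:, None] + wbar_col[None, :])
    total = float(np.sum(np.outer(p_row, p_col) * dev**2) - pe**2)
    # Round-off can push the variance term a hair below zero when it is 0.
    total = max(total, 0.0)
    return float(np.sqrt(total) / ((1.0 - pe) * np.sqrt(tab.n)))


def wald_ci(kappa: float, se: float, alpha: float = 0.05) -> tuple[float, float]:
    """Two-sided Wald interval kappa -/+ z_{alpha/2} * se, unclipped."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if se < 0:
        raise ValueError("standard error must be non-negative")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return kappa - z * se, kappa + z * se


def weighted_kappa(
    tab: CrossTab,
    W: WeightMatrix,
    alpha: float = 0.05,
) -> KappaEstimate:
    """Weighted Cohen's kappa with SE and Wald CI for one cross-tabulation.

    Raises
    ------
    EmptyTableError
        If the table holds no interactions.
    DegenerateAgreementError
        If expected weighted agreement equals 1 (e.g. n=1), where the
        chance-corrected statistic is undefined.
    """
    po = observed_agreement(tab, W)
    pe = expected_agreement(tab, W)
    if pe >= 1.0 - 1e-15:
        raise DegenerateAgreementError(
            "expected weighted agreement is 1; kappa is undefined"
        )
    kappa = (po - pe) / (1.0 - pe)
    se = kappa_se(tab, W)
    low_raw, high_raw = wald_ci(kappa, se, alpha)
    return KappaEstimate(
        kappa=kappa,
        po_w=po,
        pe_w=pe,
        se=se,
        ci_low=max(low_raw, -1.0),
        ci_high=min(high_raw, 1.0),
        ci_low_raw=low_raw,
        ci_high_raw=high_raw,
        alpha=alpha,
        n=tab.n,
        scheme=W.name,
    )
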