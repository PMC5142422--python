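"""Simulated inter-rater studies with analytically known weighted kappa.

The generator realises the random-effects model behind the pooling methods:
the true agreement of period m is ``lambda_m = clip(kappa_mean + delta_m, 0, 1)``
with ``delta_m ~ N(0, tau^2)``, and the period's joint rating distribution is
the mixture

    P_m = lambda_m * diag(pi) + (1 - lambda_m) * pi pi^T,

a convex combination of perfect agreement (all probability on the diagonal,
margins pi) and rater independence (outer product of the margins).  Both
raters share the marginal profile ``pi``.  The family is chosen because its
population weighted kappa equals ``lambda_m`` exactly for EVERY unit-diagonal
weighting scheme: p_o(w) = lambda + (1 - lambda) p_e(w), so
(p_o - p_e)/(1 - p_e) = lambda.  That gives closed-form ground truth for
parameter-recovery tests without favouring any particular scheme.  True
kappa below zero is not generatable (lambda is clipped to [0, 1]).

Cell counts are drawn multinomially, so within-period sampling noise is
exactly the multinomial noise the large-sample kappa SE describes.  Each
period uses its own child of the master seed, so enlarging g leaves earlier
periods' data unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kappa import CrossTab
from .weights import CategoryScale, QUIS_SCALE, WeightMatrix

__all__ = ["SimConfig", "SimulatedStudy", "simulate_study", "true_kappa",
           "QUIS_MARGINS"]

#: Marginal category profile of the motivating QuIS study (rater 1 margins
#: of the collapsed table): mostly positive-care ratings, few negatives.
QUIS_MARGINS: tuple[float, ...] = (59 / 354, 201 / 354, 70 / 354,
                                   14 / 354, 10 / 354)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a simulated multi-period reliability study.

    Defaults mirror the motivating QuIS study: g=18 two-hour observation
    periods of about 20 jointly rated interactions each, the study's
    marginal category profile, mean agreement 0.6 and between-period
    standard deviation 0.1.
    """

    g: int = 18
    n_m: int | Sequence[int] = 20
    pi: Sequence[float] = QUIS_MARGINS
    kappa_mean: float = 0.6
    tau: float = 0.1
    seed: int = 0
    scale: CategoryScale = QUIS_SCALE

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (self.scale.k,):
            raise ValueError(
                f"pi must have length k={self.scale.k}, got {pi.shape}"
            )
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must be non-negative and sum to 1")
        if not 0.0 <= self.kappa_mean <= 1.0:
            raise ValueError("kappa_mean must lie in [0, 1]")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.g < 1:
            raise ValueError("need at least one observation period")
        object.__setattr__(self, "pi", tuple(float(x) for x in pi))

    def period_sizes(self) -> np.ndarray:
        if np.isscalar(self.n_m):
            return np.full(self.g, int(self.n_m))
        sizes = np.asarray(self.n_m, dtype=int)
        if sizes.shape != (self.g,):
            raise ValueError(
                f"n_m list must have length g={self.g}, got {sizes.shape}"
            )
        return sizes


@dataclass
class SimulatedStudy:
    """Output of :func:`simulate_study`, with ground truth attached."""

    config: SimConfig
    pairs_by_period: dict[str, list[tuple[str, str]]]
    lambdas: np.ndarray          # per-period true agreement lambda_m
    joints: list[np.ndarray]     # per-period true joint matrices P_m
    counts: list[np.ndarray]     # per-period sampled cell counts

    def tables(self) -> dict[str, CrossTab]:
        return {
            pid: CrossTab(self.config.scale, c)
            for pid, c in zip(self.pairs_by_period, self.counts)
        }


def _mixture_joint(lam: float, pi: np.ndarray) -> np.ndarray:
    return lam * np.diag(pi) + (1.0 - lam) * np.outer(pi, pi)


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Draw a full study: period effects, joint matrices, multinomial counts.

    Identical configurations (including seed) reproduce identical studies
    bit-for-bit.
    """
    pi = np.asarray(config.pi)
    k = config.scale.k
    sizes = config.period_sizes()
    children = np.random.SeedSequence(config.seed).spawn(config.g)

    pairs_by_period: dict[str, list[tuple[str, str]]] = {}
    lambdas = np.empty(config.g)
    joints: list[np.ndarray] = []
    counts: list[np.ndarray] = []
    width = max(2, len(str(config.g)))
    for m in range(config.g):
        rng = np.random.default_rng(children[m])
        delta = rng.normal(0.0, config.tau) if config.tau > 0 else 0.0
        lam = float(np.clip(config.kappa_mean + delta, 0.0, 1.0))
        P = _mixture_joint(lam, pi)
        cell_counts = rng.multinomial(sizes[m], P.ravel()).reshape(k, k)
        pairs: list[tuple[str, str]] = []
        for i in range(k):
            for j in range(k):
                pairs.extend(
                    [(config.scale.labels[i], config.scale.labels[j])]
                    * int(cell_counts[i, j])
                )
        pid = f"period{m + 1:0{width}d}"
        pairs_by_period[pid] = pairs
        lambdas[m] = lam
        joints.append(P)
        counts.append(cell_counts)
    return SimulatedStudy(config, pairs_by_period, lambdas, joints, counts)


def true_kappa(P: np.ndarray, W: WeightMatrix) -> float:
    """Population weighted kappa of a joint rating distribution.

    Applies the weighted-kappa definition to the cells and margins of a
    probability matrix rather than sampled counts.
    """
    P = np.asarray(P, dtype=float)
    if P.shape != (W.k, W.k):
        raise ValueError(f"P shape {P.shape} does not match k={W.k}")
    if np.any(P < 0) or abs(P.sum() - 1.0) > 1e-9:
        raise ValueError("P must be a probability matrix summing to 1")
    p_row = P.sum(axis=1)
    p_col = P.sum(axis=0)
    po = float(np.sum(W.w * P))
    pe = float(p_row @ W.w @ p_col)
    if pe >= 1.0 - 1e-15:
        raise ValueError("expected weighted agreement is 1; kappa undefined")
    return (po - pe) / (1.0 - pe)
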