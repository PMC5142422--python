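"""Agreement-weight matrices for ordinal rating scales.

Weighted kappa credits partial agreement between raters through a symmetric
matrix of weights ``w_ij`` on category pairs, with ``w_ii = 1`` (identical
ratings are full agreement) and ``0 <= w_ij <= 1`` (``w_ij = 0`` marks a pair
of ratings treated as complete disagreement).  This module builds the three
formula-based schemes (identity/unweighted, linear, quadratic) for any number
of categories, and the named QuIS-specific schemes A1–A6, B1–B3 and C1–C3
defined for the five-category Quality of Interactions Schedule
(+s > +c > N > -p > -r, from positive social down to negative restrictive).

The lettered schemes share a block structure determined by three parameters:

* ``a`` — weight for disagreement within the two positive categories,
* ``b`` — weight between neutral and any positive or negative category,
* ``c`` — weight for disagreement within the two negative categories,

with every positive-vs-negative pair weighted 0 (absolute disagreement).
A-schemes and B-schemes set ``a == c``; C-schemes deem within-negative
disagreement less severe than within-positive (``c > a``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CategoryScale",
    "WeightMatrix",
    "QUIS_SCALE",
    "SCHEME_NAMES",
    "identity_weights",
    "linear_weights",
    "quadratic_weights",
    "named_scheme",
    "validate_weights",
    "UnknownSchemeError",
]


class UnknownSchemeError(ValueError):
    """Requested weighting scheme name is not recognised."""


@dataclass(frozen=True)
class CategoryScale:
    """An ordered set of rating categories, highest-ranked first.

    The default is the five-category QuIS scale.  Ordinal positions
    (1-based in formulas, 0-based as array indices) follow the label order.
    """

    labels: tuple[str, ...] = ("+s", "+c", "N", "-p", "-r")

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise ValueError("a scale needs at least two categories")
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate category labels: {labels!r}")

    @property
    def k(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown category label {label!r}; scale is {list(self.labels)}"
            ) from None

    def reversed(self) -> "CategoryScale":
        return CategoryScale(tuple(reversed(self.labels)))


#: The QuIS scale: positive social, positive care, neutral, negative
#: protective, negative restrictive.
QUIS_SCALE = CategoryScale()


@dataclass(frozen=True)
class WeightMatrix:
    """A k-by-k agreement-weight matrix bound to a category scale."""

    scale: CategoryScale
    w: np.ndarray
    name: str | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float).copy()
        if w.shape != (self.scale.k, self.scale.k):
            raise ValueError(
                f"weight matrix shape {w.shape} does not match k={self.scale.k}"
            )
        w.setflags(write=False)
        object.__setattr__(self, "w", w)

    @property
    def k(self) -> int:
        return self.scale.k

    def permuted(self, order: list[int] | np.ndarray,
                 name: str | None = None) -> "WeightMatrix":
        """Weight matrix for the scale with categories re-ordered by ``order``."""
        order = np.asarray(order)
        new_scale = CategoryScale(tuple(self.scale.labels[i] for i in order))
        return WeightMatrix(new_scale, self.w[np.ix_(order, order)], name=name)


def identity_weights(scale: CategoryScale = QUIS_SCALE) -> WeightMatrix:
    """Unweighted kappa's weight matrix: 1 on the diagonal, 0 elsewhere.

    Ignores the degree of misclassification between categories: any pair of
    non-identical ratings counts as full disagreement.
    """
    return WeightMatrix(scale, np.eye(scale.k), name="unweighted")


def _offsets(k: int) -> np.ndarray:
    idx = np.arange(k)
    return np.abs(idx[:, None] - idx[None, :])


def linear_weights(scale: CategoryScale = QUIS_SCALE) -> WeightMatrix:
    """Linear weights ``w_ij = 1 - |i - j| / (k - 1)``.

    Disagreement one category apart is equally severe everywhere on the
    scale, and severity grows proportionally with distance.
    """
    k = scale.k
    return WeightMatrix(scale, 1.0 - _offsets(k) / (k - 1), name="linear")


def quadratic_weights(scale: CategoryScale = QUIS_SCALE) -> WeightMatrix:
    """Quadratic weights ``w_ij = 1 - ((i - j) / (k - 1))**2``.

    Penalises distant disagreements more than proportionally; adjacent
    disagreements retain most of the credit.
    """
    k = scale.k
    return WeightMatrix(scale, 1.0 - (_offsets(k) / (k - 1)) ** 2, name="quadratic")


# (a, b, c) = (within-positive, neutral-adjacent, within-negative) weights.
_BLOCK_PARAMS: dict[str, tuple[float, float, float]] = {
    "A1": (1.0, 0.5, 1.0),
    "A2": (0.9, 0.5, 0.9),
    "A3": (0.8, 0.5, 0.8),
    "A4": (0.75, 0.5, 0.75),
    "A5": (0.7, 0.5, 0.7),
    "A6": (0.6, 0.5, 0.6),
    "B1": (0.66, 0.33, 0.66),
    "B2": (0.5, 0.25, 0.5),
    "B3": (0.5, 0.0, 0.5),
    "C1": (0.5, 0.25, 0.75),
    "C2": (0.6, 0.4, 0.8),
    "C3": (0.66, 0.5, 0.83),
}

_FORMULA_SCHEMES = {
    "unweighted": identity_weights,
    "linear": linear_weights,
    "quadratic": quadratic_weights,
}

#: All scheme names accepted by :func:`named_scheme`, in report order.
SCHEME_NAMES: tuple[str, ...] = (
    "unweighted", "linear", "quadratic",
    "A1", "A2", "A3", "A4", "A5", "A6",
    "B1", "B2", "B3", "C1", "C2", "C3",
)


def _block_matrix(a: float, b: float, c: float) -> np.ndarray:
    # Rows/cols ordered +s, +c, N, -p, -r.  Positive-vs-negative cells stay 0.
    w = np.eye(5)
    w[0, 1] = a          # within positives
    w[0, 2] = w[1, 2] = b  # positives vs neutral
    w[2, 3] = w[2, 4] = b  # neutral vs negatives
    w[3, 4] = c          # within negatives
    return np.maximum(w, w.T)


def named_scheme(name: str, scale: CategoryScale = QUIS_SCALE) -> WeightMatrix:
    """Return a weighting scheme by name.

    ``unweighted``, ``linear`` and ``quadratic`` work for any scale; the
    lettered QuIS schemes (A1–A6, B1–B3, C1–C3) require a five-category
    scale ordered positive-to-negative.

    Raises
    ------
    UnknownSchemeError
        If ``name`` is not a recognised scheme.
    """
    lowered = name.lower()
    if lowered in _FORMULA_SCHEMES:
        return _FORMULA_SCHEMES[lowered](scale)
    upper = name.upper()
    if upper in _BLOCK_PARAMS:
        if scale.k != 5:
            raise ValueError(
                f"scheme {upper!r} is defined for the 5-category QuIS scale, "
                f"got k={scale.k}"
            )
        return WeightMatrix(scale, _block_matrix(*_BLOCK_PARAMS[upper]), name=upper)
    raise UnknownSchemeError(
        f"unknown weighting scheme {name!r}; choose one of {', '.join(SCHEME_NAMES)}"
    )


def validate_weights(W: WeightMatrix, atol: float = 0.0) -> list[str]:
    """Check symmetry, unit diagonal and [0, 1] range; return violations.

    An empty list means the matrix is a valid agreement-weight matrix.
    """
    w = np.asarray(W.w, dtype=float)
    labels = W.scale.labels
    violations: list[str] = []
    if w.shape != (len(labels), len(labels)):
        return [f"shape {w.shape} does not match k={len(labels)}"]
    for i in range(len(labels)):
        if abs(w[i, i] - 1.0) > atol:
            violations.append(
                f"diagonal w[{labels[i]},{labels[i]}] = {w[i, i]:g} != 1"
            )
        for j in range(i + 1, len(labels)):
            if abs(w[i, j] - w[j, i]) > atol:
                violations.append(
                    f"asymmetry: w[{labels[i]},{labels[j]}] = {w[i, j]:g} but "
                    f"w[{labels[j]},{labels[i]}] = {w[j, i]:g}"
                )
    bad = np.argwhere((w < -atol) | (w > 1 + atol))
    for i, j in bad:
        violations.append(
            f"range: w[{labels[i]},{labels[j]}] = {w[i, j]:g} outside [0, 1]"
        )
    return violations
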