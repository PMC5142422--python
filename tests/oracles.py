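"""Independent brute-force references for the statistics under test.

Pure-Python double/triple-loop implementations of observed and expected
weighted agreement, weighted kappa and its large-sample standard error,
written directly from the defining sums.  Deliberately naive and kept free
of any code from the package so they can serve as an independent oracle.
"""

from __future__ import annotations

import math


def _proportions(counts):
    k = len(counts)
    n = sum(counts[i][j] for i in range(k) for j in range(k))
    p = [[counts[i][j] / n for j in range(k)] for i in range(k)]
    row = [sum(p[i][j] for j in range(k)) for i in range(k)]
    col = [sum(p[i][j] for i in range(k)) for j in range(k)]
    return p, row, col, n


def naive_po(counts, w) -> float:
    p, _, _, _ = _proportions(counts)
    k = len(counts)
    return sum(w[i][j] * p[i][j] for i in range(k) for j in range(k))


def naive_pe(counts, w) -> float:
    _, row, col, _ = _proportions(counts)
    k = len(counts)
    return sum(w[i][j] * row[i] * col[j] for i in range(k) for j in range(k))


def naive_kappa(counts, w) -> float:
    po, pe = naive_po(counts, w), naive_pe(counts, w)
    return (po - pe) / (1.0 - pe)


def naive_se(counts, w) -> float:
    """Direct summation of the large-sample SE formula for weighted kappa."""
    _, row, col, n = _proportions(counts)
    k = len(counts)
    pe = naive_pe(counts, w)
    wbar_row = [sum(col[j] * w[i][j] for j in range(k)) for i in range(k)]
    wbar_col = [sum(row[i] * w[i][j] for i in range(k)) for j in range(k)]
    total = 0.0
    for i in range(k):
        for j in range(k):
            total += row[i] * col[j] * (w[i][j] - (wbar_row[i] + wbar_col[j])) ** 2
    total -= pe**2
    return math.sqrt(max(total, 0.0)) / ((1.0 - pe) * math.sqrt(n))
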