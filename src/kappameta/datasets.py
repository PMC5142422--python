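"""Cross-tabulations from the motivating QuIS inter-rater reliability study.

In that study 18 pairs of trained observers each rated, over a two-hour
observation period on acute hospital wards, every staff-inpatient
interaction involving two selected patients; 354 interactions were rated by
both members of a pair and enter the reliability analysis.  Three published
cross-tabulations are reproduced here: the table collapsed over all 18
periods, and the single periods with the lowest and the highest unweighted
kappa.  Rows are rater 1's QuIS category, columns rater 2's, in the order
+s, +c, N, -p, -r.
"""

from __future__ import annotations

import numpy as np

from .kappa import CrossTab
from .weights import QUIS_SCALE

__all__ = [
    "quis_collapsed_counts",
    "quis_lowest_period_counts",
    "quis_highest_period_counts",
    "quis_collapsed_table",
    "quis_lowest_period_table",
    "quis_highest_period_table",
]

# Collapsed over all 18 observation periods; n = 354.
_COLLAPSED = np.array(
    [
        [36, 23, 0, 0, 0],
        [22, 164, 10, 4, 1],
        [3, 13, 47, 2, 5],
        [0, 5, 2, 7, 0],
        [3, 1, 0, 0, 6],
    ],
    dtype=np.int64,
)

# Observation period with the lowest unweighted kappa; n = 25.
_LOWEST = np.array(
    [
        [2, 4, 0, 0, 0],
        [1, 9, 2, 0, 1],
        [0, 2, 2, 1, 0],
        [0, 0, 0, 0, 0],
        [0, 0, 0, 0, 1],
    ],
    dtype=np.int64,
)

# Observation period with the highest unweighted kappa; n = 19.
_HIGHEST = np.array(
    [
        [1, 0, 0, 0, 0],
        [0, 11, 0, 0, 0],
        [0, 0, 6, 0, 0],
        [0, 0, 1, 0, 0],
        [0, 0, 0, 0, 0],
    ],
    dtype=np.int64,
)


def quis_collapsed_counts() -> np.ndarray:
    """Counts collapsed over all 18 observation periods (n=354)."""
    return _COLLAPSED.copy()


def quis_lowest_period_counts() -> np.ndarray:
    """Counts for the period with the lowest unweighted kappa (n=25)."""
    return _LOWEST.copy()


def quis_highest_period_counts() -> np.ndarray:
    """Counts for the period with the highest unweighted kappa (n=19)."""
    return _HIGHEST.copy()


def quis_collapsed_table() -> CrossTab:
    return CrossTab(QUIS_SCALE, _COLLAPSED)


def quis_lowest_period_table() -> CrossTab:
    return CrossTab(QUIS_SCALE, _LOWEST)


def quis_highest_period_table() -> CrossTab:
    return CrossTab(QUIS_SCALE, _HIGHEST)
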