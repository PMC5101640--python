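"""Reference datasets.

The package ships the one published summary dataset that suffices to
recompute an agreement result end-to-end: the 4x4 cross-tabulation of
estimated age categories for two bruises (a and b) sampled from each of 81
Danish slaughter pigs with multiple human-inflicted bruises.  Rows index
bruise b's category, columns bruise a's, in the fixed display order
inconclusive, <4 h, >4 h, overlapping 4 h.
"""

from __future__ import annotations

import numpy as np

from .age_estimation import CATEGORY_ORDER
from .agreement import ContingencyTable

__all__ = ["load_age_crosstab"]

# rows: bruise b (inconclusive, <4 h, >4 h, overlapping 4 h); columns: bruise a
_AGE_CROSSTAB_COUNTS = np.array(
    [
        [1, 3, 0, 3],
        [1, 20, 3, 12],
        [0, 3, 6, 4],
        [3, 4, 6, 12],
    ],
    dtype=np.int64,
)


def load_age_crosstab() -> ContingencyTable:
    """The 81-pig bruise-age agreement table (rows b, columns a)."""
    return ContingencyTable(categories=CATEGORY_ORDER, counts=_AGE_CROSSTAB_COUNTS.copy())
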