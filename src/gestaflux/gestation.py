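"""Gestational-age conventions shared across the package.

All gestational ages are carried in *days*; the obstetric ``w+d`` notation
maps to ``7*w + d`` days (so week 14+0 is day 98).  Trimester strata:

* first trimester: GA < 14+0 (day 98)
* second trimester: 14+0 to 27+6 (days 98-195)
* third trimester: 28+0 to 40+3 (days 196-283)
* late term: beyond 40+3 (day > 283)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

T2_START_DAY = 98  # week 14+0
T3_START_DAY = 196  # week 28+0
LATE_TERM_AFTER_DAY = 283  # week 40+3; late term is GA > this
TERM_DELIVERY_MIN_DAY = 259  # week 37+0
DELIVERY_MAX_DAY = 302  # week 43+1

TRIMESTER_LEVELS = ["T1", "T2", "T3", "late_term"]


def ga_days(weeks: int, days: int = 0) -> int:
    """Convert obstetric w+d notation to days (14+0 -> 98)."""
    if days < 0 or days > 6:
        raise ValueError("day part of w+d must be in 0..6")
    return 7 * weeks + days


def trimester(ga: float | np.ndarray | pd.Series):
    """Map gestational age in days to {'T1','T2','T3','late_term'}."""
    ga_arr = np.asarray(ga, dtype=float)
    out = np.select(
        [
            ga_arr < T2_START_DAY,
            ga_arr <= T3_START_DAY - 1,
            ga_arr <= LATE_TERM_AFTER_DAY,
        ],
        ["T1", "T2", "T3"],
        default="late_term",
    )
    if np.isscalar(ga) or np.ndim(ga) == 0:
        return str(out.item() if hasattr(out, "item") else out)
    if isinstance(ga, pd.Series):
        return pd.Series(out, index=ga.index, name="trimester")
    return out
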