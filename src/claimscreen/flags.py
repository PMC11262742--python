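"""Shared flag-table conventions for the four screening methods.

Every detector emits a DataFrame indexed by ``centre_id`` with columns

    method    one of METHODS
    eligible  bool — whether the centre met the method's prerequisites
    score     float — the method statistic (NaN when ineligible)
    flagged   bool — implies eligible

Top-fraction flagging uses exact rational arithmetic for the cutoff count
(``ceil(fraction × n_eligible)``) so that decimal fractions like 0.10 behave
as written, and breaks score ties by centre id for determinism.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd

HIGH_VOLUME = "high_volume"
LOW_POSITIVITY = "low_positivity"
BENFORD = "benford"
LAST_DIGIT = "last_digit"
METHODS = (HIGH_VOLUME, LOW_POSITIVITY, BENFORD, LAST_DIGIT)


def n_to_flag(fraction, n_eligible: int) -> int:
    """ceil(fraction × n) with the fraction taken at its decimal face value."""
    if n_eligible <= 0:
        return 0
    frac = Fraction(str(fraction)) if not isinstance(fraction, Fraction) else fraction
    if not 0 < frac < 1:
        raise ValueError(f"flag fraction must be in (0, 1), got {fraction}")
    return int(math.ceil(frac * n_eligible))


def top_fraction_mask(scores: pd.Series, fraction) -> pd.Series:
    """Boolean mask of the ceil(fraction × n) highest scores.

    ``scores`` is indexed by centre_id; NaN scores are never selected.
    Ties broken by (score desc, centre_id asc).
    """
    valid = scores.dropna()
    m = n_to_flag(fraction, len(valid))
    # stable sort over an id-ordered frame: equal scores fall back to id order
    order = valid.loc[sorted(valid.index)].sort_values(ascending=False, kind="mergesort")
    chosen = set(order.index[:m])
    return pd.Series([i in chosen for i in scores.index], index=scores.index, dtype=bool)


def make_flag_table(index: pd.Index, method: str, eligible, score, flagged) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "method": method,
            "eligible": np.asarray(eligible, dtype=bool),
            "score": np.asarray(score, dtype=float),
            "flagged": np.asarray(flagged, dtype=bool),
        },
        index=index,
    )
    out.index.name = "centre_id"
    if (out["flagged"] & ~out["eligible"]).any():
        raise ValueError("internal error: flagged centre marked ineligible")
    return out
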