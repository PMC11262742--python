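"""High-volume outlier screen.

A centre is conspicuous when its mean number of invoiced tests per active day
is unusually high compared to the other centres of the same category. The
cutoff is the 90th percentile within category, operationalised as flagging
the top ``ceil((1 − quantile_level) × n_eligible)`` centres per category —
the count rule that reproduces per-category cohort sizes exactly under ties.
"""

from __future__ import annotations

import dataclasses
import logging
from fractions import Fraction

import numpy as np
import pandas as pd

from . import flags as fl

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class VolumeFlagConfig:
    quantile_level: float = 0.90
    stratify_by_category: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.quantile_level < 1:
            raise ValueError("quantile_level must be in (0, 1)")


def flag_high_volume(summaries: pd.DataFrame, config: VolumeFlagConfig | None = None) -> pd.DataFrame:
    """Flag the top share of centres by mean daily tests within each category.

    Centres with zero active days are ineligible (no mean volume exists).
    Score = mean daily tests over active days.
    """
    config = config or VolumeFlagConfig()
    frac = Fraction(1) - Fraction(str(config.quantile_level))

    score = summaries["mean_daily_tests"].astype(float)
    eligible = summaries["n_active_days"] >= 1
    flagged = pd.Series(False, index=summaries.index)

    groups = summaries.groupby("category").groups if config.stratify_by_category else {"all": summaries.index}
    for cat, idx in groups.items():
        cat_scores = score.loc[idx].where(eligible.loc[idx])
        if cat_scores.notna().sum() == 0:
            log.warning("volume screen: category %r has no eligible centres", cat)
            continue
        flagged.loc[idx] = fl.top_fraction_mask(cat_scores, frac)

    return fl.make_flag_table(summaries.index, fl.HIGH_VOLUME, eligible, score.where(eligible), flagged)
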