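"""Digit-forensics screens: Benford first digit and uniform last digit.

Benford's law gives the expected leading-digit distribution of naturally
occurring numeric collections, p_d = log10(1 + 1/d) for d = 1..9 — about 30%
for a leading 1 down to about 5% for a leading 9. True daily test counts
should also have an approximately uniform final digit; an excess of 0s and 5s
points to rounded, hence fabricated, figures.

Both screens compute a per-centre chi-squared statistic of the observed digit
counts against the reference distribution and flag the top decile of eligible
centres. Centres with fewer than 30 active days are ineligible: their digit
distribution is not interpretable.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import flags as fl
from .claims import LAST_COLUMNS, LEAD_COLUMNS

log = logging.getLogger(__name__)

BENFORD_FIRST = "benford_first"
UNIFORM_LAST = "uniform_last"

#: Benford leading-digit probabilities, d = 1..9.
BENFORD_P = np.log10(1.0 + 1.0 / np.arange(1, 10))

#: Uniform last-digit probabilities, d = 0..9.
UNIFORM_LAST_P = np.full(10, 0.1)


def benford_probability(d: int) -> float:
    """P(leading digit = d) under Benford's law, log10(1 + 1/d)."""
    if not 1 <= int(d) <= 9 or int(d) != d:
        raise ValueError(f"leading digit must be an integer in 1..9, got {d!r}")
    return float(np.log10(1.0 + 1.0 / int(d)))


def digit_chi2(counts, expected) -> float:
    """Pearson chi-squared of observed digit counts against expected shares.

    Used as a ranking score, not a calibrated p-value: no small-count
    correction is applied.
    """
    obs = np.asarray(counts, dtype=float)
    p = np.asarray(expected, dtype=float)
    if obs.shape != p.shape:
        raise ValueError(f"counts ({obs.shape}) and expected ({p.shape}) differ in length")
    if (p <= 0).any():
        raise ValueError("expected probabilities must all be positive")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("expected probabilities must sum to 1")
    n = obs.sum()
    if n < 1:
        raise ValueError("need at least one digit observation")
    e = n * p
    return float(((obs - e) ** 2 / e).sum())


@dataclasses.dataclass(frozen=True)
class DigitScreenConfig:
    screen: str = BENFORD_FIRST
    min_active_days: int = 30
    flag_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.screen not in (BENFORD_FIRST, UNIFORM_LAST):
            raise ValueError(f"unknown digit screen {self.screen!r}")
        if self.min_active_days < 1:
            raise ValueError("min_active_days must be >= 1")
        if not 0 < self.flag_fraction < 1:
            raise ValueError("flag_fraction must be in (0, 1)")


def flag_digit_screen(summaries: pd.DataFrame, config: DigitScreenConfig) -> pd.DataFrame:
    """Chi-squared digit screen over per-centre summaries.

    Eligibility: at least ``min_active_days`` days with invoiced tests.
    Ineligible centres stay in the table unflagged. Among eligible centres
    the top ``ceil(flag_fraction × n_eligible)`` by chi-squared are flagged;
    score = the chi-squared statistic.
    """
    if config.screen == BENFORD_FIRST:
        cols, p, method = LEAD_COLUMNS, BENFORD_P, fl.BENFORD
    else:
        cols, p, method = LAST_COLUMNS, UNIFORM_LAST_P, fl.LAST_DIGIT

    eligible = summaries["n_active_days"] >= config.min_active_days
    counts = summaries[cols].to_numpy(dtype=float)
    score = np.full(len(summaries), np.nan)
    for i in np.flatnonzero(eligible.to_numpy()):
        score[i] = digit_chi2(counts[i], p)
    score = pd.Series(score, index=summaries.index)

    if eligible.sum() == 0:
        log.warning("digit screen %s: no eligible centres", config.screen)
        flagged = pd.Series(False, index=summaries.index)
    else:
        flagged = fl.top_fraction_mask(score, config.flag_fraction)

    return fl.make_flag_table(summaries.index, method, eligible, score, flagged)


def low_variance_centres(records: pd.DataFrame, min_distinct: int = 5) -> pd.Series:
    """Diagnostic: centres whose daily test counts take few distinct values.

    Digit screens presuppose sufficiently variable underlying data; a centre
    reporting near-identical numbers every day violates that. Returns the
    number of distinct daily values per offending centre (a warning aid, not
    an automatic exclusion).
    """
    active = records[records["n_tests"] >= 1]
    distinct = active.groupby("centre_id")["n_tests"].nunique()
    return distinct[distinct < min_distinct]


def plot_benford(summary_row: pd.Series, ax=None):
    """Bar plot of a centre's observed leading-digit shares against Benford."""
    import matplotlib.pyplot as plt

    counts = summary_row[LEAD_COLUMNS].to_numpy(dtype=float)
    obs = counts / counts.sum()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    d = np.arange(1, 10)
    ax.bar(d - 0.2, BENFORD_P, width=0.4, label="expected (Benford)")
    ax.bar(d + 0.2, obs, width=0.4, label="observed")
    ax.set_xticks(d)
    ax.set_xlabel("leading digit of daily tests")
    ax.set_ylabel("share of active days")
    ax.legend(frameon=False)
    return ax
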