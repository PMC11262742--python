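"""Flag combination and agreement/validity metrics.

The statistical screens are compared against two external labels:

* ``suspected_conventional`` — whether the health authority's traditional
  process (complaints, inspections, investigations) already suspected the
  centre;
* ``corroborated`` — whether a subsequent thorough investigation confirmed
  the fraud suspicion (NA = never investigated).

Three agreement metrics parallel test-accuracy language: *positive overlap*
a/(a+b) (sensitivity analogue), *negative overlap* d/(c+d) (specificity
analogue) and the *incremental share* c/(c+d) = 100 − negative overlap, the
proportion of unsuspected centres that the statistical screen newly raises.
*Incremental predictive validity* is, among all statistically conspicuous
centres, the share that were not previously suspected and whose fraud
suspicion was later corroborated.

Percentages are carried as exact rationals and rounded half-up to one
decimal for reporting.
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from . import flags as fl

ANY = "any"
AT_LEAST_K = "at_least_k"


def pct_half_up(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Exact percentage numerator/denominator × 100, rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    frac = Fraction(int(numerator) * 100, int(denominator))
    q = Decimal(frac.numerator) / Decimal(frac.denominator)
    return float(q.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


@dataclasses.dataclass(frozen=True)
class AgreementTable:
    """2×2 counts crossing conventional suspicion with statistical conspicuousness.

    a: suspected & conspicuous, b: suspected & not, c: not suspected &
    conspicuous, d: not suspected & not. ``n_excluded`` counts centres left
    out for missing suspicion labels (under the ``exclude`` policy).
    """

    a: int
    b: int
    c: int
    d: int
    n_excluded: int = 0

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d, self.n_excluded) < 0:
            raise ValueError("agreement counts must be non-negative")

    @property
    def n_suspected(self) -> int:
        return self.a + self.b

    @property
    def n_not_suspected(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclasses.dataclass(frozen=True)
class OverlapMetrics:
    """Sensitivity/specificity-style agreement percentages (one decimal)."""

    positive_overlap_pct: float
    negative_overlap_pct: float
    incremental_share_pct: float

    @classmethod
    def from_table(cls, table: AgreementTable) -> "OverlapMetrics":
        return overlap_metrics(table)


@dataclasses.dataclass(frozen=True)
class ValidityBreakdown:
    """Partition of the conspicuous centres by prior suspicion and corroboration."""

    n_already_suspected: int
    n_new_corroborated: int
    n_new_not_corroborated: int

    @property
    def n_total_conspicuous(self) -> int:
        return self.n_already_suspected + self.n_new_corroborated + self.n_new_not_corroborated

    @property
    def incremental_predictive_validity_pct(self) -> float | None:
        """Share of newly corroborated centres among all conspicuous; None if none conspicuous."""
        if self.n_total_conspicuous == 0:
            return None
        return pct_half_up(self.n_new_corroborated, self.n_total_conspicuous)


def combine_flags(
    flag_tables: Sequence[pd.DataFrame], rule: str = ANY, k: int = 1, method_name: str | None = None
) -> pd.DataFrame:
    """Combine per-method flag tables with an OR (``any``) or at-least-k rule.

    A centre is eligible for the combination when it is eligible under at
    least one method; its score is the number of methods flagging it.
    """
    if not flag_tables:
        raise ValueError("need at least one flag table")
    idx = flag_tables[0].index
    for t in flag_tables[1:]:
        if not idx.sort_values().equals(t.index.sort_values()):
            raise ValueError("flag tables cover different centre sets")
    if rule == ANY:
        k = 1
    elif rule == AT_LEAST_K:
        if not 1 <= k <= len(flag_tables):
            raise ValueError(f"k must be in 1..{len(flag_tables)}, got {k}")
    else:
        raise ValueError(f"unknown combination rule {rule!r}")

    idx = idx.sort_values()
    n_flagging = sum(t["flagged"].reindex(idx).astype(int) for t in flag_tables)
    eligible = np.logical_or.reduce([t["eligible"].reindex(idx).to_numpy() for t in flag_tables])
    name = method_name or (ANY if rule == ANY else f"at_least_{k}")
    return fl.make_flag_table(idx, name, eligible, n_flagging.astype(float), n_flagging >= k)


def _aligned_labels(flags: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    lab = labels.set_index("centre_id") if "centre_id" in labels.columns else labels
    common = flags.index.intersection(lab.index)
    if len(common) == 0:
        raise ValueError("no centres in common between flags and labels")
    out = lab.loc[common].copy()
    out["flagged"] = flags.loc[common, "flagged"]
    return out


def cross_tabulate(
    flags: pd.DataFrame,
    labels: pd.DataFrame,
    missing_label_policy: str = "treat_as_unsuspected",
) -> AgreementTable:
    """Cross statistical flags with conventional suspicion into a 2×2 table.

    ``missing_label_policy`` decides what to do with centres whose suspicion
    label is NA (e.g. pharmacies, supervised by a different authority):
    ``treat_as_unsuspected`` (default; reproduces published tabulations that
    carry such centres in the not-suspected margin) or ``exclude`` (drop
    them, reporting the count in ``n_excluded``).
    """
    if missing_label_policy not in ("treat_as_unsuspected", "exclude"):
        raise ValueError(f"unknown missing_label_policy {missing_label_policy!r}")
    merged = _aligned_labels(flags, labels)
    susp = merged["suspected_conventional"]
    n_missing = int(susp.isna().sum())
    if missing_label_policy == "exclude":
        merged = merged[susp.notna()]
        susp = merged["suspected_conventional"]
    else:
        susp = susp.fillna(0)
    s = susp.astype(int).to_numpy()
    f = merged["flagged"].to_numpy()
    return AgreementTable(
        a=int(((s == 1) & f).sum()),
        b=int(((s == 1) & ~f).sum()),
        c=int(((s == 0) & f).sum()),
        d=int(((s == 0) & ~f).sum()),
        n_excluded=n_missing if missing_label_policy == "exclude" else 0,
    )


def overlap_metrics(table: AgreementTable) -> OverlapMetrics:
    """Positive/negative overlap and incremental share, one decimal each."""
    if table.n_suspected == 0:
        raise ValueError("undefined metric: no suspected centres (a+b = 0)")
    if table.n_not_suspected == 0:
        raise ValueError("undefined metric: no unsuspected centres (c+d = 0)")
    return OverlapMetrics(
        positive_overlap_pct=pct_half_up(table.a, table.n_suspected),
        negative_overlap_pct=pct_half_up(table.d, table.n_not_suspected),
        incremental_share_pct=pct_half_up(table.c, table.n_not_suspected),
    )


def predictive_validity(flags: pd.DataFrame, labels: pd.DataFrame) -> ValidityBreakdown:
    """Partition flagged centres by prior suspicion and corroboration outcome.

    Requires a corroboration status for every flagged centre that was not
    previously suspected; missing ones raise an error listing the centres.
    """
    merged = _aligned_labels(flags, labels)
    flagged = merged[merged["flagged"]]
    already = flagged["suspected_conventional"].fillna(0).astype(int) == 1
    new = flagged[~already]
    missing = new.index[new["corroborated"].isna()]
    if len(missing):
        raise ValueError(
            "corroboration status missing for flagged, not-previously-suspected centres: "
            + ", ".join(map(str, missing[:10]))
        )
    corro = new["corroborated"].astype(int) == 1
    return ValidityBreakdown(
        n_already_suspected=int(already.sum()),
        n_new_corroborated=int(corro.sum()),
        n_new_not_corroborated=int((~corro).sum()),
    )


def agreement_report(table: AgreementTable) -> dict:
    m = overlap_metrics(table)
    return {
        "a_suspected_conspicuous": table.a,
        "b_suspected_not_conspicuous": table.b,
        "c_unsuspected_conspicuous": table.c,
        "d_unsuspected_not_conspicuous": table.d,
        "n_excluded_missing_label": table.n_excluded,
        "positive_overlap_pct": m.positive_overlap_pct,
        "negative_overlap_pct": m.negative_overlap_pct,
        "incremental_share_pct": m.incremental_share_pct,
    }


def validity_report(v: ValidityBreakdown) -> dict:
    return {
        "n_already_suspected": v.n_already_suspected,
        "n_new_corroborated": v.n_new_corroborated,
        "n_new_not_corroborated": v.n_new_not_corroborated,
        "n_total_conspicuous": v.n_total_conspicuous,
        "incremental_predictive_validity_pct": v.incremental_predictive_validity_pct,
    }
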