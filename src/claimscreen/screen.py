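"""End-to-end screening model: four detectors, combination rules, evaluation.

``FraudScreen`` is the top-level modelling object: built from a claims table
(plus optional external labels), its :meth:`fit` runs all four statistical
screens, combines them, and — when labels are present — computes the
agreement tables and predictive-validity breakdowns. The returned
``ScreenResults`` carries every intermediate table and renders a text
``summary()``.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import pandas as pd

from . import evaluate as ev
from . import flags as fl
from .claims import StudyWindow, summarise_centres
from .digits import BENFORD_FIRST, UNIFORM_LAST, DigitScreenConfig, flag_digit_screen
from .positivity import ConvergenceError, PositivityModel, PositivityResults, flag_low_positivity
from .volume import VolumeFlagConfig, flag_high_volume

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ScreenConfig:
    """Tunable thresholds of the four screens and the combination rules."""

    volume: VolumeFlagConfig = dataclasses.field(default_factory=VolumeFlagConfig)
    benford: DigitScreenConfig = dataclasses.field(
        default_factory=lambda: DigitScreenConfig(screen=BENFORD_FIRST)
    )
    last_digit: DigitScreenConfig = dataclasses.field(
        default_factory=lambda: DigitScreenConfig(screen=UNIFORM_LAST)
    )
    positivity_alpha: float = 0.05
    combination_ks: tuple[int, ...] = (2,)
    missing_label_policy: str = "treat_as_unsuspected"


class FraudScreen:
    """Statistical conspicuousness screen over a claims dataset.

    Parameters
    ----------
    claims : validated claims table (see :mod:`claimscreen.claims`)
    labels : optional per-centre table with ``suspected_conventional`` and
        ``corroborated`` columns
    window : study window; inferred from the data range when omitted
    config : detector thresholds and combination rules
    """

    def __init__(
        self,
        claims: pd.DataFrame,
        labels: Optional[pd.DataFrame] = None,
        window: Optional[StudyWindow] = None,
        config: Optional[ScreenConfig] = None,
    ):
        self.claims = claims
        self.labels = labels
        self.window = window or StudyWindow(claims["date"].min(), claims["date"].max())
        self.config = config or ScreenConfig()

    def fit(self, fit_positivity: bool = True) -> "ScreenResults":
        cfg = self.config
        summaries = summarise_centres(self.claims)
        method_flags: dict[str, pd.DataFrame] = {
            fl.HIGH_VOLUME: flag_high_volume(summaries, cfg.volume),
            fl.BENFORD: flag_digit_screen(summaries, cfg.benford),
            fl.LAST_DIGIT: flag_digit_screen(summaries, cfg.last_digit),
        }

        positivity_fit: Optional[PositivityResults] = None
        degraded = False
        if fit_positivity:
            try:
                model = PositivityModel.from_claims(self.claims, self.window)
                positivity_fit = model.fit()
                method_flags[fl.LOW_POSITIVITY] = flag_low_positivity(
                    positivity_fit, alpha=cfg.positivity_alpha, centres=summaries.index
                )
            except ConvergenceError as exc:
                degraded = True
                log.warning(
                    "positivity model did not converge (%s); continuing with three detectors", exc
                )

        ordered = [m for m in fl.METHODS if m in method_flags]
        combined: dict[str, pd.DataFrame] = {
            "any": ev.combine_flags([method_flags[m] for m in ordered], rule=ev.ANY)
        }
        for k in cfg.combination_ks:
            combined[f"at_least_{k}"] = ev.combine_flags(
                [method_flags[m] for m in ordered], rule=ev.AT_LEAST_K, k=k
            )

        agreement: dict[str, ev.AgreementTable] = {}
        overlap: dict[str, ev.OverlapMetrics] = {}
        validity: dict[str, ev.ValidityBreakdown] = {}
        if self.labels is not None:
            for name, table in {**method_flags, **combined}.items():
                agreement[name] = ev.cross_tabulate(
                    table, self.labels, missing_label_policy=cfg.missing_label_policy
                )
                try:
                    overlap[name] = ev.overlap_metrics(agreement[name])
                except ValueError:
                    log.warning("overlap metrics undefined for %s (empty margin)", name)
                validity[name] = ev.predictive_validity(table, self.labels)

        return ScreenResults(
            model=self,
            summaries=summaries,
            method_flags=method_flags,
            combined_flags=combined,
            positivity=positivity_fit,
            agreement=agreement,
            overlap=overlap,
            validity=validity,
            degraded=degraded,
        )


@dataclasses.dataclass
class ScreenResults:
    """All outputs of one screening run."""

    model: FraudScreen
    summaries: pd.DataFrame
    method_flags: dict[str, pd.DataFrame]
    combined_flags: dict[str, pd.DataFrame]
    positivity: Optional[PositivityResults]
    agreement: dict[str, ev.AgreementTable]
    overlap: dict[str, ev.OverlapMetrics]
    validity: dict[str, ev.ValidityBreakdown]
    degraded: bool = False

    @property
    def all_flags(self) -> dict[str, pd.DataFrame]:
        return {**self.method_flags, **self.combined_flags}

    def flags_long(self) -> pd.DataFrame:
        """All flag tables stacked into one long table."""
        frames = [t.reset_index() for t in self.all_flags.values()]
        return pd.concat(frames, ignore_index=True)[
            ["centre_id", "method", "eligible", "score", "flagged"]
        ]

    def summary(self) -> str:
        n_centres = len(self.summaries)
        lines = [
            "Statistical fraud screen",
            "=" * 72,
            f"centres: {n_centres}   centre-days: {len(self.model.claims)}"
            + ("   [DEGRADED: positivity model unavailable]" if self.degraded else ""),
            "",
            f"{'method':<16}{'eligible':>10}{'flagged':>10}"
            + (f"{'pos.ovl%':>10}{'neg.ovl%':>10}{'incr%':>8}{'ipv%':>8}" if self.overlap else ""),
            "-" * 72,
        ]
        for name, table in self.all_flags.items():
            row = f"{name:<16}{int(table['eligible'].sum()):>10}{int(table['flagged'].sum()):>10}"
            if name in self.overlap:
                m = self.overlap[name]
                v = self.validity[name]
                ipv = v.incremental_predictive_validity_pct
                row += (
                    f"{m.positive_overlap_pct:>10.1f}{m.negative_overlap_pct:>10.1f}"
                    f"{m.incremental_share_pct:>8.1f}"
                    + (f"{ipv:>8.1f}" if ipv is not None else f"{'--':>8}")
                )
            lines.append(row)
        if self.positivity is not None:
            lines += ["", self.positivity.summary()]
        return "\n".join(lines)

    def report(self) -> dict:
        """JSON-serialisable bundle of counts and metrics."""
        out: dict = {
            "n_centres": int(len(self.summaries)),
            "n_centre_days": int(len(self.model.claims)),
            "degraded": self.degraded,
            "methods": {},
        }
        for name, table in self.all_flags.items():
            entry: dict = {
                "n_eligible": int(table["eligible"].sum()),
                "n_flagged": int(table["flagged"].sum()),
            }
            if name in self.agreement:
                entry["agreement"] = ev.agreement_report(self.agreement[name])
            if name in self.validity:
                entry["validity"] = ev.validity_report(self.validity[name])
            out["methods"][name] = entry
        if self.positivity is not None:
            out["positivity_model"] = self.positivity.report()
        return out
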