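"""Synthetic daily-claims generator with injected fraud behaviours.

The real billing data are confidential, so every downstream stage is
exercised on simulated claims whose ground truth is known. The generator
emulates the pilot's observable structure:

* three centre categories (pharmacy / doctor's-or-dentist's office /
  private) with strongly right-skewed daily volumes — per category a
  log-normal whose median and mean match the published descriptives
  (medians 64 / 5 / 115, means 108 / 21 / 194), split into a between-centre
  size component and day-to-day variation;
* positivity near 2% (category levels 2.44% / 2.75% / 1.95%) varying by
  calendar week on the log-odds scale, with centre-level heterogeneity;
* centres active on subsets of the ~73-week window (late openers, closed
  days, a short-lived minority), so a realistic share of centres fails the
  30-active-day digit-screen eligibility rule;
* four injectable fraud behaviours matching the screens' targets —
  volume inflation, positivity suppression, digit rounding to multiples of
  5 or 10, and fabrication of near-constant counts — applied in the order
  inflation → fabrication → rounding, with suppression acting on the
  positivity probability;
* imperfect external labels: conventional suspicion and post-investigation
  corroboration are drawn from a two-coin misclassification model so the
  agreement tables are non-trivial.

All randomness derives from a single root seed through per-centre
substreams, so adding a centre never shifts the draws of existing ones and
identical configs produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from scipy.special import expit, logit

from .claims import CATEGORIES, CLAIM_COLUMNS, DEFAULT_WINDOW, StudyWindow

log = logging.getLogger(__name__)

VOLUME_INFLATION = "volume_inflation"
POSITIVITY_SUPPRESSION = "positivity_suppression"
DIGIT_ROUNDING = "digit_rounding"
FABRICATION = "fabrication"
BEHAVIOURS = (VOLUME_INFLATION, POSITIVITY_SUPPRESSION, DIGIT_ROUNDING, FABRICATION)


class CategoryVolume(BaseModel):
    """Log-normal daily-volume parameters for one category.

    ``log_median`` is ln(median daily tests); the total log-sd (between-centre
    size + within-centre day-to-day) controls the mean/median ratio via
    mean = median·exp(sd²/2).
    """

    log_median: float
    log_sd_between: float = Field(gt=0)
    log_sd_within: float = Field(gt=0)


def _category_volume(median: float, mean: float) -> CategoryVolume:
    # total variance from the mean/median ratio, split evenly between and within
    total_var = 2.0 * np.log(mean / median)
    sd = float(np.sqrt(total_var / 2.0))
    return CategoryVolume(log_median=float(np.log(median)), log_sd_between=sd, log_sd_within=sd)


class BehaviourParams(BaseModel):
    inflation_factor: float = Field(default=8.0, ge=1.0)
    suppression_factor: float = Field(default=0.25, gt=0.0, le=1.0)
    rounding_base: int = Field(default=5)
    fabrication_low: int = Field(default=480, ge=1)
    fabrication_high: int = Field(default=520, ge=1)

    @field_validator("rounding_base")
    @classmethod
    def _base(cls, v):
        if v not in (5, 10):
            raise ValueError("rounding_base must be 5 or 10")
        return v

    def model_post_init(self, _ctx) -> None:
        if self.fabrication_low > self.fabrication_high:
            raise ValueError("fabrication band low must be <= high")


class LabelModel(BaseModel):
    """Two-coin misclassification model for the external labels."""

    p_suspected_given_fraud: float = Field(default=0.45, ge=0, le=1)
    p_suspected_given_honest: float = Field(default=0.025, ge=0, le=1)
    p_corroborated_given_fraud: float = Field(default=0.85, ge=0, le=1)
    p_corroborated_given_honest: float = Field(default=0.10, ge=0, le=1)


class ActivityModel(BaseModel):
    """How centres occupy the study window."""

    open_prob: dict[str, float] = Field(
        default={"pharmacy": 0.70, "practice": 0.25, "private": 0.80}
    )
    max_start_fraction: float = Field(default=0.5, ge=0, le=1)
    short_lived_prob: float = Field(default=0.25, ge=0, le=1)
    short_span_days: tuple[int, int] = (5, 60)


class SimulationConfig(BaseModel):
    """Full specification of a synthetic claims dataset."""

    seed: int = 0
    n_centres: dict[str, int] = Field(default={"pharmacy": 60, "practice": 390, "private": 457})
    window_start: dt.date = DEFAULT_WINDOW.start
    window_end: dt.date = DEFAULT_WINDOW.end
    volume: dict[str, CategoryVolume] = Field(
        default_factory=lambda: {
            "pharmacy": _category_volume(64, 108),
            "practice": _category_volume(5, 21),
            "private": _category_volume(115, 194),
        }
    )
    base_positivity: dict[str, float] = Field(
        default={"pharmacy": 0.0244, "practice": 0.0275, "private": 0.0195}
    )
    weekly_curve: Optional[list[float]] = None
    week_sd: float = Field(default=0.3, ge=0)
    centre_sd: float = Field(default=0.3, ge=0)
    fraud_prevalence: dict[str, float] = Field(
        default={b: 0.05 for b in BEHAVIOURS}
    )
    behaviour: BehaviourParams = Field(default_factory=BehaviourParams)
    labels: LabelModel = Field(default_factory=LabelModel)
    activity: ActivityModel = Field(default_factory=ActivityModel)

    @field_validator("n_centres")
    @classmethod
    def _counts(cls, v):
        for cat, n in v.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
            if n <= 0:
                raise ValueError(f"centre count for {cat!r} must be positive")
        return v

    @field_validator("fraud_prevalence")
    @classmethod
    def _prev(cls, v):
        for b, p in v.items():
            if b not in BEHAVIOURS:
                raise ValueError(f"unknown behaviour {b!r}")
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {b!r} must be in [0, 1]")
        return v

    @property
    def window(self) -> StudyWindow:
        return StudyWindow(self.window_start, self.window_end)


@dataclasses.dataclass(frozen=True)
class CentreSpec:
    """Ground-truth description of one simulated centre."""

    centre_id: str
    category: str
    stream_key: tuple[int, int]  # (category code, within-category position)
    start_day: int  # offset into the window
    end_day: int  # inclusive offset
    open_prob: float
    base_volume: float  # centre-level median daily tests
    positivity_offset: float  # centre random intercept on the log-odds scale
    behaviours: frozenset[str]
    params: BehaviourParams

    @property
    def honest(self) -> bool:
        return not self.behaviours


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def generate_centres(config: SimulationConfig) -> list[CentreSpec]:
    """Draw centre specifications (size, activity, behaviours) from the config."""
    window = config.window
    d = window.n_days
    specs: list[CentreSpec] = []
    prefix = {"pharmacy": "PH", "practice": "DR", "private": "PT"}
    for cat_code, cat in enumerate(CATEGORIES):
        n = config.n_centres.get(cat, 0)
        if n == 0:
            continue
        vol = config.volume[cat]
        for j in range(n):
            # streams keyed by (category, position) so adding a centre to one
            # category never shifts the draws of existing centres
            rng = _stream(config.seed, 1, cat_code, j)
            behaviours = frozenset(
                b for b in BEHAVIOURS if rng.random() < config.fraud_prevalence.get(b, 0.0)
            )
            start = int(rng.integers(0, max(1, int(config.activity.max_start_fraction * d))))
            if rng.random() < config.activity.short_lived_prob:
                lo, hi = config.activity.short_span_days
                end = min(d - 1, start + int(rng.integers(lo, hi + 1)) - 1)
            else:
                end = d - 1
            base_volume = float(
                np.exp(vol.log_median + vol.log_sd_between * rng.standard_normal())
            )
            offset = float(config.centre_sd * rng.standard_normal())
            specs.append(
                CentreSpec(
                    centre_id=f"{prefix[cat]}{j + 1:04d}",
                    category=cat,
                    stream_key=(cat_code, j),
                    start_day=start,
                    end_day=end,
                    open_prob=config.activity.open_prob[cat],
                    base_volume=base_volume,
                    positivity_offset=offset,
                    behaviours=behaviours,
                    params=config.behaviour,
                )
            )
    return specs


def _week_effects(config: SimulationConfig) -> np.ndarray:
    """Per-week additive effects on the log-odds of positivity."""
    n_weeks = config.window.n_weeks
    if config.weekly_curve is not None:
        curve = np.asarray(config.weekly_curve, dtype=float)
        if len(curve) != n_weeks:
            raise ValueError(f"weekly_curve must have length {n_weeks}, got {len(curve)}")
        lo = logit(curve)
        return lo - lo.mean()
    rng = _stream(config.seed, 0)
    return config.week_sd * rng.standard_normal(n_weeks)


def generate_claims(
    specs: list[CentreSpec], config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate daily claims and the ground-truth/label table.

    Returns ``(claims, truth)``. ``claims`` has the standard five columns.
    ``truth`` has one row per centre: category, the injected behaviours,
    a ``fraudulent`` indicator, and the external labels
    ``suspected_conventional`` and ``corroborated`` (0/1).
    """
    window = config.window
    week_eff = _week_effects(config)
    dates = np.array(window.dates())
    day_weeks = np.arange(window.n_days) // 7  # 0-based week per day offset

    rows_centre: list[np.ndarray] = []
    rows = {"date": [], "n_tests": [], "n_positive": []}
    truth_rows = []
    for spec in specs:
        rng = _stream(config.seed, 2, *spec.stream_key)
        p = spec.params
        span = np.arange(spec.start_day, spec.end_day + 1)
        open_days = span[rng.random(len(span)) < spec.open_prob]

        base = spec.base_volume
        if VOLUME_INFLATION in spec.behaviours:
            base = base * p.inflation_factor
        sd_w = config.volume[spec.category].log_sd_within
        vols = np.maximum(
            1, np.rint(np.exp(np.log(base) + sd_w * rng.standard_normal(len(open_days))))
        ).astype(np.int64)
        if FABRICATION in spec.behaviours:
            vols = rng.integers(p.fabrication_low, p.fabrication_high + 1, size=len(open_days))
        if DIGIT_ROUNDING in spec.behaviours:
            vols = np.maximum(
                p.rounding_base,
                (np.rint(vols / p.rounding_base) * p.rounding_base).astype(np.int64),
            )

        prob = expit(
            logit(config.base_positivity[spec.category])
            + spec.positivity_offset
            + week_eff[day_weeks[open_days]]
        )
        if POSITIVITY_SUPPRESSION in spec.behaviours:
            prob = prob * p.suppression_factor
        pos = rng.binomial(vols, np.clip(prob, 0.0, 1.0))

        rows_centre.append(np.repeat(spec.centre_id, len(open_days)))
        rows["date"].append(dates[open_days])
        rows["n_tests"].append(vols)
        rows["n_positive"].append(pos)

        lrng = _stream(config.seed, 3, *spec.stream_key)
        lm = config.labels
        fraud = not spec.honest
        p_susp = lm.p_suspected_given_fraud if fraud else lm.p_suspected_given_honest
        p_corr = lm.p_corroborated_given_fraud if fraud else lm.p_corroborated_given_honest
        truth_rows.append(
            {
                "centre_id": spec.centre_id,
                "category": spec.category,
                "behaviours": ";".join(sorted(spec.behaviours)),
                "fraudulent": int(fraud),
                "suspected_conventional": int(lrng.random() < p_susp),
                "corroborated": int(lrng.random() < p_corr),
            }
        )

    truth = pd.DataFrame(truth_rows)
    if not rows["date"] or sum(len(x) for x in rows["date"]) == 0:
        log.warning("simulation produced no centre-days (degenerate window or activity)")
        claims = pd.DataFrame(columns=CLAIM_COLUMNS)
        return claims, truth

    cat_by_id = {s.centre_id: s.category for s in specs}
    claims = pd.DataFrame(
        {
            "centre_id": np.concatenate(rows_centre),
            "date": np.concatenate(rows["date"]),
            "n_tests": np.concatenate(rows["n_tests"]),
            "n_positive": np.concatenate(rows["n_positive"]),
        }
    )
    claims["category"] = claims["centre_id"].map(cat_by_id)
    claims = claims.loc[:, CLAIM_COLUMNS].reset_index(drop=True)
    return claims, truth


def simulate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: generate_centres + generate_claims."""
    return generate_claims(generate_centres(config), config)


def truth_to_labels(truth: pd.DataFrame) -> pd.DataFrame:
    """External-label view of the ground-truth table (for the evaluation stage)."""
    out = truth.loc[:, ["centre_id", "suspected_conventional", "corroborated"]].copy()
    out["suspected_conventional"] = out["suspected_conventional"].astype("Int64")
    out["corroborated"] = out["corroborated"].astype("Int64")
    return out
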