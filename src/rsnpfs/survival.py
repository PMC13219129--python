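"""Progression classification and survival analysis.

Implements the radiographic progression rules used to derive
progression-free survival (PFS) in high-grade glioma (RANO 2.0 style):
measurable lesions are contrast-enhancing, visible on two or more axial
slices, with both perpendicular diameters strictly greater than 10 mm;
progression is a >= 25% increase in the sum of perpendicular diameter
products, or a significant increase of non-enhancing FLAIR/T2 lesions.

Kaplan-Meier curves, the two-group log-rank test and the univariate Cox
proportional-hazards fit are delegated to lifelines; this module wraps them
behind a small array-based interface and adds the median-split
stratification of predicted PFS used to compare risk groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

DAYS_PER_MONTH = 30.44  # mean Gregorian month
MEASURABLE_DIAMETER_MM = 10.0
PROGRESSION_RATIO = 1.25


@dataclass(frozen=True)
class LesionMeasurement:
    """One lesion at one timepoint: two perpendicular diameters (mm)."""

    diameters_mm: tuple[float, float]
    axial_slices: int
    enhancing: bool = True
    timepoint: str = "baseline"

    def __post_init__(self) -> None:
        if min(self.diameters_mm) <= 0:
            raise ValueError("lesion diameters must be positive")
        if self.axial_slices < 1:
            raise ValueError("axial slice count must be >= 1")


def lesions_from_frame(df: pd.DataFrame) -> list[LesionMeasurement]:
    """Build lesion measurements from a table with documented headers."""
    return [
        LesionMeasurement(
            diameters_mm=(float(r.diameter1_mm), float(r.diameter2_mm)),
            axial_slices=int(r.axial_slices),
            enhancing=bool(r.enhancing),
            timepoint=str(r.timepoint),
        )
        for r in df.itertuples()
    ]


def is_measurable(lesion: LesionMeasurement) -> bool:
    """Measurable: enhancing, on >= 2 axial slices, both diameters > 10 mm."""
    return (
        lesion.enhancing
        and lesion.axial_slices >= 2
        and min(lesion.diameters_mm) > MEASURABLE_DIAMETER_MM
    )


def sum_perpendicular_products(lesions: list[LesionMeasurement]) -> float:
    """Sum over measurable lesions of diameter1 x diameter2 (mm^2)."""
    return float(
        sum(l.diameters_mm[0] * l.diameters_mm[1] for l in lesions if is_measurable(l))
    )


def classify_progression(
    baseline_lesions: list[LesionMeasurement],
    followup_lesions: list[LesionMeasurement],
    flair_increase: bool = False,
) -> bool:
    """Progression iff follow-up sum >= 1.25 x baseline sum, or FLAIR increase.

    A zero measurable baseline sum with no FLAIR information is
    indeterminate and raises.
    """
    if flair_increase:
        return True
    base = sum_perpendicular_products(baseline_lesions)
    if base == 0:
        raise ValueError(
            "no measurable baseline lesion sum and no FLAIR flag: progression indeterminate"
        )
    follow = sum_perpendicular_products(followup_lesions)
    return follow >= PROGRESSION_RATIO * base


def compute_pfs(baseline_date, recurrence_or_death_date) -> float:
    """Months between the post-radiotherapy baseline scan and recurrence/death.

    Dates are anything ``pandas.Timestamp`` accepts; a month is 30.44 days.
    """
    delta_days = (pd.Timestamp(recurrence_or_death_date) - pd.Timestamp(baseline_date)).days
    if delta_days <= 0:
        raise ValueError("recurrence/death date must be after the baseline date")
    return float(delta_days / DAYS_PER_MONTH)


def km_curve(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) estimate honoring right-censoring.

    Returns a step table with columns ``time``, ``n_at_risk``, ``n_events``
    and ``survival`` (one row per distinct observed time, plus t=0).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    return pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "n_at_risk": table["at_risk"].to_numpy(dtype=int),
            "n_events": table["observed"].to_numpy(dtype=int),
            "survival": surv.to_numpy(dtype=float),
        }
    )


def logrank_test(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic with 1 df, p-value)."""
    res = _ll_logrank(
        np.asarray(times_a, dtype=float),
        np.asarray(times_b, dtype=float),
        event_observed_A=np.asarray(events_a).astype(int),
        event_observed_B=np.asarray(events_b).astype(int),
    )
    return float(res.test_statistic), float(res.p_value)


def cox_hr(
    times: np.ndarray,
    events: np.ndarray,
    group: np.ndarray,
) -> tuple[float, float]:
    """Univariate proportional-hazards fit on a binary group indicator.

    Returns (hazard ratio = exp(coefficient), p-value) for membership in
    group 1 relative to group 0. Raises if either group has no events (the
    partial likelihood has no maximum).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    group = np.asarray(group).astype(int)
    if set(np.unique(group)) - {0, 1}:
        raise ValueError("group must be a binary 0/1 indicator")
    for g in (0, 1):
        if events[group == g].sum() == 0:
            raise ValueError(
                f"group {g} has no observed events; Cox fit cannot converge"
            )
    df = pd.DataFrame({"time": times, "event": events, "group": group})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    coef = float(cph.params_["group"])
    pval = float(cph.summary.loc["group", "p"])
    return float(np.exp(coef)), pval


def breslow_score(beta: float, times: np.ndarray, events: np.ndarray, group: np.ndarray) -> float:
    """Score (d logL / d beta) of the Breslow partial likelihood.

    Provided for optimality checks of the fitted coefficient: at the
    maximizer the score is ~0 (exactly equal to the Efron score when event
    times are untied).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    x = np.asarray(group, dtype=float)
    score = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        w = np.exp(beta * x[at_risk])
        d = int(((times == t) & (events == 1)).sum())
        x_event_sum = x[(times == t) & (events == 1)].sum()
        score += x_event_sum - d * float((w * x[at_risk]).sum() / w.sum())
    return score


def stratify_by_median(predictions: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Median split of predicted PFS: (low indices, high indices, cutoff).

    Subjects at or below the median go to the low group, so an odd cohort
    splits (n+1)/2 low vs (n-1)/2 high (e.g. 23 vs 22 for n = 45). An
    all-equal prediction vector is a degenerate split and raises.
    """
    pred = np.asarray(predictions, dtype=float)
    if np.ptp(pred) == 0:
        raise ValueError("all predictions equal; median split is degenerate")
    cutoff = float(np.median(pred))
    low = np.flatnonzero(pred <= cutoff)
    high = np.flatnonzero(pred > cutoff)
    return low, high, cutoff
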