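"""Four-level lending-trajectory classification.

Crosses two tract-level axes:

* **historic redlining** — the 1930s HOLC-grade-weighted historical
  redlining score (HRS, 1 = "A/Best" … 4 = "D/Hazardous") dichotomized at
  a percentile of its citywide distribution (default 25th; at/above the
  cutoff = "high historic redlining");
* **current lending discrimination** — bottom decile of originated loans
  per 1,000 residents citywide, OR a high-cost-loan share of at least 15%
  (rate spread > 1.5 points over the average prime offer rate), OR both.

The cross yields four categories::

    (low,  none) -> high_investment        (high, none) -> growing_investment
    (low,  yes ) -> disinvested            (high, yes ) -> sustained_disinvestment

``disinvested`` is the modeling reference category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TRAJECTORY_LEVELS = (
    "disinvested",
    "growing_investment",
    "high_investment",
    "sustained_disinvestment",
)

REFERENCE_TRAJECTORY = "disinvested"


def dichotomize_hrs(hrs: np.ndarray, percentile: float = 25.0) -> np.ndarray:
    """Flag tracts at/above the given percentile of the non-missing HRS.

    The cutoff uses linear interpolation between order statistics. Returns a
    float array with 1.0 (high historic redlining), 0.0 (low) and NaN where
    HRS is missing; missing tracts are excluded downstream.
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    x = np.asarray(hrs, dtype=float)
    valid = ~np.isnan(x)
    if not valid.any():
        raise ValueError("no non-missing HRS values to dichotomize")
    cutoff = np.percentile(x[valid], percentile)  # linear interpolation
    out = np.full(x.shape, np.nan)
    out[valid] = (x[valid] >= cutoff).astype(float)
    return out


def flag_lending_discrimination(
    loans_per_1000: np.ndarray,
    high_cost_fraction: np.ndarray,
    decile_cut: float = 10.0,
    cost_threshold: float = 0.15,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Current-discrimination flags from lending aggregates.

    ``low_lending`` is true iff loans per 1,000 residents fall at/below the
    ``decile_cut`` percentile citywide (ties included: a tract exactly at
    the cutoff is flagged). ``high_cost`` is true iff the high-cost-loan
    share is at least ``cost_threshold``; tracts with no originated loans
    carry a missing share and can only qualify through the low-lending arm.
    ``current_discrimination`` is the OR, missing only if both arms are
    missing (low-lending is never missing here).

    Returns three float arrays with values 1.0 / 0.0 / NaN.
    """
    loans = np.asarray(loans_per_1000, dtype=float)
    frac = np.asarray(high_cost_fraction, dtype=float)
    if np.isnan(loans).all() and np.isnan(frac).all():
        raise ValueError("all lending columns missing; cannot classify")
    valid_loans = ~np.isnan(loans)
    if not valid_loans.any():
        raise ValueError("loans_per_1000 entirely missing")
    cutoff = np.percentile(loans[valid_loans], decile_cut)
    low = np.full(loans.shape, np.nan)
    low[valid_loans] = (loans[valid_loans] <= cutoff).astype(float)

    high = np.full(frac.shape, np.nan)
    valid_frac = ~np.isnan(frac)
    high[valid_frac] = (frac[valid_frac] >= cost_threshold).astype(float)

    # OR with missing-aware semantics: any known 1 wins; known 0 + missing -> 0
    # only when the missing arm is the high-cost share of a zero-loan tract,
    # which cannot rescue a tract already below the low-lending cutoff.
    current = np.where(
        np.isnan(low) & np.isnan(high),
        np.nan,
        (np.nan_to_num(low) + np.nan_to_num(high) > 0).astype(float),
    )
    return low, high, current


def assign_trajectory(
    high_historic_redlining: bool, current_discrimination: bool
) -> str:
    """Exact truth table of the two dichotomous axes."""
    table = {
        (False, False): "high_investment",
        (True, False): "growing_investment",
        (False, True): "disinvested",
        (True, True): "sustained_disinvestment",
    }
    return table[(bool(high_historic_redlining), bool(current_discrimination))]


@dataclass
class ClassificationResult:
    """Classified tract table plus exclusion accounting."""

    table: pd.DataFrame
    n_excluded: int
    exclusion_reasons: dict[str, int]


def classify_tracts(
    table: pd.DataFrame,
    hrs_percentile: float = 25.0,
    decile_cut: float = 10.0,
    cost_threshold: float = 0.15,
) -> ClassificationResult:
    """Attach flags and trajectory labels to a tract table.

    Adds columns ``high_historic_redlining``, ``low_lending_flag``,
    ``high_cost_flag``, ``current_discrimination``, ``trajectory`` and
    ``exclusion_reason`` (empty string = included). Tracts with missing HRS
    cannot be placed on the historic axis and are excluded with a recorded
    reason, mirroring undetermined-trajectory exclusions in real studies.
    """
    df = table.copy()
    hrs_flag = dichotomize_hrs(df["hrs"].to_numpy(dtype=float), hrs_percentile)
    low, high, current = flag_lending_discrimination(
        df["loans_per_1000"].to_numpy(dtype=float),
        df["high_cost_fraction"].to_numpy(dtype=float),
        decile_cut=decile_cut,
        cost_threshold=cost_threshold,
    )
    df["high_historic_redlining"] = hrs_flag
    df["low_lending_flag"] = low
    df["high_cost_flag"] = high
    df["current_discrimination"] = current

    reasons = []
    labels = []
    for h, c in zip(hrs_flag, current):
        if np.isnan(h):
            reasons.append("hrs_missing")
            labels.append("")
        elif np.isnan(c):
            reasons.append("lending_undetermined")
            labels.append("")
        else:
            reasons.append("")
            labels.append(assign_trajectory(h > 0, c > 0))
    df["trajectory"] = labels
    df["exclusion_reason"] = reasons

    counts: dict[str, int] = {}
    for r in reasons:
        if r:
            counts[r] = counts.get(r, 0) + 1
    return ClassificationResult(table=df, n_excluded=sum(counts.values()), exclusion_reasons=counts)
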