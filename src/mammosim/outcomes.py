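"""Scenario aggregation: counters, rates, benefits, harms, attribution.

Works on tidy per-woman logs (one row per woman per scenario) produced by
the engine.  Benefits (deaths averted, life-years gained) are always
relative to a named comparator run on the same cohort with paired seeds.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .constants import STD_AGE_BANDS, age_band

__all__ = [
    "ScenarioResult",
    "AttributionResult",
    "classify_overdiagnosis",
    "age_adjust",
    "compare_scenarios",
    "harm_benefit_ratio",
    "attribute_reduction",
    "complementary_share",
    "ensemble_summary",
    "summarize_log",
    "mortality_rate",
]


@dataclasses.dataclass
class ScenarioResult:
    """Counters per 1,000 women plus optional comparator-relative benefits."""

    label: str
    n_women: int
    screens: float
    false_positives: float
    benign_biopsies: float
    interval_cancers: float
    screen_detected: float
    clinically_detected: float
    overdiagnosed: float
    bc_deaths: float
    deaths_averted: float | None = None
    life_years_gained: float | None = None
    comparator: str | None = None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class AttributionResult:
    total_reduction_pct: float
    screening_share_pct: float
    treatment_share_pct: float
    method: str = "shapley"


def classify_overdiagnosis(mode: str | None, latent_clinical_age: float | None, other_cause_death_age: float) -> bool:
    """True iff the case was screen detected and its latent symptomatic
    date falls after other-cause death (it would never have surfaced)."""
    if mode != "screen":
        return False
    if latent_clinical_age is None:
        raise ValueError("screen-detected case with no latent clinical age")
    return latent_clinical_age > other_cause_death_age


def age_adjust(rates, weights) -> float:
    """Direct standardization: weighted sum of age-group rates."""
    r = np.asarray(rates, dtype=float)
    w = np.asarray(weights, dtype=float)
    if r.shape != w.shape:
        raise ValueError(f"rate groups {r.shape} do not match weight groups {w.shape}")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"standard-population weights sum to {w.sum():.12g}, not 1")
    return float(r @ w)


def summarize_log(log: pd.DataFrame, label: str) -> ScenarioResult:
    """Collapse a per-woman log into per-1,000-women counters."""
    n = len(log)
    k = 1000.0 / n
    return ScenarioResult(
        label=label,
        n_women=n,
        screens=float(log["n_screens"].sum() * k),
        false_positives=float(log["n_false_positives"].sum() * k),
        benign_biopsies=float(log["n_benign_biopsies"].sum() * k),
        interval_cancers=float(log["interval_cancer"].sum() * k),
        screen_detected=float((log["detection_mode"] == "screen").sum() * k),
        clinically_detected=float((log["detection_mode"] == "clinical").sum() * k),
        overdiagnosed=float(log["overdiagnosed"].sum() * k),
        bc_deaths=float((log["cause"] == "breast_cancer").sum() * k),
    )


def compare_scenarios(log: pd.DataFrame, comparator_log: pd.DataFrame) -> dict:
    """Per-1,000-women deaths averted and life-years gained vs comparator.

    Requires paired cohorts (same women, same ids, paired seeds)."""
    if len(log) != len(comparator_log) or not (log["id"].to_numpy() == comparator_log["id"].to_numpy()).all():
        raise ValueError("scenario and comparator logs are not paired (cohorts differ)")
    k = 1000.0 / len(log)
    deaths = float((log["cause"] == "breast_cancer").sum())
    deaths_cmp = float((comparator_log["cause"] == "breast_cancer").sum())
    lyg = float((log["death_age"].to_numpy() - comparator_log["death_age"].to_numpy()).sum())
    return {
        "deaths_averted": (deaths_cmp - deaths) * k,
        "life_years_gained": lyg * k,
    }


def harm_benefit_ratio(harm: float, benefit: float) -> float | None:
    """Harm per unit benefit; None (never a silent infinity) when the
    benefit is non-positive."""
    if benefit <= 0:
        return None
    return float(harm) / float(benefit)


def complementary_share(share_pct: float) -> float:
    """The other component's share of an exhaustive two-way decomposition."""
    return 100.0 - float(share_pct)


def attribute_reduction(
    m_none: float,
    m_screen_only: float,
    m_treat_only: float,
    m_both: float,
    method: str = "shapley",
) -> AttributionResult:
    """Split the mortality reduction (none -> both) between screening and
    treatment.

    ``shapley`` (default): each player gets the average of its marginal
    contributions over the two orderings, so the (negative) synergy is
    split evenly and the shares are exhaustive by construction.
    ``screen_first``: sequential decomposition crediting screening with
    its solo effect and treatment with the remainder.
    """
    if m_none <= 0:
        raise ValueError("background mortality rate must be positive")
    total = m_none - m_both
    if total == 0:
        raise ValueError("zero total reduction: shares are undefined")
    if method == "shapley":
        phi_screen = 0.5 * ((m_none - m_screen_only) + (m_treat_only - m_both))
        phi_treat = 0.5 * ((m_none - m_treat_only) + (m_screen_only - m_both))
    elif method == "screen_first":
        phi_screen = m_none - m_screen_only
        phi_treat = m_screen_only - m_both
    else:
        raise ValueError(f"unknown attribution method {method!r}")
    return AttributionResult(
        total_reduction_pct=100.0 * total / m_none,
        screening_share_pct=100.0 * phi_screen / total,
        treatment_share_pct=100.0 * phi_treat / total,
        method=method,
    )


def mortality_rate(log: pd.DataFrame, weights: pd.Series | None = None) -> float:
    """Age-adjusted breast-cancer mortality per 100,000 woman-years.

    Person-years and deaths are binned into the standard-population age
    groups; group rates are directly standardized with ``weights`` (or
    person-year weights when None)."""
    bands = STD_AGE_BANDS
    labels = [b[2] for b in bands]
    py = {lab: 0.0 for lab in labels}
    deaths = {lab: 0.0 for lab in labels}
    death_age = log["death_age"].to_numpy(dtype=float)
    is_bc = (log["cause"] == "breast_cancer").to_numpy()
    for lo, hi, lab in bands:
        time_in = np.clip(np.minimum(death_age, hi) - lo, 0.0, None)
        py[lab] = float(time_in.sum())
        deaths[lab] = float((is_bc & (death_age >= lo) & (death_age < hi)).sum())
    rates = []
    w = []
    for lab in labels:
        rates.append(1e5 * deaths[lab] / py[lab] if py[lab] > 0 else 0.0)
        if weights is None:
            w.append(py[lab])
        else:
            w.append(float(weights[lab]))
    w = np.asarray(w) / np.sum(w)
    return age_adjust(rates, w)


def ensemble_summary(results: list[dict]) -> dict:
    """Average-and-range summary across parameter variants.

    Returns {field: {"mean": .., "min": .., "max": ..}} over every numeric
    field present in all results."""
    if not results:
        raise ValueError("ensemble_summary needs at least one result")
    keys = set(results[0])
    for r in results[1:]:
        keys &= set(r)
    out = {}
    for key in sorted(keys):
        vals = [r[key] for r in results]
        if not all(isinstance(v, (int, float)) and v is not None for v in vals):
            continue
        arr = np.asarray(vals, dtype=float)
        out[key] = {"mean": float(arr.mean()), "min": float(arr.min()), "max": float(arr.max())}
    return out
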