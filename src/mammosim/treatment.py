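"""Adjuvant treatment assignment and breast-cancer survival.

Treatment receipt follows a dissemination table stratified by age group,
stage, subtype, and calendar period, filtered by receptor eligibility
(endocrine therapy needs ER+, trastuzumab needs HER2+).  Efficacy acts
either as multiplicative hazard ratios on the baseline breast-cancer
death hazard or as per-modality cure probabilities — exactly one
mechanism per run.

Survival draws use a single shared uniform per woman so her survival
quantile is preserved across scenarios: a scenario can change her
stratum (stage shift) or her hazard (treatment), never her luck.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .constants import MODALITIES, SURV_AGE_BANDS, TREAT_AGE_BANDS, age_band, period_label
from .fixtures import ParameterSet
from .rng import substream

__all__ = [
    "TreatmentAssignment",
    "EfficacySpec",
    "assign_treatment",
    "sample_bc_survival",
    "resolve_death",
    "CURED",
]

CURED = "cured"


@dataclasses.dataclass(frozen=True)
class TreatmentAssignment:
    modalities: frozenset
    assignment_age: float
    calendar_year: float


@dataclasses.dataclass(frozen=True)
class EfficacySpec:
    """Per-modality efficacy under one active mechanism."""

    mechanism: str  # "hazard_reduction" | "cure_fraction"
    hazard_ratio: dict
    cure_probability: dict

    def __post_init__(self):
        if self.mechanism not in ("hazard_reduction", "cure_fraction"):
            raise ValueError(f"unknown efficacy mechanism {self.mechanism!r}")
        for m, hr in self.hazard_ratio.items():
            if not (0 < hr <= 1):
                raise ValueError(f"hazard ratio for {m!r} must lie in (0,1]")
        for m, c in self.cure_probability.items():
            if not (0 <= c <= 1):
                raise ValueError(f"cure probability for {m!r} must lie in [0,1]")

    @classmethod
    def from_params(cls, params: ParameterSet, mechanism: str | None = None) -> "EfficacySpec":
        eff = params.efficacy
        return cls(
            mechanism=mechanism or params.mechanism,
            hazard_ratio={m: float(eff.loc[m, "hazard_ratio"]) for m in eff.index},
            cure_probability={m: float(eff.loc[m, "cure_probability"]) for m in eff.index},
        )

    @classmethod
    def null(cls) -> "EfficacySpec":
        """No-effect spec: hazard ratios 1, cure probabilities 0."""
        return cls(
            mechanism="hazard_reduction",
            hazard_ratio={m: 1.0 for m in MODALITIES},
            cure_probability={m: 0.0 for m in MODALITIES},
        )


def _eligible(modality: str, subtype: str) -> bool:
    if modality == "endocrine":
        return subtype.startswith("ER+")
    if modality == "trastuzumab":
        return "HER2+" in subtype
    return True


def assign_treatment(
    detection_age: float,
    calendar_year: float,
    stage: str,
    subtype: str,
    params: ParameterSet,
    stream,
) -> TreatmentAssignment:
    """Draw each modality independently with its dissemination-stratum
    probability, then drop receptor-ineligible modalities."""
    ag = age_band(detection_age, TREAT_AGE_BANDS)
    per = period_label(calendar_year)
    cache = _dissemination_cache(params)
    got = set()
    for m in MODALITIES:
        key = (m, per, ag, stage, subtype)
        if key not in cache:
            raise KeyError(f"dissemination: no stratum {key}")
        if stream.random() < cache[key] and _eligible(m, subtype):
            got.add(m)
    return TreatmentAssignment(modalities=frozenset(got), assignment_age=detection_age, calendar_year=calendar_year)


def _dissemination_cache(params: ParameterSet) -> dict:
    # lazy per-table dict: the long table is too slow to filter per woman;
    # invalidated when the table object is swapped (e.g. copied ParameterSets)
    src, cache = getattr(params, "_dissem_cache", (None, None))
    if src is not params.dissemination:
        cache = {
            (r.modality, r.period, r.age_group, r.stage, r.subtype): float(r.probability)
            for r in params.dissemination.itertuples()
        }
        params._dissem_cache = (params.dissemination, cache)
    return cache


def _survival_cache(params: ParameterSet) -> dict:
    src, cache = getattr(params, "_surv_cache", (None, None))
    if src is not params.survival_baseline:
        cache = {
            (r.age_group, r.stage, r.subtype): float(r.hazard)
            for r in params.survival_baseline.itertuples()
        }
        params._surv_cache = (params.survival_baseline, cache)
    return cache


def _baseline_hazard(detection_age: float, stage: str, subtype: str, params: ParameterSet) -> float:
    key = (age_band(detection_age, SURV_AGE_BANDS), stage, subtype)
    cache = _survival_cache(params)
    if key not in cache:
        raise KeyError(f"survival_baseline: no stratum {key}")
    return cache[key]


def sample_bc_survival(
    detection_age: float,
    stage: str,
    subtype: str,
    assignment: TreatmentAssignment,
    efficacy: EfficacySpec,
    params: ParameterSet,
    *,
    survival_u: float,
    cure_u: float,
) -> float | str:
    """Breast-cancer death age, or :data:`CURED`.

    hazard_reduction: exponential survival at the baseline stratum hazard
    times the product of assigned modalities' hazard ratios.
    cure_fraction: cured with probability 1 - prod(1 - c_m) over assigned
    modalities, else unmodified baseline survival.

    ``survival_u``/``cure_u`` are the woman's shared uniforms (common
    random numbers across scenarios).
    """
    h = _baseline_hazard(detection_age, stage, subtype, params)
    if efficacy.mechanism == "hazard_reduction":
        for m in assignment.modalities:
            h *= efficacy.hazard_ratio[m]
    else:
        p_not_cured = 1.0
        for m in assignment.modalities:
            p_not_cured *= 1.0 - efficacy.cure_probability[m]
        if cure_u < 1.0 - p_not_cured:
            return CURED
    if h <= 0:
        return CURED
    t = -math.log(max(1.0 - survival_u, 1e-300)) / h
    return float(detection_age + t)


def resolve_death(woman, bc_death_age: float | str | None) -> tuple[float, str]:
    """Earlier of the two death ages wins; cured or undiagnosed women die
    of other causes."""
    other = woman.other_cause_death_age
    if bc_death_age is None or bc_death_age == CURED or bc_death_age >= other:
        return float(other), "other"
    return float(bc_death_age), "breast_cancer"


def treat_and_survive(
    woman,
    detection,
    subtype: str,
    params: ParameterSet,
    efficacy: EfficacySpec,
    seed: int,
    *,
    treatment_on: bool = True,
) -> tuple[TreatmentAssignment, float | str]:
    """Assignment + survival for one diagnosed woman, with all draws on
    scenario-stable per-woman streams."""
    year = woman.birth_year + detection.age
    if treatment_on:
        assignment = assign_treatment(
            detection.age, year, detection.stage, subtype, params, substream(seed, woman.id, "treat")
        )
    else:
        assignment = TreatmentAssignment(frozenset(), detection.age, year)
    bc_death = sample_bc_survival(
        detection.age,
        detection.stage,
        subtype,
        assignment,
        efficacy,
        params,
        survival_u=substream(seed, woman.id, "survival").random(),
        cure_u=substream(seed, woman.id, "cure").random(),
    )
    return assignment, bc_death
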