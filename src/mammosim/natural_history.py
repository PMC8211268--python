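"""Counterfactual tumor natural histories in the absence of screening.

Each woman's tumor history — whether a tumor ever arises, its latent
symptomatic (clinical) detection age, subtype, preclinical sojourn, and
stage progression — is generated once from streams keyed only by
(seed, woman, purpose).  Screening and treatment scenarios read it but
never touch its streams, so the history is bitwise identical across
scenarios.  The latent clinical-detection age is generated even when it
falls after other-cause death: that latent date is what classifies a
screen-detected case as overdiagnosed.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .constants import (
    MAX_AGE,
    SOJOURN_AGE_BANDS,
    STAGES,
    STAGE_AGE_BANDS,
    SUBTYPE_AGE_BANDS,
    age_band,
)
from .fixtures import ParameterSet, background_rate
from .rng import substream

__all__ = [
    "TumorHistory",
    "sample_clinical_incidence",
    "assign_subtype",
    "sample_sojourn",
    "assign_stage",
    "stage_from_uniform",
    "progress_stage_dwell",
    "stage_at",
    "gompertz_diameter",
    "gompertz_crossing_time",
    "build_tumor_history",
    "make_stage_fn",
]


@dataclasses.dataclass
class TumorHistory:
    has_tumor: bool
    clinical_detection_age: float  # latent symptomatic age absent screening
    sojourn_years: float
    preclinical_onset_age: float
    subtype: str
    stage_at_clinical: str | None = None
    dwell_entry_ages: dict | None = None  # stage -> entry age (dwell variant)
    growth_params: dict | None = None


def _base_rates(birth_year: int, params: ParameterSet) -> np.ndarray:
    """Per-100k annual clinical-incidence rates over ages 0..119 for one
    birth cohort (cached per ParameterSet: shared by the whole cohort)."""
    src, cache = getattr(params, "_rate_cache", (None, None))
    if src is not params.incidence_table:
        cache = {}
        params._rate_cache = (params.incidence_table, cache)
    key = (params.incidence_mode, birth_year)
    if key in cache:
        return cache[key]
    ages = np.arange(120)
    if params.incidence_mode == "table":
        tbl = params.incidence_table
        vals = tbl.to_numpy(dtype=float)
        years = tbl.columns.to_numpy()
        aidx = np.clip(ages, tbl.index[0], tbl.index[-1]) - tbl.index[0]
        yidx = np.clip(birth_year + ages, years[0], years[-1]) - years[0]
        rates = vals[aidx, yidx]
    elif params.incidence_mode == "linear_1975":
        yrs = np.maximum(birth_year + ages, 1975)
        rates = params.linear_params["baseline"] + params.linear_params["annual_increment"] * (yrs - 1975)
        if params.age_profile is not None:
            ap = params.age_profile
            aidx = np.clip(ages, ap.index[0], ap.index[-1])
            rates = rates * ap.reindex(aidx).to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown incidence mode {params.incidence_mode!r}")
    if np.isnan(rates).any():
        raise ValueError("incidence hazard table has gaps (NaN rates)")
    cache[key] = rates
    return rates


def _hazard_per_year(woman, params: ParameterSet) -> np.ndarray:
    """Annual clinical-incidence hazard over ages 0..119 for one woman."""
    rates = _base_rates(woman.birth_year, params)
    mult = woman.risk_multiplier * float(params.density_risk_multiplier[woman.density_at[40]])
    return rates / 1e5 * mult


def sample_clinical_incidence(woman, params: ParameterSet, stream) -> float | None:
    """Latent age of symptomatic detection absent screening, or None.

    Inverse-transform draw against the cumulative hazard (piecewise
    constant on single-year age bins), scaled by the woman's risk
    multiplier and optional density multiplier.  Deliberately not
    truncated at other-cause death.
    """
    h = _hazard_per_year(woman, params)
    cum = np.concatenate([[0.0], np.cumsum(h)])
    e = stream.exponential()
    if e >= cum[-1]:
        return None
    k = int(np.searchsorted(cum, e, side="right") - 1)
    age = k + (e - cum[k]) / h[k]
    return float(age) if age < MAX_AGE else None


def assign_subtype(age_at_clinical: float, params: ParameterSet, stream) -> str:
    band = age_band(age_at_clinical, SUBTYPE_AGE_BANDS)
    probs = params.subtype_probs.loc[band].to_numpy(dtype=float)
    return str(params.subtype_probs.columns[int(stream.choice(len(probs), p=probs))])


def sample_sojourn(subtype: str, age_at_clinical: float, params: ParameterSet, stream) -> tuple[float, float]:
    """Return (sojourn_years, preclinical_onset_age).

    Exponential with the stratum mean by default; ``fixed`` mode returns
    the mean itself.  Onset is floored at age 0 (sojourn truncated).
    """
    band = age_band(age_at_clinical, SOJOURN_AGE_BANDS)
    mean = float(params.sojourn_means.loc[band, subtype])
    if mean <= 0:
        raise ValueError(f"sojourn mean must be positive for stratum ({band}, {subtype})")
    sojourn = mean if params.sojourn_mode == "fixed" else float(stream.exponential(mean))
    onset = max(age_at_clinical - sojourn, 0.0)
    return age_at_clinical - onset, onset


def _stage_dist(mode: str, age: float, params: ParameterSet) -> np.ndarray:
    band = age_band(age, STAGE_AGE_BANDS)
    src, cache = getattr(params, "_stage_cache", (None, None))
    if src is not params.stage_dists:
        cache = {
            (r.mode, r.age_group): np.array([getattr(r, st) for st in STAGES], dtype=float)
            for r in params.stage_dists.itertuples()
        }
        params._stage_cache = (params.stage_dists, cache)
    if (mode, band) not in cache:
        raise KeyError(f"stage_dists: no stratum for mode {mode!r}, age group {band!r}")
    return cache[(mode, band)]


def stage_from_uniform(mode: str, age: float, params: ParameterSet, u: float) -> str:
    """Invert the (mode, age-group) stage distribution at quantile ``u``.

    Using one shared uniform per woman makes stages comonotone across
    detection modes: an earlier detection can only shift stage earlier.
    """
    probs = _stage_dist(mode, age, params)
    return STAGES[int(np.searchsorted(np.cumsum(probs), u, side="right"))]


def assign_stage(mode: str, age: float, params: ParameterSet, stream) -> str:
    return stage_from_uniform(mode, age, params, stream.random())


def progress_stage_dwell(preclinical_onset_age: float, dwell_means: dict, stream) -> dict:
    """Sample stage-entry ages: local at onset, then exponential dwells
    into regional and distant.  Entry ages are strictly increasing."""
    for st, mean in dwell_means.items():
        if mean <= 0:
            raise ValueError(f"dwell mean for {st!r} must be positive")
    t_local = preclinical_onset_age
    t_regional = t_local + float(stream.exponential(dwell_means["local"]))
    t_distant = t_regional + float(stream.exponential(dwell_means["regional"]))
    return {"local": t_local, "regional": t_regional, "distant": t_distant}


def stage_at(t: float, entry_ages: dict) -> str:
    if t < entry_ages["local"]:
        raise ValueError(f"stage queried at {t} before onset {entry_ages['local']}")
    if t < entry_ages["regional"]:
        return "local"
    if t < entry_ages["distant"]:
        return "regional"
    return "distant"


# ---------------------------------------------------------------------------
# Gompertz-with-lag growth (growth variant; stand-in parameterization)


def gompertz_diameter(t: float, gp: dict) -> float:
    """d(t) = dmax * (d0/dmax) ** exp(-rate * max(0, t - lag)), t years from onset."""
    d0, dmax, rate, lag = gp["d0_mm"], gp["dmax_mm"], gp["rate_per_year"], gp["lag_years"]
    if not (0 < d0 < dmax) or rate <= 0:
        raise ValueError("invalid growth parameters")
    s = max(0.0, t - lag)
    return float(dmax * (d0 / dmax) ** math.exp(-rate * s))


def gompertz_crossing_time(gp: dict, threshold_mm: float) -> float:
    """Closed-form first time d(t) reaches ``threshold_mm`` (from onset)."""
    d0, dmax, rate, lag = gp["d0_mm"], gp["dmax_mm"], gp["rate_per_year"], gp["lag_years"]
    if threshold_mm <= d0:
        return 0.0
    if threshold_mm >= dmax:
        return math.inf
    return lag + math.log(math.log(dmax / d0) / math.log(dmax / threshold_mm)) / rate


def _growth_stage(diameter_mm: float) -> str:
    if diameter_mm < 20.0:
        return "local"
    if diameter_mm < 45.0:
        return "regional"
    return "distant"


# ---------------------------------------------------------------------------
# assembly


def build_tumor_history(woman, params: ParameterSet, seed: int) -> TumorHistory | None:
    """Generate one woman's full latent tumor history (or None).

    All draws come from substreams keyed by (seed, woman.id, purpose);
    nothing here depends on any scenario.
    """
    age = sample_clinical_incidence(woman, params, substream(seed, woman.id, "incidence"))
    if age is None:
        return None
    subtype = assign_subtype(age, params, substream(seed, woman.id, "subtype"))

    if params.stage_mechanism == "growth":
        gp = params.growth_params
        t_screen = gompertz_crossing_time(gp, gp["screen_threshold_mm"])
        t_clin = gompertz_crossing_time(gp, gp["clinical_threshold_mm"])
        onset = max(age - (t_clin - t_screen), 0.0)
        sojourn = age - onset
        growth = dict(gp)
    else:
        sojourn, onset = sample_sojourn(subtype, age, params, substream(seed, woman.id, "sojourn"))
        growth = None

    dwell = None
    if params.stage_mechanism == "dwell":
        dwell = progress_stage_dwell(onset, params.dwell_means, substream(seed, woman.id, "dwell"))

    tumor = TumorHistory(
        has_tumor=True,
        clinical_detection_age=age,
        sojourn_years=sojourn,
        preclinical_onset_age=onset,
        subtype=subtype,
        dwell_entry_ages=dwell,
        growth_params=growth,
    )
    tumor.stage_at_clinical = make_stage_fn(woman, tumor, params, seed)("clinical", age)
    return tumor


def make_stage_fn(woman, tumor: TumorHistory, params: ParameterSet, seed: int):
    """Return ``stage_fn(mode, age) -> stage`` under the active mechanism."""
    if params.stage_mechanism == "table":
        u = substream(seed, woman.id, "stage").random()

        def stage_fn(mode, age):
            return stage_from_uniform(mode, age, params, u)

    elif params.stage_mechanism == "dwell":

        def stage_fn(mode, age):
            return stage_at(age, tumor.dwell_entry_ages)

    elif params.stage_mechanism == "growth":
        gp = tumor.growth_params or params.growth_params
        t_screen = gompertz_crossing_time(gp, gp["screen_threshold_mm"])

        def stage_fn(mode, age):
            t = age - tumor.preclinical_onset_age + t_screen
            return _growth_stage(gompertz_diameter(t, gp))

    else:
        raise ValueError(f"unknown stage mechanism {params.stage_mechanism!r}")
    return stage_fn
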