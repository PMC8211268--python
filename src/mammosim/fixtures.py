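"""Parameter tables: synthetic defaults, file I/O, and validation.

Every table the simulator consumes lives in a :class:`ParameterSet`.  The
*shapes* (stratification by age group, density, subtype, stage, interval,
calendar period) mirror the input catalogue of multi-group breast-cancer
policy models; the default *values* are synthetic and deliberately
uncalibrated — plausible orders of magnitude chosen so that every
downstream behaviour (stage shift under screening, treatment benefit,
density effects on test performance) is exercised, nothing more.

Storage format: one YAML master config holding scalar settings plus
references to per-table CSV files (header row = stratum keys + values).
Rates are stored per 100,000 woman-years; probabilities as decimals.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import (
    DENSITY_AGES,
    DENSITY_CATS,
    MODALITIES,
    PERF_AGE_BANDS,
    SOJOURN_AGE_BANDS,
    STAGES,
    STAGE_AGE_BANDS,
    STD_AGE_BANDS,
    SUBTYPES,
    SUBTYPE_AGE_BANDS,
    SURV_AGE_BANDS,
    TREAT_AGE_BANDS,
    TREATMENT_PERIODS,
)
from .rng import substream
from .screening import PerformanceTable

__all__ = [
    "ParameterSet",
    "ParameterError",
    "make_default_parameters",
    "load_parameters",
    "write_parameters",
    "validate_parameters",
    "background_rate",
    "parameters_equal",
]

VARIANTS = ("hazard_reduction", "cure_fraction")

_DIST_TOL = 1e-9


class ParameterError(ValueError):
    """A parameter table is missing, malformed, or violates an invariant."""


@dataclasses.dataclass
class ParameterSet:
    """All input tables for one simulator run.

    Attributes
    ----------
    life_table : DataFrame
        Annual other-cause death probability; index = age 0..119,
        one column per birth cohort (int year).  Terminal row must be 1.
    incidence_table : DataFrame
        Clinical-detection rate per 100,000 woman-years; index = age,
        columns = calendar year.  Used when ``incidence_mode == "table"``.
    incidence_mode : str
        ``"table"`` or ``"linear_1975"``.
    linear_params : dict
        ``baseline`` (per 100,000 in 1975), ``relative_increase``
        (fraction/year), ``annual_increment`` (per 100,000/year,
        = baseline * relative_increase).
    age_profile : Series or None
        Optional multiplicative age profile for the linear mode
        (index = age, mean 1 recommended).  None = age-independent.
    subtype_probs : DataFrame
        P(subtype) by age group (index) x subtype (columns); rows sum to 1.
    sojourn_means : DataFrame
        Mean preclinical sojourn (years) by age decade (index) x subtype.
    sojourn_mode : str
        ``"exponential"`` (default) or ``"fixed"``.
    density_prevalence : DataFrame
        P(BI-RADS category) at ages 40/50/65 (index) x category (columns).
    performance : PerformanceTable
        Mammography sensitivity/specificity by age group x density x
        interval class x first-vs-subsequent.
    stage_dists : DataFrame
        Long table: mode, age_group, then one column per stage; each row
        a distribution over stages.
    stage_mechanism : str
        ``"table"``, ``"dwell"``, or ``"growth"``.
    dwell_means : dict
        Mean years in local and regional stage (dwell variant).
    growth_params : dict
        Gompertz growth with lag (growth variant): d0_mm, dmax_mm,
        rate_per_year, lag_years, screen_threshold_mm,
        clinical_threshold_mm.
    survival_baseline : DataFrame
        Long table: age_group, stage, subtype, hazard (annual
        breast-cancer death hazard absent treatment).
    dissemination : DataFrame
        Long table: modality, period, age_group, stage, subtype,
        probability of receipt.
    efficacy : DataFrame
        Index = modality; columns hazard_ratio, cure_probability.
    mechanism : str
        ``"hazard_reduction"`` or ``"cure_fraction"``.
    biopsy_prob : float
        P(benign biopsy | false-positive screen).
    standard_population : Series
        Direct-standardization weights by age group; sums to 1.
    density_risk_multiplier : Series
        Optional incidence multiplier per density category (default 1).
    dcis_sensitivity : float
        Screening sensitivity for preclinical DCIS lesions.
    """

    life_table: pd.DataFrame
    incidence_table: pd.DataFrame
    incidence_mode: str
    linear_params: dict
    age_profile: pd.Series | None
    subtype_probs: pd.DataFrame
    sojourn_means: pd.DataFrame
    sojourn_mode: str
    density_prevalence: pd.DataFrame
    performance: PerformanceTable
    stage_dists: pd.DataFrame
    stage_mechanism: str
    dwell_means: dict
    growth_params: dict
    survival_baseline: pd.DataFrame
    dissemination: pd.DataFrame
    efficacy: pd.DataFrame
    mechanism: str
    biopsy_prob: float
    standard_population: pd.Series
    density_risk_multiplier: pd.Series
    dcis_sensitivity: float


# ---------------------------------------------------------------------------
# synthetic defaults


def _default_life_table(cohorts=(1970,)) -> pd.DataFrame:
    ages = np.arange(120)
    # Gompertz-Makeham shape; forced certain death in the last bin
    q = 1.0 - np.exp(-(5e-4 + 3.2e-5 * np.exp(0.093 * ages)))
    q = np.clip(q, 0.0, 1.0)
    q[-1] = 1.0
    return pd.DataFrame({int(c): q for c in cohorts}, index=pd.Index(ages, name="age"))


def _default_incidence_table(rng) -> pd.DataFrame:
    ages = np.arange(120)
    years = np.arange(1975, 2021)
    profile = np.zeros(120)
    ramp = (ages >= 25) & (ages < 60)
    profile[ramp] = (ages[ramp] - 25) / 35.0
    profile[ages >= 60] = 1.0
    peak = 250.0 * (1 + rng.uniform(-0.02, 0.02))
    year_factor = 1.0 + 0.004 * (years - 1975)
    table = np.outer(profile * peak, year_factor)
    return pd.DataFrame(table, index=pd.Index(ages, name="age"), columns=pd.Index(years, name="year"))


def _default_performance(rng) -> PerformanceTable:
    rows = []
    sens_age = {"25-39": 0.72, "40-49": 0.78, "50-64": 0.84, "65+": 0.87}
    spec_age = {"25-39": 0.92, "40-49": 0.93, "50-64": 0.94, "65+": 0.95}
    dens_sens = {"a": 0.06, "b": 0.02, "c": -0.04, "d": -0.10}
    dens_spec = {"a": 0.02, "b": 0.01, "c": -0.01, "d": -0.03}
    # longer gaps leave larger tumours at the screen -> slightly higher sensitivity
    int_sens = {"annual": 0.0, "biennial": 0.015, "triennial": 0.03}
    for _, _, ag in PERF_AGE_BANDS:
        for d in DENSITY_CATS:
            for ic in ("annual", "biennial", "triennial"):
                for first in ("first", "subsequent"):
                    sens = sens_age[ag] + dens_sens[d] + int_sens[ic] + (0.02 if first == "first" else 0.0)
                    spec = spec_age[ag] + dens_spec[d] + (-0.03 if first == "first" else 0.0)
                    sens += rng.uniform(-0.004, 0.004)
                    spec += rng.uniform(-0.004, 0.004)
                    rows.append(
                        {
                            "age_group": ag,
                            "density": d,
                            "interval": ic,
                            "first": first,
                            "sensitivity": round(min(max(sens, 0.5), 0.99), 4),
                            "specificity": round(min(max(spec, 0.75), 0.995), 4),
                        }
                    )
    return PerformanceTable(pd.DataFrame(rows))


def _default_density_prevalence() -> pd.DataFrame:
    # built forward from stay probabilities so the triangular solve is feasible
    p40 = np.array([0.10, 0.40, 0.40, 0.10])
    stay1 = np.array([1.0, 0.88, 0.90, 0.85])
    stay2 = np.array([1.0, 0.90, 0.92, 0.90])

    def step(p, stay):
        out = p * stay
        out[:-1] += p[1:] * (1 - stay[1:])
        return out

    p50 = step(p40, stay1)
    p65 = step(p50, stay2)
    return pd.DataFrame(
        [p40, p50, p65], index=pd.Index(list(DENSITY_AGES), name="age"), columns=pd.Index(DENSITY_CATS, name="density")
    )


def _default_stage_dists() -> pd.DataFrame:
    rows = []
    screen = {"<50": (0.72, 0.23, 0.05), "50-64": (0.76, 0.20, 0.04), "65+": (0.78, 0.18, 0.04)}
    clinical = {"<50": (0.42, 0.43, 0.15), "50-64": (0.46, 0.41, 0.13), "65+": (0.48, 0.39, 0.13)}
    for mode, table in (("screen", screen), ("clinical", clinical)):
        for _, _, ag in STAGE_AGE_BANDS:
            local, regional, distant = table[ag]
            rows.append({"mode": mode, "age_group": ag, "local": local, "regional": regional, "distant": distant})
    return pd.DataFrame(rows)


def _default_survival_baseline(rng) -> pd.DataFrame:
    stage_base = {"local": 0.010, "regional": 0.045, "distant": 0.250}
    subtype_mult = {"ER+/HER2-": 0.80, "ER+/HER2+": 1.00, "ER-/HER2+": 1.30, "ER-/HER2-": 1.55}
    age_mult = {"<40": 1.20, "40-49": 1.00, "50-59": 0.95, "60-69": 1.00, "70+": 1.10}
    rows = []
    for _, _, ag in SURV_AGE_BANDS:
        for st in STAGES:
            for sub in SUBTYPES:
                h = stage_base[st] * subtype_mult[sub] * age_mult[ag] * (1 + rng.uniform(-0.02, 0.02))
                rows.append({"age_group": ag, "stage": st, "subtype": sub, "hazard": round(h, 6)})
    return pd.DataFrame(rows)


def _default_dissemination() -> pd.DataFrame:
    base = {
        "chemotherapy": {"1975-1994": 0.20, "1995-2012": 0.50, "2013+": 0.65},
        "endocrine": {"1975-1994": 0.30, "1995-2012": 0.60, "2013+": 0.80},
        "trastuzumab": {"1975-1994": 0.00, "1995-2012": 0.40, "2013+": 0.75},
    }
    stage_f = {"local": 0.85, "regional": 1.05, "distant": 1.10}
    age_f = {"<50": 1.05, "50-69": 1.00, "70+": 0.70}
    rows = []
    for m in MODALITIES:
        for _, _, per in TREATMENT_PERIODS:
            for _, _, ag in TREAT_AGE_BANDS:
                for st in STAGES:
                    for sub in SUBTYPES:
                        p = min(max(base[m][per] * stage_f[st] * age_f[ag], 0.0), 1.0)
                        rows.append(
                            {
                                "modality": m,
                                "period": per,
                                "age_group": ag,
                                "stage": st,
                                "subtype": sub,
                                "probability": round(p, 6),
                            }
                        )
    return pd.DataFrame(rows)


def make_default_parameters(variant: str = "hazard_reduction", seed: int = 0) -> ParameterSet:
    """Build a fully populated synthetic :class:`ParameterSet`.

    ``variant`` selects the treatment-efficacy mechanism: hazard ratios on
    the breast-cancer death hazard, or per-modality cure probabilities
    (hazard ratios then fixed at 1).  Deterministic given ``seed``.
    """
    if variant not in VARIANTS:
        raise ParameterError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    rng = substream(seed, "fixtures", variant)

    subtype_probs = pd.DataFrame(
        [[0.55, 0.10, 0.10, 0.25], [0.70, 0.08, 0.05, 0.17]],
        index=pd.Index([b[2] for b in SUBTYPE_AGE_BANDS], name="age_group"),
        columns=pd.Index(SUBTYPES, name="subtype"),
    )

    base_sojourn = {"ER+/HER2-": 4.0, "ER+/HER2+": 3.0, "ER-/HER2+": 2.5, "ER-/HER2-": 2.0}
    decade_scale = {"<40": 0.6, "40-49": 0.8, "50-59": 1.0, "60-69": 1.2, "70+": 1.3}
    sojourn_means = pd.DataFrame(
        {sub: [round(base_sojourn[sub] * decade_scale[b[2]], 4) for b in SOJOURN_AGE_BANDS] for sub in SUBTYPES},
        index=pd.Index([b[2] for b in SOJOURN_AGE_BANDS], name="age_group"),
    )
    sojourn_means.columns.name = "subtype"

    if variant == "hazard_reduction":
        efficacy = pd.DataFrame(
            {"hazard_ratio": [0.775, 0.71, 0.67], "cure_probability": [0.0, 0.0, 0.0]},
            index=pd.Index(MODALITIES, name="modality"),
        )
    else:
        efficacy = pd.DataFrame(
            {"hazard_ratio": [1.0, 1.0, 1.0], "cure_probability": [0.15, 0.20, 0.25]},
            index=pd.Index(MODALITIES, name="modality"),
        )

    baseline = 167.0
    rel = 0.003
    return ParameterSet(
        life_table=_default_life_table(),
        incidence_table=_default_incidence_table(rng),
        incidence_mode="table",
        linear_params={
            "baseline": baseline,
            "relative_increase": rel,
            "annual_increment": round(baseline * rel, 1),
        },
        age_profile=None,
        subtype_probs=subtype_probs,
        sojourn_means=sojourn_means,
        sojourn_mode="exponential",
        density_prevalence=_default_density_prevalence(),
        performance=_default_performance(rng),
        stage_dists=_default_stage_dists(),
        stage_mechanism="table",
        dwell_means={"local": 2.0, "regional": 1.5},
        growth_params={
            "d0_mm": 2.0,
            "dmax_mm": 128.0,
            "rate_per_year": 0.5,
            "lag_years": 0.5,
            "screen_threshold_mm": 5.0,
            "clinical_threshold_mm": 20.0,
        },
        survival_baseline=_default_survival_baseline(rng),
        dissemination=_default_dissemination(),
        efficacy=efficacy,
        mechanism=variant,
        biopsy_prob=0.5,
        standard_population=pd.Series(
            [0.70, 0.18, 0.12], index=pd.Index([b[2] for b in STD_AGE_BANDS], name="age_group"), name="weight"
        ),
        density_risk_multiplier=pd.Series(1.0, index=pd.Index(DENSITY_CATS, name="density"), name="multiplier"),
        dcis_sensitivity=0.8,
    )


# ---------------------------------------------------------------------------
# validation


def _check_dist(df: pd.DataFrame, table: str) -> None:
    vals = df.to_numpy(dtype=float)
    if (vals < -_DIST_TOL).any() or (vals > 1 + _DIST_TOL).any():
        bad = df.index[np.where((vals < -_DIST_TOL) | (vals > 1 + _DIST_TOL))[0][0]]
        raise ParameterError(f"{table}: probability outside [0,1] in stratum {bad!r}")
    sums = vals.sum(axis=1)
    off = np.where(np.abs(sums - 1.0) > 1e-9)[0]
    if off.size:
        raise ParameterError(f"{table}: distribution for stratum {df.index[off[0]]!r} sums to {sums[off[0]]:.12g}, not 1")


def validate_parameters(p: ParameterSet) -> None:
    """Raise :class:`ParameterError` naming the offending table and stratum."""
    lt = p.life_table.to_numpy(dtype=float)
    if lt.shape[0] != 120:
        raise ParameterError("life_table: must cover ages 0..119")
    if (lt < 0).any() or (lt > 1).any():
        raise ParameterError("life_table: death probabilities must lie in [0,1]")
    if not np.allclose(lt[-1], 1.0):
        raise ParameterError("life_table: terminal probability at age 119 must be 1")

    if p.incidence_mode not in ("table", "linear_1975"):
        raise ParameterError(f"incidence_mode: unknown mode {p.incidence_mode!r}")
    if (p.incidence_table.to_numpy(dtype=float) < 0).any():
        raise ParameterError("incidence_hazard: negative rate in table")
    for key in ("baseline", "relative_increase", "annual_increment"):
        if key not in p.linear_params:
            raise ParameterError(f"linear_params: missing {key!r}")
        if p.linear_params[key] < 0:
            raise ParameterError(f"linear_params: {key} is negative")

    _check_dist(p.subtype_probs, "subtype_probs")
    _check_dist(p.density_prevalence, "density_prevalence")

    sm = p.sojourn_means.to_numpy(dtype=float)
    if (sm <= 0).any():
        i, j = map(int, np.argwhere(sm <= 0)[0])
        raise ParameterError(
            f"sojourn_means: non-positive mean for stratum "
            f"({p.sojourn_means.index[i]!r}, {p.sojourn_means.columns[j]!r})"
        )
    if p.sojourn_mode not in ("exponential", "fixed"):
        raise ParameterError(f"sojourn_mode: unknown mode {p.sojourn_mode!r}")

    p.performance.validate()

    stage_cols = list(STAGES)
    _check_dist(p.stage_dists.set_index(["mode", "age_group"])[stage_cols], "stage_dists")
    if p.stage_mechanism not in ("table", "dwell", "growth"):
        raise ParameterError(f"stage_mechanism: unknown mechanism {p.stage_mechanism!r}")
    for st, mean in p.dwell_means.items():
        if mean <= 0:
            raise ParameterError(f"dwell_means: non-positive mean for stage {st!r}")
    gp = p.growth_params
    if not (0 < gp["d0_mm"] < gp["dmax_mm"]):
        raise ParameterError("growth_params: require 0 < d0_mm < dmax_mm")
    if gp["rate_per_year"] <= 0 or gp["lag_years"] < 0:
        raise ParameterError("growth_params: rate must be > 0 and lag >= 0")

    if (p.survival_baseline["hazard"] < 0).any():
        bad = p.survival_baseline.loc[p.survival_baseline["hazard"] < 0].iloc[0]
        raise ParameterError(
            f"survival_baseline: negative hazard for stratum "
            f"({bad['age_group']}, {bad['stage']}, {bad['subtype']})"
        )

    dis = p.dissemination["probability"]
    if (dis < 0).any() or (dis > 1).any():
        bad = p.dissemination.loc[(dis < 0) | (dis > 1)].iloc[0]
        raise ParameterError(
            f"dissemination: probability outside [0,1] for stratum "
            f"({bad['modality']}, {bad['period']}, {bad['age_group']}, {bad['stage']}, {bad['subtype']})"
        )

    for m in p.efficacy.index:
        hr = p.efficacy.loc[m, "hazard_ratio"]
        cp = p.efficacy.loc[m, "cure_probability"]
        if not (0 < hr <= 1):
            raise ParameterError(f"efficacy: hazard_ratio for {m!r} must lie in (0,1]")
        if not (0 <= cp <= 1):
            raise ParameterError(f"efficacy: cure_probability for {m!r} must lie in [0,1]")
    if p.mechanism not in VARIANTS:
        raise ParameterError(f"mechanism: unknown mechanism {p.mechanism!r}")

    if not (0 <= p.biopsy_prob <= 1):
        raise ParameterError("biopsy_prob: must lie in [0,1]")
    if abs(float(p.standard_population.sum()) - 1.0) > 1e-9:
        raise ParameterError("standard_population: weights must sum to 1")
    if (p.density_risk_multiplier < 0).any():
        raise ParameterError("density_risk_multiplier: must be >= 0")
    if not (0 <= p.dcis_sensitivity <= 1):
        raise ParameterError("dcis_sensitivity: must lie in [0,1]")


# ---------------------------------------------------------------------------
# background incidence


def background_rate(p: ParameterSet, age: float, year: float) -> float:
    """Clinical-detection rate per 100,000 woman-years at (age, year).

    Table mode looks up the table cell (year clamped to table coverage).
    Linear mode returns ``baseline + annual_increment * (year - 1975)``,
    age-independent unless an ``age_profile`` is supplied (multiplicative).
    """
    if p.incidence_mode == "table":
        ages = p.incidence_table.index.to_numpy()
        if not (ages[0] <= age <= ages[-1] + 1):
            raise ParameterError(f"incidence_hazard: age {age} outside table range")
        a = int(min(np.floor(age), ages[-1]))
        years = p.incidence_table.columns.to_numpy()
        y = int(min(max(np.floor(year), years[0]), years[-1]))
        return float(p.incidence_table.loc[a, y])
    if p.incidence_mode == "linear_1975":
        if year < 1975:
            raise ParameterError("incidence_hazard: linear mode undefined before 1975")
        rate = p.linear_params["baseline"] + p.linear_params["annual_increment"] * (year - 1975)
        if p.age_profile is not None:
            a = int(min(np.floor(age), p.age_profile.index[-1]))
            rate *= float(p.age_profile.loc[a])
        return float(rate)
    raise ParameterError(f"incidence_mode: unknown mode {p.incidence_mode!r}")


# ---------------------------------------------------------------------------
# file I/O

_TABLE_FILES = {
    "life_table": "life_table.csv",
    "incidence_table": "incidence.csv",
    "subtype_probs": "subtype_probs.csv",
    "sojourn_means": "sojourn_means.csv",
    "density_prevalence": "density_prevalence.csv",
    "performance": "performance.csv",
    "stage_dists": "stage_dists.csv",
    "survival_baseline": "survival_baseline.csv",
    "dissemination": "dissemination.csv",
    "efficacy": "efficacy.csv",
    "standard_population": "standard_population.csv",
    "density_risk_multiplier": "density_risk_multiplier.csv",
}


def write_parameters(p: ParameterSet, outdir) -> Path:
    """Write the CSV tables plus a ``config.yaml`` master file; return the config path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    fmt = "%.17g"  # full float64 precision so load(write(p)) == p exactly
    p.life_table.to_csv(outdir / _TABLE_FILES["life_table"], float_format=fmt)
    p.incidence_table.to_csv(outdir / _TABLE_FILES["incidence_table"], float_format=fmt)
    p.subtype_probs.to_csv(outdir / _TABLE_FILES["subtype_probs"], float_format=fmt)
    p.sojourn_means.to_csv(outdir / _TABLE_FILES["sojourn_means"], float_format=fmt)
    p.density_prevalence.to_csv(outdir / _TABLE_FILES["density_prevalence"], float_format=fmt)
    p.performance.table.to_csv(outdir / _TABLE_FILES["performance"], index=False, float_format=fmt)
    p.stage_dists.to_csv(outdir / _TABLE_FILES["stage_dists"], index=False, float_format=fmt)
    p.survival_baseline.to_csv(outdir / _TABLE_FILES["survival_baseline"], index=False, float_format=fmt)
    p.dissemination.to_csv(outdir / _TABLE_FILES["dissemination"], index=False, float_format=fmt)
    p.efficacy.to_csv(outdir / _TABLE_FILES["efficacy"], float_format=fmt)
    p.standard_population.to_csv(outdir / _TABLE_FILES["standard_population"], float_format=fmt)
    p.density_risk_multiplier.to_csv(outdir / _TABLE_FILES["density_risk_multiplier"], float_format=fmt)
    if p.age_profile is not None:
        p.age_profile.rename("multiplier").to_csv(outdir / "age_profile.csv", float_format=fmt)

    config = {
        "format": "mammosim-parameters-v1",
        "note": "Synthetic, uncalibrated default values; only the strata shapes are meaningful.",
        "tables": dict(_TABLE_FILES),
        "incidence_mode": p.incidence_mode,
        "linear_params": {k: float(v) for k, v in p.linear_params.items()},
        "age_profile": "age_profile.csv" if p.age_profile is not None else None,
        "sojourn_mode": p.sojourn_mode,
        "stage_mechanism": p.stage_mechanism,
        "dwell_means": {k: float(v) for k, v in p.dwell_means.items()},
        "growth_params": {k: float(v) for k, v in p.growth_params.items()},
        "mechanism": p.mechanism,
        "biopsy_prob": float(p.biopsy_prob),
        "dcis_sensitivity": float(p.dcis_sensitivity),
    }
    cfg_path = outdir / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return cfg_path


def load_parameters(path) -> ParameterSet:
    """Load and validate a ParameterSet from a config file (or its directory)."""
    path = Path(path)
    if path.is_dir():
        path = path / "config.yaml"
    if not path.exists():
        raise ParameterError(f"config file not found: {path}")
    config = yaml.safe_load(path.read_text())
    if not isinstance(config, dict) or "tables" not in config:
        raise ParameterError(f"{path}: not a parameter config (missing 'tables')")
    d = path.parent

    def read(name, **kw):
        f = d / config["tables"][name]
        if not f.exists():
            raise ParameterError(f"missing table {name!r} (expected file {f.name})")
        return pd.read_csv(f, float_precision="round_trip", **kw)

    life = read("life_table", index_col=0)
    life.columns = life.columns.astype(int)
    life.index.name = "age"
    inc = read("incidence_table", index_col=0)
    inc.columns = pd.Index(inc.columns.astype(int), name="year")
    inc.index.name = "age"

    age_profile = None
    if config.get("age_profile"):
        ap = pd.read_csv(d / config["age_profile"], index_col=0, float_precision="round_trip")
        age_profile = ap["multiplier"]
        age_profile.index.name = "age"

    p = ParameterSet(
        life_table=life,
        incidence_table=inc,
        incidence_mode=config["incidence_mode"],
        linear_params=dict(config["linear_params"]),
        age_profile=age_profile,
        subtype_probs=read("subtype_probs", index_col=0).rename_axis(columns="subtype"),
        sojourn_means=read("sojourn_means", index_col=0).rename_axis(columns="subtype"),
        sojourn_mode=config["sojourn_mode"],
        density_prevalence=read("density_prevalence", index_col=0).rename_axis(columns="density"),
        performance=PerformanceTable(read("performance")),
        stage_dists=read("stage_dists"),
        stage_mechanism=config["stage_mechanism"],
        dwell_means=dict(config["dwell_means"]),
        growth_params=dict(config["growth_params"]),
        survival_baseline=read("survival_baseline"),
        dissemination=read("dissemination"),
        efficacy=read("efficacy", index_col=0),
        mechanism=config["mechanism"],
        biopsy_prob=float(config["biopsy_prob"]),
        standard_population=read("standard_population", index_col=0)["weight"],
        density_risk_multiplier=read("density_risk_multiplier", index_col=0)["multiplier"],
        dcis_sensitivity=float(config["dcis_sensitivity"]),
    )
    p.subtype_probs.index.name = "age_group"
    p.sojourn_means.index.name = "age_group"
    p.density_prevalence.index.name = "age"
    p.efficacy.index.name = "modality"
    p.standard_population.index.name = "age_group"
    p.density_risk_multiplier.index.name = "density"
    validate_parameters(p)
    return p


def parameters_equal(a: ParameterSet, b: ParameterSet) -> bool:
    """Exact equality of every table and scalar (used for round-trip checks)."""
    for f in dataclasses.fields(ParameterSet):
        va, vb = getattr(a, f.name), getattr(b, f.name)
        if isinstance(va, PerformanceTable):
            if not va.table.reset_index(drop=True).equals(vb.table.reset_index(drop=True)):
                return False
        elif isinstance(va, (pd.DataFrame, pd.Series)):
            eq = va.equals(vb)
            if not eq:
                try:
                    eq = bool(np.array_equal(np.asarray(va, dtype=float), np.asarray(vb, dtype=float)))
                except (TypeError, ValueError):
                    eq = False
            if not eq:
                return False
        elif va is None or vb is None:
            if va is not vb:
                return False
        elif isinstance(va, dict):
            if {k: float(v) for k, v in va.items()} != {k: float(v) for k, v in vb.items()}:
                return False
        else:
            if va != vb:
                return False
    return True
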