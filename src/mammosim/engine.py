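"""Scenario orchestration under common random numbers.

The natural-history layer (cohort + latent tumor histories) is built
exactly once per run from streams keyed by (seed, woman, purpose) and
shared by every scenario; scenarios differ only in which screening
schedule and treatment mechanism they lay on top.  Adding or removing a
scenario therefore changes no numbers in any other scenario's output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .fixtures import ParameterSet, load_parameters, make_default_parameters
from .natural_history import build_tumor_history, make_stage_fn
from .outcomes import (
    AttributionResult,
    attribute_reduction,
    classify_overdiagnosis,
    compare_scenarios,
    mortality_rate,
    summarize_log,
)
from .population import AVERAGE_RISK, RiskProfile, build_cohort
from .rng import substream
from .screening import NO_SCREENING, ScreeningStrategy, build_schedule, first_detection
from .treatment import EfficacySpec, treat_and_survive

__all__ = ["Scenario", "RunManifest", "run_scenario", "run_scenarios", "attribution_scenarios", "ConfigError"]

LOG_COLUMNS = [
    "id",
    "birth_year",
    "other_cause_death_age",
    "has_tumor",
    "latent_clinical_age",
    "preclinical_onset_age",
    "sojourn_years",
    "subtype",
    "detection_mode",
    "detection_age",
    "stage",
    "n_screens",
    "n_false_positives",
    "n_benign_biopsies",
    "interval_cancer",
    "modalities",
    "bc_death_age",
    "death_age",
    "cause",
    "overdiagnosed",
]


class ConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class Scenario:
    label: str
    strategy: ScreeningStrategy = NO_SCREENING
    treatment_on: bool = False
    mechanism_override: str | None = None


@dataclasses.dataclass
class RunManifest:
    version: str
    seed: int
    config_hash: str
    scenario_labels: list
    n_women: int
    birth_year: int
    output_files: dict
    wall_seconds: float

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def simulate_natural_histories(women, params: ParameterSet, seed: int) -> list:
    """(woman, tumor-or-None) pairs, scenario-independent."""
    return [(w, build_tumor_history(w, params, seed)) for w in women]


def run_scenario(histories, params: ParameterSet, scenario: Scenario, seed: int) -> pd.DataFrame:
    """Apply one scenario's screening and treatment to fixed histories;
    return the tidy per-woman log."""
    efficacy = (
        EfficacySpec.from_params(params, scenario.mechanism_override)
        if scenario.treatment_on
        else EfficacySpec.null()
    )
    rows = []
    for woman, tumor in histories:
        schedule = build_schedule(scenario.strategy, woman, substream(seed, woman.id, "dissemination"))
        stage_fn = make_stage_fn(woman, tumor, params, seed) if tumor is not None else None
        det = first_detection(
            woman,
            tumor,
            schedule,
            params.performance,
            seed,
            biopsy_prob=params.biopsy_prob,
            stage_fn=stage_fn,
        )
        bc_death = None
        modalities = ""
        if det.diagnosed:
            assignment, bc_death = treat_and_survive(
                woman, det, tumor.subtype, params, efficacy, seed, treatment_on=scenario.treatment_on
            )
            modalities = "+".join(sorted(assignment.modalities))
        death_age, cause = _resolve(woman, bc_death)
        overdx = classify_overdiagnosis(
            det.mode, tumor.clinical_detection_age if tumor else None, woman.other_cause_death_age
        )
        rows.append(
            {
                "id": woman.id,
                "birth_year": woman.birth_year,
                "other_cause_death_age": woman.other_cause_death_age,
                "has_tumor": tumor is not None,
                "latent_clinical_age": tumor.clinical_detection_age if tumor else None,
                "preclinical_onset_age": tumor.preclinical_onset_age if tumor else None,
                "sojourn_years": tumor.sojourn_years if tumor else None,
                "subtype": tumor.subtype if tumor else None,
                "detection_mode": det.mode,
                "detection_age": det.age,
                "stage": det.stage,
                "n_screens": len(det.events),
                "n_false_positives": sum(e.result == "false_positive" for e in det.events),
                "n_benign_biopsies": sum(e.led_to_biopsy for e in det.events),
                "interval_cancer": det.interval_cancer,
                "modalities": modalities,
                "bc_death_age": bc_death if isinstance(bc_death, float) else None,
                "death_age": death_age,
                "cause": cause,
                "overdiagnosed": overdx,
            }
        )
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def _resolve(woman, bc_death):
    from .treatment import resolve_death

    return resolve_death(woman, bc_death)


# ---------------------------------------------------------------------------
# config-driven runs


def _parse_strategy(spec) -> ScreeningStrategy:
    if spec is None:
        return NO_SCREENING
    segments = tuple(
        (float(s[0]), float(s[1]), None if s[2] is None else float(s[2])) for s in spec["segments"]
    )
    return ScreeningStrategy(
        label=spec.get("label", "screening"),
        segments=segments,
        dissemination=spec.get("dissemination", {"mode": "full"}),
    )


def parse_config(config: dict) -> tuple[dict, list[Scenario], str | None]:
    """Validate the run config up front; all errors surface before any
    simulation starts."""
    if "cohort" not in config or "scenarios" not in config:
        raise ConfigError("config must define 'cohort' and 'scenarios'")
    cohort = config["cohort"]
    for key in ("n", "birth_year"):
        if key not in cohort:
            raise ConfigError(f"cohort: missing {key!r}")
    if int(cohort["n"]) < 1:
        raise ConfigError("cohort: n must be >= 1")
    scenarios = []
    labels = set()
    for spec in config["scenarios"]:
        label = spec.get("label")
        if not label:
            raise ConfigError("every scenario needs a label")
        if label in labels:
            raise ConfigError(f"duplicate scenario label {label!r}")
        labels.add(label)
        scenarios.append(
            Scenario(
                label=label,
                strategy=_parse_strategy(spec.get("screening")),
                treatment_on=bool(spec.get("treatment", False)),
                mechanism_override=spec.get("mechanism"),
            )
        )
    comparator = config.get("comparator")
    if comparator is not None and comparator not in labels:
        raise ConfigError(f"comparator {comparator!r} is not a scenario label")
    return cohort, scenarios, comparator


def _load_params(config: dict, base_dir: Path | None) -> ParameterSet:
    spec = config.get("parameters", {"variant": "hazard_reduction"})
    if "path" in spec:
        path = Path(spec["path"])
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        return load_parameters(path)
    return make_default_parameters(spec.get("variant", "hazard_reduction"), int(spec.get("seed", 0)))


def run_scenarios(config: dict, seed: int, outdir=None, base_dir=None) -> dict:
    """Run every scenario in the config on one shared cohort.

    Returns {"logs": {label: DataFrame}, "results": [ScenarioResult],
    "manifest": RunManifest}; writes CSVs and a manifest when ``outdir``
    is given.
    """
    t0 = time.time()
    cohort_spec, scenarios, comparator = parse_config(config)
    params = _load_params(config, Path(base_dir) if base_dir else None)

    prof_spec = cohort_spec.get("profile", {})
    profile = RiskProfile(
        label=prof_spec.get("label", AVERAGE_RISK.label),
        risk_multiplier=float(prof_spec.get("risk_multiplier", 1.0)),
        other_cause_hazard_multiplier=float(prof_spec.get("other_cause_hazard_multiplier", 1.0)),
    )
    n = int(cohort_spec["n"])
    birth_year = int(cohort_spec["birth_year"])
    women = build_cohort(n, birth_year, profile, params, seed)
    histories = simulate_natural_histories(women, params, seed)

    logs = {}
    results = []
    for sc in scenarios:
        log = run_scenario(histories, params, sc, seed)
        logs[sc.label] = log
        results.append(summarize_log(log, sc.label))
    if comparator is not None:
        for res in results:
            if res.label == comparator:
                continue
            deltas = compare_scenarios(logs[res.label], logs[comparator])
            res.deaths_averted = deltas["deaths_averted"]
            res.life_years_gained = deltas["life_years_gained"]
            res.comparator = comparator

    output_files = {}
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "logs").mkdir(parents=True, exist_ok=True)
        for label, log in logs.items():
            f = outdir / "logs" / f"{label}.csv"
            log.to_csv(f, index=False)
            output_files[label] = str(f)
        tidy = pd.DataFrame([r.as_dict() for r in results])
        tidy.to_csv(outdir / "results.csv", index=False)
        output_files["results"] = str(outdir / "results.csv")

    manifest = RunManifest(
        version=__version__,
        seed=int(seed),
        config_hash=hashlib.sha256(yaml.safe_dump(config, sort_keys=True).encode()).hexdigest(),
        scenario_labels=[sc.label for sc in scenarios],
        n_women=n,
        birth_year=birth_year,
        output_files=output_files,
        wall_seconds=round(time.time() - t0, 3),
    )
    if outdir is not None:
        manifest.write(Path(outdir) / "manifest.json")
    return {"logs": logs, "results": results, "manifest": manifest, "params": params}


def attribution_scenarios(strategy: ScreeningStrategy) -> list[Scenario]:
    """The four paired scenarios needed for screening-vs-treatment
    mortality attribution."""
    return [
        Scenario("none", NO_SCREENING, False),
        Scenario("screen_only", strategy, False),
        Scenario("treat_only", NO_SCREENING, True),
        Scenario("both", strategy, True),
    ]


def attribute_from_logs(logs: dict, weights=None, method: str = "shapley") -> AttributionResult:
    """Shapley (or sequential) attribution from the four standard logs."""
    needed = ("none", "screen_only", "treat_only", "both")
    missing = [k for k in needed if k not in logs]
    if missing:
        raise ConfigError(f"attribution needs scenarios {needed}; missing {missing}")
    rates = {k: mortality_rate(logs[k], weights) for k in needed}
    return attribute_reduction(
        rates["none"], rates["screen_only"], rates["treat_only"], rates["both"], method=method
    )
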