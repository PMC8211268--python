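"""DCIS multistate natural history and overdiagnosis estimation.

States: undetectable lesion -> preclinical screen-detectable DCIS ->
{clinical DCIS, invasive cancer, regression to no-cancer}.  Only a
configurable fraction of undetectable lesions ever progress to the
preclinical state; exits from the preclinical state compete as
independent exponentials.  Every history carries its *latent* exit
(beyond other-cause death if need be) so the counterfactual
overdiagnosis definition — a screen-detected lesion that would never
have surfaced clinically in the woman's remaining lifetime — is
computable per lesion.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .constants import MAX_AGE
from .rng import substream

__all__ = [
    "DcisParameters",
    "DcisHistory",
    "default_dcis_parameters",
    "simulate_dcis_history",
    "screen_detect_dcis",
    "estimate_dcis_metrics",
]

PAPER_PROGRESSION_FRACTIONS = (0.3, 0.5, 0.8)

EXIT_TYPES = ("clinical_dcis", "invasive", "regressed", "censored_by_death")


@dataclasses.dataclass(frozen=True)
class DcisParameters:
    """Rates are per year.  ``rate_regress = 0`` prohibits regression.

    ``onset_hazard`` is an array of per-year lesion-onset rates over ages
    0..119 (synthetic default; the source models calibrate this)."""

    progression_fraction: float
    rate_to_clinical: float
    rate_to_invasive: float
    rate_regress: float
    onset_hazard: np.ndarray
    mean_latency_years: float = 1.0  # undetectable -> preclinical, given progression

    def __post_init__(self):
        if not (0 <= self.progression_fraction <= 1):
            raise ValueError("progression_fraction must lie in [0,1]")
        for name in ("rate_to_clinical", "rate_to_invasive", "rate_regress"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mean_latency_years <= 0:
            raise ValueError("mean_latency_years must be positive")

    @property
    def total_exit_rate(self) -> float:
        return self.rate_to_clinical + self.rate_to_invasive + self.rate_regress


def default_dcis_parameters(
    progression_fraction: float = 0.5, regression: bool = True
) -> DcisParameters:
    """Synthetic default parameterization (onset ramps over ages 30-70)."""
    ages = np.arange(120)
    onset = np.zeros(120)
    ramp = (ages >= 30) & (ages < 70)
    onset[ramp] = 30e-5 * (ages[ramp] - 30) / 40.0
    onset[ages >= 70] = 30e-5
    return DcisParameters(
        progression_fraction=progression_fraction,
        rate_to_clinical=0.15,
        rate_to_invasive=0.30,
        rate_regress=0.10 if regression else 0.0,
        onset_hazard=onset,
    )


@dataclasses.dataclass
class DcisHistory:
    """One lesion's path.  ``exit_type``/``exit_age`` are censored at
    other-cause death; the ``latent_*`` fields carry the counterfactual
    exit used by the overdiagnosis classifier."""

    onset_age: float
    preclinical_entry_age: float | None
    exit_age: float | None
    exit_type: str | None
    latent_exit_age: float | None = None
    latent_exit_type: str | None = None


def _sample_onset(onset_hazard: np.ndarray, stream) -> float | None:
    h = np.asarray(onset_hazard, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(h)])
    e = stream.exponential()
    if e >= cum[-1]:
        return None
    k = int(np.searchsorted(cum, e, side="right") - 1)
    return float(k + (e - cum[k]) / h[k])


def simulate_dcis_history(woman, params: DcisParameters, stream) -> DcisHistory | None:
    """Simulate one woman's lesion history, or None if no lesion onsets
    before other-cause death.

    Lesions failing the progression Bernoulli never enter the preclinical
    state.  Exits from the preclinical state are competing exponentials;
    a lesion whose latent exit falls after other-cause death is recorded
    as censored_by_death (the latent exit is kept alongside).
    """
    onset = _sample_onset(params.onset_hazard, stream)
    if onset is None or onset >= woman.other_cause_death_age:
        return None
    if stream.random() >= params.progression_fraction:
        return DcisHistory(onset_age=onset, preclinical_entry_age=None, exit_age=None, exit_type=None)

    entry = onset + float(stream.exponential(params.mean_latency_years))
    total = params.total_exit_rate
    if total <= 0:
        raise ValueError("preclinical DCIS state is absorbing: all exit rates are zero")
    wait = float(stream.exponential(1.0 / total))
    rates = np.array([params.rate_to_clinical, params.rate_to_invasive, params.rate_regress])
    latent_type = ("clinical_dcis", "invasive", "regressed")[int(stream.choice(3, p=rates / total))]
    latent_age = entry + wait

    if entry >= woman.other_cause_death_age:
        # dies before the lesion ever becomes screen-detectable
        return DcisHistory(
            onset_age=onset,
            preclinical_entry_age=None,
            exit_age=woman.other_cause_death_age,
            exit_type="censored_by_death",
            latent_exit_age=latent_age,
            latent_exit_type=latent_type,
        )
    if latent_age > woman.other_cause_death_age:
        exit_age, exit_type = woman.other_cause_death_age, "censored_by_death"
    else:
        exit_age, exit_type = latent_age, latent_type
    return DcisHistory(
        onset_age=onset,
        preclinical_entry_age=entry,
        exit_age=min(exit_age, MAX_AGE),
        exit_type=exit_type,
        latent_exit_age=latent_age,
        latent_exit_type=latent_type,
    )


def screen_detect_dcis(history: DcisHistory, woman, screen_ages, sensitivity: float, stream) -> float | None:
    """Age of first screen detection of the preclinical lesion, or None.

    Detection can happen at screens falling in [preclinical entry, latent
    exit) before other-cause death; progression is halted at detection
    (the lesion is treated as fully excised)."""
    if history is None or history.preclinical_entry_age is None:
        return None
    stop = min(history.latent_exit_age, woman.other_cause_death_age)
    for a in screen_ages:
        if history.preclinical_entry_age <= a < stop and stream.random() < sensitivity:
            return float(a)
    return None


def estimate_dcis_metrics(records) -> dict:
    """Aggregate (history, woman, detection_age) triples.

    Returns mean latent preclinical sojourn among lesions that entered the
    preclinical state, and the overdiagnosis fraction among screen-detected
    lesions: detected lesions whose latent exit is regression, or whose
    latent clinical/invasive surfacing falls after other-cause death.
    The fraction is None when nothing was screen detected.
    """
    sojourns = []
    n_detected = 0
    n_overdx = 0
    for history, woman, det_age in records:
        if history is None or history.preclinical_entry_age is None:
            continue
        sojourns.append(history.latent_exit_age - history.preclinical_entry_age)
        if det_age is None:
            continue
        n_detected += 1
        if history.latent_exit_type == "regressed" or history.latent_exit_age > woman.other_cause_death_age:
            n_overdx += 1
    return {
        "mean_preclinical_sojourn": float(np.mean(sojourns)) if sojourns else None,
        "n_screen_detected": n_detected,
        "overdiagnosis_fraction": (n_overdx / n_detected) if n_detected else None,
    }


def run_dcis_cohort(
    women,
    params: DcisParameters,
    screen_ages,
    sensitivity: float,
    seed: int,
) -> dict:
    """Convenience wrapper: simulate lesions plus screening for a cohort
    and return the estimated metrics (used by the CLI sweep)."""
    records = []
    for w in women:
        hist = simulate_dcis_history(w, params, substream(seed, w.id, "dcis"))
        det = screen_detect_dcis(hist, w, screen_ages, sensitivity, substream(seed, w.id, "dcis_screen"))
        records.append((hist, w, det))
    return estimate_dcis_metrics(records)
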