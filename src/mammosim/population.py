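"""Person-level trajectories: birth, other-cause death, breast density.

Everything sampled here is scenario-invariant: the same woman carries the
same other-cause death age and density trajectory through every screening
or treatment scenario, which is what makes per-woman counterfactual
comparisons meaningful.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .constants import DENSITY_CATS, MAX_AGE
from .rng import substream

__all__ = [
    "Woman",
    "RiskProfile",
    "DensityTransitions",
    "DensityTransitionError",
    "sample_other_cause_death",
    "solve_density_transitions",
    "assign_density_trajectory",
    "build_cohort",
    "AVERAGE_RISK",
]


@dataclasses.dataclass(frozen=True)
class RiskProfile:
    """Collapses person-level risk modifiers (family history, polygenic
    score, prior chest radiation, Down syndrome, ...) into one breast-cancer
    incidence multiplier and one other-cause mortality hazard multiplier."""

    label: str
    risk_multiplier: float = 1.0
    other_cause_hazard_multiplier: float = 1.0
    description: str = ""

    def __post_init__(self):
        if self.risk_multiplier < 0 or self.other_cause_hazard_multiplier < 0:
            raise ValueError(f"risk profile {self.label!r}: multipliers must be >= 0")


AVERAGE_RISK = RiskProfile("average", 1.0, 1.0, "average-risk woman")


@dataclasses.dataclass
class Woman:
    id: int
    birth_year: int
    other_cause_death_age: float
    density_at: dict  # {40: cat, 50: cat, 65: cat}
    risk_multiplier: float = 1.0
    risk_profile_label: str = "average"


def sample_other_cause_death(life_table_q: np.ndarray, profile: RiskProfile, stream) -> float:
    """Continuous age at other-cause death from annual death probabilities.

    The annual probabilities are converted to piecewise-constant hazards
    h = -log(1 - q) on single-year bins, scaled by the profile's
    other-cause hazard multiplier, and inverted against a unit exponential
    draw.  The table must cover ages 0..119 with q = 1 in the last bin.
    """
    q = np.asarray(life_table_q, dtype=float)
    if q.shape[0] != 120:
        raise ValueError(f"life table must cover ages 0..119, got {q.shape[0]} rows")
    m = profile.other_cause_hazard_multiplier
    if m < 0:
        raise ValueError("other_cause_hazard_multiplier must be >= 0")
    h = -np.log1p(-np.clip(q, 0.0, 1.0 - 1e-12)) * m
    cum = np.concatenate([[0.0], np.cumsum(h)])
    e = stream.exponential()
    if e >= cum[-1]:
        return float(MAX_AGE)
    k = int(np.searchsorted(cum, e, side="right") - 1)
    age = k + (e - cum[k]) / h[k]
    return float(min(age, MAX_AGE))


@dataclasses.dataclass(frozen=True)
class DensityTransitions:
    """Per-category stay probabilities for the 40->50 and 50->65 steps.

    Under the stay-or-step-down-one-category rule the marginal prevalences
    at the two ages determine these probabilities via a triangular system
    solved from the highest category downward.
    """

    stay_40_50: tuple
    stay_50_65: tuple


class DensityTransitionError(ValueError):
    pass


def _solve_step(p_from: np.ndarray, p_to: np.ndarray, step_name: str) -> tuple:
    stay = np.ones(4)
    inflow = 0.0  # mass arriving from the next-higher category
    for i in range(3, -1, -1):
        target = p_to[i] - inflow
        if p_from[i] <= 0:
            if abs(target) > 1e-9:
                raise DensityTransitionError(
                    f"{step_name}: category {DENSITY_CATS[i]!r} infeasible (no mass to supply {target:.4g})"
                )
            stay[i] = 1.0
            inflow = 0.0
            continue
        s = target / p_from[i]
        if i == 0:
            # lowest category cannot step down; its stay probability is forced to 1
            if abs(s - 1.0) > 1e-9:
                raise DensityTransitionError(
                    f"{step_name}: category {DENSITY_CATS[0]!r} infeasible (implied stay {s:.6g} != 1)"
                )
            s = 1.0
        if not (-1e-9 <= s <= 1 + 1e-9):
            raise DensityTransitionError(
                f"{step_name}: category {DENSITY_CATS[i]!r} stay probability {s:.6g} outside [0,1]"
            )
        s = float(min(max(s, 0.0), 1.0))
        stay[i] = s
        inflow = p_from[i] * (1.0 - s)
    return tuple(stay)


def solve_density_transitions(prev40, prev50, prev65) -> DensityTransitions:
    """Solve stay probabilities from the three marginal prevalences.

    Raises :class:`DensityTransitionError` naming the category when the
    marginals cannot be produced by stay-or-step-down-one transitions.
    """
    p40, p50, p65 = (np.asarray(p, dtype=float) for p in (prev40, prev50, prev65))
    for name, p in (("age 40", p40), ("age 50", p50), ("age 65", p65)):
        if abs(p.sum() - 1.0) > 1e-9:
            raise DensityTransitionError(f"prevalence at {name} sums to {p.sum():.12g}, not 1")
    return DensityTransitions(
        stay_40_50=_solve_step(p40, p50, "40->50"),
        stay_50_65=_solve_step(p50, p65, "50->65"),
    )


def assign_density_trajectory(prev40, transitions: DensityTransitions, stream) -> dict:
    """Sample one woman's density categories at 40, 50, and 65.

    Density never increases; after 65 it is constant (the age-65 category
    stands for all later ages)."""
    c40 = int(stream.choice(4, p=np.asarray(prev40, dtype=float)))
    c50 = c40 if stream.random() < transitions.stay_40_50[c40] else max(c40 - 1, 0)
    c65 = c50 if stream.random() < transitions.stay_50_65[c50] else max(c50 - 1, 0)
    return {40: DENSITY_CATS[c40], 50: DENSITY_CATS[c50], 65: DENSITY_CATS[c65]}


def build_cohort(n: int, birth_year: int, profile: RiskProfile, params, seed: int) -> list[Woman]:
    """Construct ``n`` women with independent per-woman streams keyed by
    (seed, id, purpose); identical inputs give identical cohorts."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    cohorts = params.life_table.columns.to_numpy()
    col = cohorts[np.argmin(np.abs(cohorts - birth_year))]
    q = params.life_table[col].to_numpy(dtype=float)
    prev = params.density_prevalence
    transitions = solve_density_transitions(
        prev.loc[40].to_numpy(), prev.loc[50].to_numpy(), prev.loc[65].to_numpy()
    )
    p40 = prev.loc[40].to_numpy(dtype=float)
    women = []
    for i in range(n):
        death = sample_other_cause_death(q, profile, substream(seed, i, "other_cause"))
        density = assign_density_trajectory(p40, transitions, substream(seed, i, "density"))
        women.append(
            Woman(
                id=i,
                birth_year=birth_year,
                other_cause_death_age=death,
                density_at=density,
                risk_multiplier=profile.risk_multiplier,
                risk_profile_label=profile.label,
            )
        )
    return women
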