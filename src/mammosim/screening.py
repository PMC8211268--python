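"""Screening strategies, schedules, test performance, and detection.

Screening never alters a woman's natural history; it can only move the
diagnosis earlier.  Detection noise at each screen is drawn from a stream
keyed by (seed, woman, quantized screen age), so two strategies that
screen the same woman at the same age see the same draw — nested
schedules then produce nested detections under paired seeds.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .constants import DENSITY_CATS, PERF_AGE_BANDS, age_band
from .rng import substream

__all__ = [
    "ScreeningStrategy",
    "PerformanceTable",
    "ScreenEvent",
    "DetectionRecord",
    "build_schedule",
    "interval_class",
    "perform_screen",
    "first_detection",
    "density_at_age",
]

RESULTS = ("true_positive", "false_negative", "false_positive", "true_negative")


@dataclasses.dataclass(frozen=True)
class ScreeningStrategy:
    """Ordered, non-overlapping age segments with fixed intervals.

    Each segment is ``(start_age, end_age, interval_years)``; an interval
    of ``None`` marks a one-time screen at the segment start.
    ``dissemination`` is either ``{"mode": "full"}`` (perfect adherence)
    or ``{"mode": "empirical", "first_age_offsets": [(offset, prob), ...],
    "attendance": p}`` which delays the first screen and thins attendance.
    """

    label: str
    segments: tuple
    dissemination: dict = dataclasses.field(default_factory=lambda: {"mode": "full"})

    def __post_init__(self):
        prev_end = -np.inf
        for seg in self.segments:
            start, end, interval = seg
            if start > end:
                raise ValueError(f"strategy {self.label!r}: segment start {start} > end {end}")
            if start < prev_end:
                raise ValueError(f"strategy {self.label!r}: overlapping segments at age {start}")
            if interval is not None and interval <= 0:
                raise ValueError(f"strategy {self.label!r}: non-positive interval")
            prev_end = end

    @classmethod
    def one_time(cls, age: float, label: str | None = None) -> "ScreeningStrategy":
        return cls(label or f"one-time-{age:g}", ((age, age, None),))

    @classmethod
    def uniform(cls, start: float, end: float, interval: float, label: str | None = None) -> "ScreeningStrategy":
        return cls(label or f"every-{interval:g}y-{start:g}-{end:g}", ((start, end, interval),))


NO_SCREENING = ScreeningStrategy("no-screening", ())


class PerformanceTable:
    """Mammography sensitivity/specificity by age group x density x
    interval class x first-vs-subsequent round.

    Backed by a long DataFrame with columns
    ``age_group, density, interval, first, sensitivity, specificity``.
    """

    COLUMNS = ("age_group", "density", "interval", "first", "sensitivity", "specificity")

    def __init__(self, table):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"performance table missing columns {missing}")
        self.table = table[list(self.COLUMNS)].copy()
        self._cache = {
            (r.age_group, r.density, r.interval, r.first): (float(r.sensitivity), float(r.specificity))
            for r in self.table.itertuples()
        }

    @classmethod
    def constant(cls, sensitivity: float, specificity: float) -> "PerformanceTable":
        """A stratification-free table (every stratum gets the same values)."""
        import pandas as pd

        rows = [
            {
                "age_group": ag,
                "density": d,
                "interval": ic,
                "first": fs,
                "sensitivity": sensitivity,
                "specificity": specificity,
            }
            for _, _, ag in PERF_AGE_BANDS
            for d in DENSITY_CATS
            for ic in ("annual", "biennial", "triennial")
            for fs in ("first", "subsequent")
        ]
        return cls(pd.DataFrame(rows))

    def lookup(self, age: float, density: str, interval: str, first: bool) -> tuple[float, float]:
        key = (age_band(age, PERF_AGE_BANDS), density, interval, "first" if first else "subsequent")
        try:
            return self._cache[key]
        except KeyError:
            raise KeyError(f"performance table has no stratum {key}") from None

    def validate(self) -> None:
        vals = self.table[["sensitivity", "specificity"]].to_numpy(dtype=float)
        if (vals < 0).any() or (vals > 1).any():
            bad = self.table.iloc[int(np.argwhere((vals < 0) | (vals > 1))[0][0])]
            raise ValueError(
                "performance: value outside [0,1] for stratum "
                f"({bad['age_group']}, {bad['density']}, {bad['interval']}, {bad['first']})"
            )


@dataclasses.dataclass(frozen=True)
class ScreenEvent:
    woman_id: int
    age: float
    result: str  # one of RESULTS
    first_screen: bool
    led_to_biopsy: bool


@dataclasses.dataclass
class DetectionRecord:
    """Outcome of the detection process for one woman under one strategy."""

    mode: str | None  # "screen", "clinical", or None (never diagnosed)
    age: float | None
    stage: str | None
    events: list
    interval_cancer: bool = False

    @property
    def diagnosed(self) -> bool:
        return self.mode is not None


def interval_class(gap_years: float | None) -> str:
    """Map the time since the previous attended screen to a Table-style
    interval class: <1.5y annual, <2.5y biennial, else triennial/infrequent."""
    if gap_years is None or gap_years >= 2.5:
        return "triennial"
    if gap_years < 1.5:
        return "annual"
    return "biennial"


def density_at_age(woman, age: float) -> str:
    if age < 50:
        return woman.density_at[40]
    if age < 65:
        return woman.density_at[50]
    return woman.density_at[65]


def build_schedule(strategy: ScreeningStrategy, woman, stream=None) -> list[float]:
    """Scheduled (attended) screen ages for one woman.

    Screens run from each segment start every ``interval`` years through
    the segment end (inclusive).  Across a boundary the next screen is
    ``max(next segment start, previous screen + new interval)``.  The
    schedule is truncated strictly before other-cause death.  Empirical
    dissemination shifts the first screen by a sampled offset and thins
    later screens by Bernoulli attendance draws.
    """
    dis = strategy.dissemination
    empirical = dis.get("mode") == "empirical"
    if empirical and stream is None:
        raise ValueError("empirical dissemination requires a random stream")

    first_offset = 0.0
    if empirical:
        offsets, probs = zip(*dis["first_age_offsets"])
        first_offset = float(stream.choice(offsets, p=np.asarray(probs) / np.sum(probs)))

    ages: list[float] = []
    prev = None
    for start, end, interval in strategy.segments:
        if interval is None:
            candidates = [start]
        else:
            first = start if prev is None else max(start, prev + interval)
            if prev is None:
                first += first_offset
            candidates = list(np.arange(first, end + 1e-9, interval)) if first <= end + 1e-9 else []
        for a in candidates:
            ages.append(float(a))
            prev = float(a)

    death = woman.other_cause_death_age
    ages = [a for a in ages if a < death]

    if empirical:
        p_attend = float(dis.get("attendance", 1.0))
        kept = []
        for a in ages:
            if not kept or stream.random() < p_attend:  # first screen always attended
                kept.append(a)
        ages = kept
    return ages


def perform_screen(
    woman,
    tumor,
    age: float,
    performance: PerformanceTable,
    rng,
    *,
    first: bool,
    gap_years: float | None,
    biopsy_prob: float = 0.0,
) -> ScreenEvent:
    """Apply one mammogram at ``age`` against the fixed natural history.

    A tumor whose preclinical window covers the age (onset <= age <
    latent clinical age, half-open) can yield true_positive/false_negative;
    otherwise the draw is false_positive/true_negative.
    """
    density = density_at_age(woman, age)
    sens, spec = performance.lookup(age, density, interval_class(gap_years), first)
    in_window = (
        tumor is not None
        and tumor.has_tumor
        and tumor.preclinical_onset_age <= age < tumor.clinical_detection_age
    )
    u = rng.random()
    biopsy = False
    if in_window:
        result = "true_positive" if u < sens else "false_negative"
    else:
        if u >= spec:
            result = "false_positive"
            biopsy = rng.random() < biopsy_prob
        else:
            result = "true_negative"
    return ScreenEvent(woman_id=woman.id, age=age, result=result, first_screen=first, led_to_biopsy=biopsy)


def _screen_key(age: float) -> int:
    # quantize to days so identical ages across strategies share one stream
    return int(round(age * 365.25))


def first_detection(
    woman,
    tumor,
    schedule,
    performance: PerformanceTable,
    seed: int,
    *,
    biopsy_prob: float = 0.0,
    stage_fn=None,
) -> DetectionRecord:
    """Run the schedule against the fixed natural history; return the
    earliest diagnosis (screen detection, else latent clinical detection
    before other-cause death, else none).

    ``stage_fn(mode, age) -> stage`` is supplied by the caller so that the
    active stage-assignment mechanism (table / dwell / growth) decides the
    stage at diagnosis.
    """
    death = woman.other_cause_death_age
    latent = tumor.clinical_detection_age if (tumor is not None and tumor.has_tumor) else np.inf
    stop = min(latent, death)

    events: list[ScreenEvent] = []
    had_false_negative = False
    prev_age = None
    detection_age = None
    for age in schedule:
        if age >= stop:
            break
        rng = substream(seed, woman.id, "screen", _screen_key(age))
        ev = perform_screen(
            woman,
            tumor,
            age,
            performance,
            rng,
            first=prev_age is None,
            gap_years=None if prev_age is None else age - prev_age,
            biopsy_prob=biopsy_prob,
        )
        events.append(ev)
        prev_age = age
        if ev.result == "true_positive":
            detection_age = age
            break
        if ev.result == "false_negative":
            had_false_negative = True

    if detection_age is not None:
        stage = stage_fn("screen", detection_age) if stage_fn else None
        return DetectionRecord(mode="screen", age=detection_age, stage=stage, events=events)
    if latent < death:
        stage = stage_fn("clinical", latent) if stage_fn else None
        return DetectionRecord(
            mode="clinical", age=float(latent), stage=stage, events=events, interval_cancer=had_false_negative
        )
    return DetectionRecord(mode=None, age=None, stage=None, events=events)
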