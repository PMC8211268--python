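"""Shared category labels and age-band definitions.

All age bands are half-open intervals ``[lo, hi)``; the top band is
effectively unbounded (capped at the 120-year model horizon).  Calendar
periods follow the same half-open convention.
"""

from __future__ import annotations

MAX_AGE = 120.0

SUBTYPES = ("ER+/HER2-", "ER+/HER2+", "ER-/HER2+", "ER-/HER2-")
DENSITY_CATS = ("a", "b", "c", "d")  # BI-RADS, a = almost entirely fatty
STAGES = ("local", "regional", "distant")
MODALITIES = ("chemotherapy", "endocrine", "trastuzumab")
DETECTION_MODES = ("screen", "clinical")
INTERVAL_CLASSES = ("annual", "biennial", "triennial")

# (lo, hi, label) half-open bands, per parameter family
PERF_AGE_BANDS = ((0, 40, "25-39"), (40, 50, "40-49"), (50, 65, "50-64"), (65, MAX_AGE, "65+"))
SUBTYPE_AGE_BANDS = ((0, 50, "<50"), (50, MAX_AGE, "50+"))
STAGE_AGE_BANDS = ((0, 50, "<50"), (50, 65, "50-64"), (65, MAX_AGE, "65+"))
TREAT_AGE_BANDS = ((0, 50, "<50"), (50, 70, "50-69"), (70, MAX_AGE, "70+"))
SURV_AGE_BANDS = ((0, 40, "<40"), (40, 50, "40-49"), (50, 60, "50-59"), (60, 70, "60-69"), (70, MAX_AGE, "70+"))
SOJOURN_AGE_BANDS = ((0, 40, "<40"), (40, 50, "40-49"), (50, 60, "50-59"), (60, 70, "60-69"), (70, MAX_AGE, "70+"))
STD_AGE_BANDS = ((0, 50, "0-49"), (50, 65, "50-64"), (65, MAX_AGE, "65+"))

TREATMENT_PERIODS = ((1975, 1995, "1975-1994"), (1995, 2013, "1995-2012"), (2013, 9999, "2013+"))

DENSITY_AGES = (40, 50, 65)


def age_band(age: float, bands) -> str:
    """Return the band label containing ``age`` (half-open intervals)."""
    for lo, hi, label in bands:
        if lo <= age < hi:
            return label
    if age >= bands[-1][0]:
        return bands[-1][2]
    raise KeyError(f"age {age} outside band coverage")


def period_label(year: float, periods=TREATMENT_PERIODS) -> str:
    for lo, hi, label in periods:
        if lo <= year < hi:
            return label
    # clamp: years before the first period use the first, after the last use the last
    if year < periods[0][0]:
        return periods[0][2]
    return periods[-1][2]
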