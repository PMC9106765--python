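"""Published summary statistics for Spartathlon finishers, 2011-2019.

These constants reproduce the published cohort description for the 2598
finishers (2255 men, 343 women) of the Athens-Sparta race over 2011-2019:
the 10-checkpoint course geometry, the age-group composition, and the
per-checkpoint speed summaries by sex.  They are used (a) as arithmetic
fixtures for the metric definitions and (b) to calibrate the synthetic
cohort generator, which is the only data source this package ships.
"""

from __future__ import annotations

#: (checkpoint index, race section, segment length in km)
SPARTATHLON_SEGMENTS: list[tuple[int, str, float]] = [
    (1, "Athens-Corinth", 19.5),
    (2, "Athens-Corinth", 22.7),
    (3, "Athens-Corinth", 37.8),
    (4, "Corinth-Nemea", 20.1),
    (5, "Corinth-Nemea", 23.2),
    (6, "Nemea-Nestani", 36.2),
    (7, "Nemea-Nestani", 12.0),
    (8, "Nestani-Tegea", 23.8),
    (9, "Tegea-Sparta", 31.4),
    (10, "Tegea-Sparta", 20.1),
]

SPARTATHLON_TOTAL_KM = 246.8
SPARTATHLON_TIME_LIMIT_HOURS = 36.0

N_MEN = 2255
N_WOMEN = 343
N_FINISHERS = N_MEN + N_WOMEN

#: Finisher counts per age group; "missing" = finishers with no recorded age.
AGE_GROUP_COUNTS: dict[str, dict[str, int]] = {
    "M": {
        "<30": 113, "30-34": 223, "35-39": 246, "40-44": 525,
        "45-49": 527, "50-54": 366, "55-59": 147, "60+": 84, "missing": 24,
    },
    "F": {
        "<30": 19, "30-34": 48, "35-39": 41, "40-44": 104,
        "45-49": 64, "50-54": 37, "55-59": 14, "60+": 16, "missing": 0,
    },
}

#: Mean checkpoint speed (m/s) per sex, checkpoints 1..10.
CHECKPOINT_SPEED_MEAN: dict[str, list[float]] = {
    "M": [2.92, 2.90, 2.51, 2.23, 2.07, 1.74, 1.53, 1.91, 1.82, 2.09],
    "F": [2.85, 2.80, 2.48, 2.22, 2.07, 1.72, 1.50, 1.90, 1.80, 2.06],
}

#: SD of checkpoint speed (m/s) per sex.
CHECKPOINT_SPEED_SD: dict[str, list[float]] = {
    "M": [0.22, 0.26, 0.28, 0.34, 0.31, 0.26, 0.23, 0.25, 0.20, 0.42],
    "F": [0.18, 0.22, 0.24, 0.33, 0.29, 0.24, 0.21, 0.21, 0.16, 0.35],
}

#: Average race speed (mean, SD, min, max) in m/s per sex.
AVERAGE_SPEED_SUMMARY: dict[str, tuple[float, float, float, float]] = {
    "M": (2.22, 0.32, 1.18, 3.40),
    "F": (2.21, 0.28, 1.41, 3.12),
}
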