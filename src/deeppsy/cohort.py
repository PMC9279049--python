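"""Synthetic boarding-school cohort generator.

Simulates the multimodal behavioral logs the screening pipeline consumes:
canteen meal events, internet sessions, course records, insomnia-night
counts, and a four-level concern label (none / mild / moderate / severe).
Students flagged with a mental-disorder (MD) label differ from the rest in
four planted, independently tunable channels:

* ``dining_irregularity`` — larger meal-time jitter, more skipped meals and
  more out-of-window "stray" canteen visits, raising dining entropy;
* ``late_night_use`` — a larger share of internet sessions starting in the
  00:00-06:00 window;
* ``grade_deficit`` — course scores shifted down;
* ``insomnia_rate`` — elevated probability of insomnia nights.

Each channel's shift is scaled by a standardized effect size, so a zero
effect size makes MD and non-MD students exchangeable on that channel.
All randomness flows from a single integer seed; identical configurations
produce byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LEVELS = ("primary", "junior", "senior")
LABELS = ("none", "mild", "moderate", "severe")
SEVERITIES = ("mild", "moderate", "severe")

# canonical meal windows: centers in minutes-of-day
MEAL_CENTERS = (450.0, 720.0, 1080.0)  # 07:30, 12:00, 18:00
NIGHT_END = 360  # 06:00; the late-night window is [0, 360)

#: severity scales the planted channel shifts while keeping them ordinal
SEVERITY_FACTOR = {"mild": 0.75, "moderate": 1.0, "severe": 1.25}

DEFAULT_EFFECTS = {
    "dining_irregularity": 1.0,
    "late_night_use": 1.0,
    "grade_deficit": 1.0,
    "insomnia_rate": 1.0,
}

COURSE_IDS = tuple(f"C{i:02d}" for i in range(1, 9))
COURSE_CREDITS = (3, 2, 4, 1, 3, 2, 3, 2)


class ConfigurationError(ValueError):
    """Raised for an internally inconsistent cohort configuration."""


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a simulated cohort.

    Defaults mirror the reference study design: 210 boarding students,
    70 per school level, balanced gender, ~60 observed days.
    """

    n_students: int = 210
    per_level: dict = field(
        default_factory=lambda: {"primary": 70, "junior": 70, "senior": 70}
    )
    md_prevalence: float = 0.3
    severity_mix: tuple = (0.5, 0.3, 0.2)
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    n_days: int = 60
    seed: int = 0

    def __post_init__(self):
        if sum(self.per_level.values()) != self.n_students:
            raise ConfigurationError(
                f"per_level counts {self.per_level} do not sum to "
                f"n_students={self.n_students}"
            )
        if not 0.0 < self.md_prevalence < 1.0:
            raise ConfigurationError("md_prevalence must lie in (0, 1)")
        if abs(sum(self.severity_mix) - 1.0) > 1e-9:
            raise ConfigurationError("severity_mix must sum to 1")
        if any(f < 0 or f > 1 for f in self.severity_mix):
            raise ConfigurationError("severity_mix fractions must lie in [0, 1]")
        unknown = set(self.effect_sizes) - set(DEFAULT_EFFECTS)
        if unknown:
            raise ConfigurationError(f"unknown effect channels: {sorted(unknown)}")
        if self.n_days < 1:
            raise ConfigurationError("n_days must be positive")

    def effect(self, channel: str) -> float:
        return float(self.effect_sizes.get(channel, 0.0))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["severity_mix"] = list(self.severity_mix)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "severity_mix" in d:
            d["severity_mix"] = tuple(d["severity_mix"])
        return cls(**d)


@dataclass
class StudentRecord:
    """One student's raw multimodal logs plus the concern label."""

    student_id: str
    level: str
    gender: str
    meal_events: list  # [(day, minute)] sorted
    net_sessions: list  # [(day, start, end)] sorted, 0 <= start < end < 1440
    courses: list  # [(course_id, score, credit)]; credit may be NaN
    insomnia_nights: int
    label: str  # none / mild / moderate / severe

    @property
    def is_md(self) -> bool:
        return self.label != "none"


def _severity_scale(label: str) -> float:
    return 0.0 if label == "none" else SEVERITY_FACTOR[label]


def _simulate_meals(rng, n_days: int, e: float) -> list:
    """Meal events: jittered canonical windows, skips and strays.

    All three irregularity mechanisms grow monotonically with the
    dining effect ``e``.
    """
    jitter_sd = 25.0 * (1.0 + 0.6 * e)
    p_skip = min(0.05 + 0.05 * e, 0.6)
    p_stray = min(0.03 + 0.04 * e, 0.5)
    kept = rng.random((n_days, 3)) >= p_skip
    minutes = np.clip(
        np.round(rng.normal(MEAL_CENTERS, jitter_sd, size=(n_days, 3))), 0, 1439
    ).astype(int)
    stray_mask = rng.random(n_days) < p_stray
    stray_minutes = rng.integers(0, 1440, size=n_days)
    events = []
    seen = set()
    days = np.arange(n_days)
    for day in days:
        for m in range(3):
            if kept[day, m] and (day, minutes[day, m]) not in seen:
                seen.add((day, minutes[day, m]))
                events.append((int(day), int(minutes[day, m])))
        if stray_mask[day] and (day, stray_minutes[day]) not in seen:
            seen.add((day, stray_minutes[day]))
            events.append((int(day), int(stray_minutes[day])))
    events.sort()
    return events


def _simulate_sessions(rng, n_days: int, e: float) -> list:
    """Internet sessions: Poisson daily counts, day/night start mixture."""
    w_night = min(0.04 + 0.10 * e, 0.85)
    counts = rng.poisson(2.0, size=n_days)
    total = int(counts.sum())
    if total == 0:
        return []
    days = np.repeat(np.arange(n_days), counts)
    is_night = rng.random(total) < w_night
    starts = np.where(
        is_night,
        np.clip(rng.normal(120.0, 60.0, size=total), 0, 330),
        np.clip(rng.normal(1140.0, 150.0, size=total), 540, 1380),
    ).astype(int)
    durs = np.clip(rng.exponential(45.0, size=total) + 10.0, 5.0, 180.0)
    ends = np.minimum(starts + durs, 1439).astype(int)
    keep = ends > starts
    sessions = [
        (int(d), int(s), int(en))
        for d, s, en in zip(days[keep], starts[keep], ends[keep])
    ]
    sessions.sort()
    return sessions


def _simulate_courses(rng, e: float) -> list:
    mean = 75.0 - 4.0 * e
    scores = np.clip(rng.normal(mean, 8.0, size=len(COURSE_IDS)), 50.0, 100.0)
    return [
        (cid, int(round(s)), int(cr))
        for cid, s, cr in zip(COURSE_IDS, scores, COURSE_CREDITS)
    ]


def _insomnia_nights(rng, sessions: list, n_days: int, e: float) -> int:
    active = {d for d, s, _ in sessions if s < NIGHT_END}
    p_extra = min(0.04 + 0.08 * e, 0.9)
    draws = rng.random(n_days) < p_extra
    extra = sum(1 for d in range(n_days) if d not in active and draws[d])
    return len(active) + extra


def simulate_cohort(config: CohortConfig) -> list:
    """Generate the full cohort; deterministic under (config, seed)."""
    rng = np.random.default_rng(config.seed)
    records = []
    sid = 0
    for level in LEVELS:
        count = config.per_level.get(level, 0)
        for j in range(count):
            sid += 1
            gender = "F" if j % 2 == 0 else "M"
            if rng.random() < config.md_prevalence:
                label = rng.choice(SEVERITIES, p=np.asarray(config.severity_mix))
                label = str(label)
            else:
                label = "none"
            s = _severity_scale(label)
            e_dine = config.effect("dining_irregularity") * s
            e_night = config.effect("late_night_use") * s
            e_grade = config.effect("grade_deficit") * s
            e_ins = config.effect("insomnia_rate") * s
            meals = _simulate_meals(rng, config.n_days, e_dine)
            sessions = _simulate_sessions(rng, config.n_days, e_night)
            courses = _simulate_courses(rng, e_grade)
            nights = _insomnia_nights(rng, sessions, config.n_days, e_ins)
            records.append(
                StudentRecord(
                    student_id=f"S{sid:04d}",
                    level=level,
                    gender=gender,
                    meal_events=meals,
                    net_sessions=sessions,
                    courses=courses,
                    insomnia_nights=nights,
                    label=label,
                )
            )
    return records


# ---------------------------------------------------------------------------
# corruption for preprocessing tests


@dataclass
class CorruptionLedger:
    """Ground truth of injected noise, for validating preprocessing."""

    injected_meals: list  # [(student_id, day, minute)] noise rows added
    blanked_credits: list  # [(student_id, course_index)] credits set to NaN


def corrupt_for_preprocessing(
    cohort: list,
    noise_rate: float,
    missing_credit_rate: float,
    seed: int = 0,
) -> tuple:
    """Inject consumption noise and blank course credits.

    Noise events are exact duplicates of existing meal rows or
    physically impossible rows (minute >= 1440); both kinds are what the
    cleaning step must remove. Exactly ``round(rate * n)`` rows are
    affected per channel. Returns ``(corrupted_cohort, ledger)``.
    """
    if not 0 <= noise_rate <= 1 or not 0 <= missing_credit_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = [
        dataclasses.replace(
            r,
            meal_events=list(r.meal_events),
            courses=list(r.courses),
        )
        for r in cohort
    ]

    meal_index = [
        (i, j) for i, r in enumerate(out) for j in range(len(r.meal_events))
    ]
    n_noise = int(round(noise_rate * len(meal_index)))
    injected = []
    if n_noise:
        picks = rng.choice(len(meal_index), size=n_noise, replace=False)
        for t, flat in enumerate(picks):
            i, j = meal_index[int(flat)]
            day, minute = out[i].meal_events[j]
            if t % 2 == 0:  # exact duplicate
                noise = (day, minute)
            else:  # impossible timestamp
                noise = (day, 1440 + int(rng.integers(0, 60)))
            out[i].meal_events.append(noise)
            injected.append((out[i].student_id, noise[0], noise[1]))
        for r in out:
            r.meal_events.sort()

    course_index = [
        (i, j) for i, r in enumerate(out) for j in range(len(r.courses))
    ]
    n_blank = int(round(missing_credit_rate * len(course_index)))
    blanked = []
    if n_blank:
        picks = rng.choice(len(course_index), size=n_blank, replace=False)
        for flat in picks:
            i, j = course_index[int(flat)]
            cid, score, _ = out[i].courses[j]
            out[i].courses[j] = (cid, score, float("nan"))
            blanked.append((out[i].student_id, j))

    return out, CorruptionLedger(injected_meals=injected, blanked_credits=blanked)


# ---------------------------------------------------------------------------
# serialization: one CSV per channel plus a JSON manifest


def write_cohort(cohort: list, outdir, config: CohortConfig = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "student_id": r.student_id,
                "level": r.level,
                "gender": r.gender,
                "insomnia_nights": r.insomnia_nights,
                "label": r.label,
            }
            for r in cohort
        ]
    ).to_csv(outdir / "students.csv", index=False)
    pd.DataFrame(
        [
            {"student_id": r.student_id, "day": d, "minute": m}
            for r in cohort
            for d, m in r.meal_events
        ]
    ).to_csv(outdir / "meals.csv", index=False)
    pd.DataFrame(
        [
            {"student_id": r.student_id, "day": d, "start": s, "end": e}
            for r in cohort
            for d, s, e in r.net_sessions
        ]
    ).to_csv(outdir / "sessions.csv", index=False)
    pd.DataFrame(
        [
            {
                "student_id": r.student_id,
                "course_id": cid,
                "score": score,
                "credit": credit,
            }
            for r in cohort
            for cid, score, credit in r.courses
        ]
    ).to_csv(outdir / "courses.csv", index=False)
    manifest = {"config": config.to_dict() if config else None}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_cohort(indir) -> list:
    indir = Path(indir)
    students = pd.read_csv(indir / "students.csv")
    meals = pd.read_csv(indir / "meals.csv")
    sessions = pd.read_csv(indir / "sessions.csv")
    courses = pd.read_csv(indir / "courses.csv")
    meals_by = {
        sid: sorted(zip(g["day"].astype(int), g["minute"].astype(int)))
        for sid, g in meals.groupby("student_id")
    }
    sess_by = {
        sid: sorted(
            zip(g["day"].astype(int), g["start"].astype(int), g["end"].astype(int))
        )
        for sid, g in sessions.groupby("student_id")
    }
    course_by = {
        sid: list(zip(g["course_id"], g["score"], g["credit"]))
        for sid, g in courses.groupby("student_id", sort=False)
    }
    records = []
    for row in students.itertuples(index=False):
        records.append(
            StudentRecord(
                student_id=row.student_id,
                level=row.level,
                gender=row.gender,
                meal_events=meals_by.get(row.student_id, []),
                net_sessions=sess_by.get(row.student_id, []),
                courses=course_by.get(row.student_id, []),
                insomnia_nights=int(row.insomnia_nights),
                label=row.label,
            )
        )
    return records


def read_manifest(indir) -> CohortConfig:
    d = json.loads((Path(indir) / "manifest.json").read_text())
    return CohortConfig.from_dict(d["config"])
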