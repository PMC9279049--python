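"""Behavioral feature engineering for the screening pipeline.

Implements the preprocessing and feature formulas:

* grade point ``F_i = (Score_i - 50) / 10``, course quality
  ``Q_i = Credit_i * F_i`` and the aggregate GPA ``F_avg = sum Q_i / sum
  Score_i`` (a conventional per-credit denominator is available behind a
  flag);
* the dining distribution over daily meal windows, its Shannon entropy
  (natural log), k-means clustering of dining behavior with k=3, and the
  cluster-distance anomaly score ``M = D(n, c_i) * (1 - |c_i| / |C|)``
  where ``|c_i| / |C|`` is the fraction of the cohort in the student's
  cluster — members of small clusters score higher at equal distance;
* the insomnia probability ``P_i = t_i / T`` (insomnia nights over
  observed days).

``build_feature_table`` assembles the per-student tabular feature vector
consumed by the classifier bench and by the fusion model's basic branch.
"""

from __future__ import annotations

import logging
import math
from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)

#: daily meal windows in minutes-of-day: [lo, hi) — breakfast, lunch,
#: dinner, plus a catch-all "other" bin for irregular eating
MEAL_WINDOWS = ((360, 540), (660, 840), (1020, 1200))
N_BINS = len(MEAL_WINDOWS) + 1  # + "other"

#: fixed column order of the feature table
FEATURE_COLUMNS = (
    "gpa_avg",
    "dining_entropy",
    "anomaly_score",
    "insomnia_prob",
    "sessions_per_day",
    "night_session_frac",
)

#: ablation channel -> tabular columns carrying it
CHANNEL_COLUMNS = {
    "performance": ("gpa_avg",),
    "consumption": ("dining_entropy", "anomaly_score"),
    "network": ("insomnia_prob", "sessions_per_day", "night_session_frac"),
}


class ImputationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# preprocessing


def clean_consumption(events: list) -> list:
    """Drop duplicate and physically impossible consumption events.

    Keeps the first occurrence of each (day, minute); removes rows with a
    minute outside [0, 1440).
    """
    seen = set()
    out = []
    for day, minute in events:
        if not 0 <= minute < 1440:
            continue
        if (day, minute) in seen:
            continue
        seen.add((day, minute))
        out.append((day, minute))
    out.sort()
    return out


def fill_missing_credits(cohort: list) -> list:
    """Impute missing course credits with the cohort median for the course.

    Raises :class:`ImputationError` if some course has no observed credit
    anywhere in the cohort.
    """
    observed = {}
    for r in cohort:
        for cid, _, credit in r.courses:
            if credit == credit:  # not NaN
                observed.setdefault(cid, []).append(float(credit))
    medians = {cid: float(np.median(v)) for cid, v in observed.items()}
    out = []
    for r in cohort:
        courses = []
        for cid, score, credit in r.courses:
            if credit != credit:
                if cid not in medians:
                    raise ImputationError(
                        f"course {cid} has no observed credit in the cohort"
                    )
                credit = medians[cid]
            courses.append((cid, score, credit))
        out.append(replace(r, courses=courses))
    return out


def clean_cohort(cohort: list) -> list:
    """Full preprocessing: de-noise consumption, impute credits."""
    cohort = [
        replace(r, meal_events=clean_consumption(r.meal_events)) for r in cohort
    ]
    return fill_missing_credits(cohort)


# ---------------------------------------------------------------------------
# grade features


def grade_point(score: float) -> float:
    """Affine grade-point transform of a 0-100 course score."""
    if not 0 <= score <= 100:
        raise ValueError(f"score {score} outside [0, 100]")
    return (score - 50.0) / 10.0


def course_quality(credit: float, gpa: float) -> float:
    """Course quality: credit times grade point."""
    if credit < 0:
        raise ValueError("negative credit")
    return credit * gpa


def gpa_average(courses: list, denominator: str = "score") -> float:
    """Aggregate GPA: sum of course qualities over sum of raw scores.

    ``denominator="credit"`` switches to the conventional per-credit
    average. ``courses`` is a list of (course_id, score, credit).
    """
    q = sum(course_quality(credit, grade_point(score)) for _, score, credit in courses)
    if denominator == "score":
        denom = sum(score for _, score, _ in courses)
    elif denominator == "credit":
        denom = sum(credit for _, _, credit in courses)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom <= 0:
        raise ZeroDivisionError("GPA denominator is zero")
    return q / denom


# ---------------------------------------------------------------------------
# dining regularity


def dining_distribution(meal_events: list, windows=MEAL_WINDOWS) -> np.ndarray:
    """Empirical distribution of meal events over the daily windows.

    Returns probabilities over len(windows)+1 bins (the last bin collects
    events outside every window). Returns None for an empty profile.
    """
    if not meal_events:
        return None
    counts = np.zeros(len(windows) + 1)
    for _, minute in meal_events:
        for b, (lo, hi) in enumerate(windows):
            if lo <= minute < hi:
                counts[b] += 1
                break
        else:
            counts[-1] += 1
    return counts / counts.sum()


def dining_entropy(probabilities) -> float:
    """Shannon entropy (natural log) of a dining distribution; 0 log 0 = 0."""
    if probabilities is None:
        return 0.0
    p = np.asarray(probabilities, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def dining_feature_matrix(cohort: list, n_days: int) -> np.ndarray:
    """Per-student dining descriptors for clustering.

    Columns: entropy, meals/day rate, fraction of the three canonical
    windows ever used — separating "eats rarely" from "eats often" groups
    with similar entropy.
    """
    rows = []
    for r in cohort:
        probs = dining_distribution(r.meal_events)
        ent = dining_entropy(probs)
        rate = len(r.meal_events) / max(n_days, 1)
        used = 0.0
        if r.meal_events:
            minutes = [m for _, m in r.meal_events]
            used = (
                sum(
                    any(lo <= m < hi for m in minutes) for lo, hi in MEAL_WINDOWS
                )
                / len(MEAL_WINDOWS)
            )
        rows.append((ent, rate, used))
    return np.asarray(rows, dtype=float)


def cluster_dining(features: np.ndarray, k: int = 3, seed: int = 0, n_init: int = 10):
    """Lloyd k-means with restarts on standardized dining descriptors.

    Returns (assignments, centroids, sizes) in the standardized space.
    """
    x = np.asarray(features, dtype=float)
    if len(x) < k:
        raise ValueError(f"need at least k={k} students, got {len(x)}")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(z)
    sizes = np.bincount(labels, minlength=k)
    return labels, km.cluster_centers_, sizes, z


def anomaly_score(
    point, centroid, cluster_size: int, cohort_size: int
) -> float:
    """Cluster-distance anomaly score.

    Euclidean distance to the student's own centroid, weighted by
    ``1 - cluster_size / cohort_size`` so that members of small clusters
    score higher at equal distance. Zero for a whole-cohort cluster.
    """
    if cluster_size < 1 or cluster_size > cohort_size:
        raise ValueError("cluster_size must lie in [1, cohort_size]")
    d = float(np.linalg.norm(np.asarray(point, float) - np.asarray(centroid, float)))
    return d * (1.0 - cluster_size / cohort_size)


def anomaly_scores(cohort: list, n_days: int, seed: int = 0) -> np.ndarray:
    """Per-student anomaly score from dining clustering (k=3)."""
    feats = dining_feature_matrix(cohort, n_days)
    labels, centroids, sizes, z = cluster_dining(feats, k=3, seed=seed)
    n = len(cohort)
    return np.array(
        [
            anomaly_score(z[i], centroids[labels[i]], int(sizes[labels[i]]), n)
            for i in range(n)
        ]
    )


# ---------------------------------------------------------------------------
# insomnia


def insomnia_probability(insomnia_nights: int, n_days: int) -> float:
    """Fraction of observed nights marked as insomnia."""
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    if not 0 <= insomnia_nights <= n_days:
        raise ValueError("insomnia_nights outside [0, n_days]")
    return insomnia_nights / n_days


# ---------------------------------------------------------------------------
# assembly


def build_feature_table(
    cohort: list,
    n_days: int,
    seed: int = 0,
    gpa_denominator: str = "score",
) -> pd.DataFrame:
    """One row per student: engineered features plus the binary MD label.

    Missing channels are imputed by the cohort median and flagged with a
    warning log. Column order is fixed (see :data:`FEATURE_COLUMNS`).
    """
    m_scores = anomaly_scores(cohort, n_days, seed=seed)
    rows = []
    for r, m in zip(cohort, m_scores):
        row = {"student_id": r.student_id}
        try:
            row["gpa_avg"] = gpa_average(r.courses, denominator=gpa_denominator)
        except (ZeroDivisionError, ValueError):
            row["gpa_avg"] = np.nan
        row["dining_entropy"] = dining_entropy(dining_distribution(r.meal_events))
        row["anomaly_score"] = m
        try:
            row["insomnia_prob"] = insomnia_probability(r.insomnia_nights, n_days)
        except ValueError:
            row["insomnia_prob"] = np.nan
        n_sessions = len(r.net_sessions)
        row["sessions_per_day"] = n_sessions / max(n_days, 1)
        if n_sessions:
            night = sum(1 for _, s, _ in r.net_sessions if s < 360)
            row["night_session_frac"] = night / n_sessions
        else:
            row["night_session_frac"] = np.nan
        row["label"] = int(r.is_md)
        rows.append(row)
    table = pd.DataFrame(rows, columns=["student_id", *FEATURE_COLUMNS, "label"])
    for col in FEATURE_COLUMNS:
        if table[col].isna().any():
            n_missing = int(table[col].isna().sum())
            log.warning("imputing %d missing values in %s", n_missing, col)
            table[col] = table[col].fillna(table[col].median())
    return table


def entropy_upper_bound(n_bins: int = N_BINS) -> float:
    return math.log(n_bins)
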