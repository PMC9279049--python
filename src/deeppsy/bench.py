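"""Classifier bench: five standard algorithms on the tabular features.

Random forest (RF), Gaussian naive Bayes (NB), gradient boosting (GB),
a small multilayer-perceptron neural network (NN) and a decision tree
(DT) are fitted on a stratified 60/20/20 train/validation/test split,
tuned on validation over small fixed grids, and reported on test with
the standard screening panel: accuracy, precision, recall, F1 and AUC,
all with respect to the MD (positive) class. The best model is the
validation-F1 argmax with recall as tiebreak — recall is the screening
quantity of interest (the fraction of truly at-risk students flagged).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

log = logging.getLogger(__name__)

MODEL_NAMES = ("RF", "NB", "GB", "NN", "DT")


class StratificationError(ValueError):
    pass


@dataclass
class EvalReport:
    """Confusion-matrix metrics for one model on one split."""

    model: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    tp: int
    fp: int
    fn: int
    tn: int
    split: str = "test"
    seed: int = 0
    converged: bool = True

    def to_dict(self):
        return asdict(self)


# ---------------------------------------------------------------------------
# splitting


def split_data(n: int, labels, fractions=(0.6, 0.2, 0.2), seed: int = 0):
    """Stratified disjoint train/validation/test index partition."""
    labels = np.asarray(labels)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_test = int(round(fractions[2] * n))
    n_val = int(round(fractions[1] * n))
    idx = np.arange(n)
    try:
        s1 = StratifiedShuffleSplit(n_splits=1, test_size=n_test, random_state=seed)
        rest, test = next(s1.split(idx.reshape(-1, 1), labels))
        s2 = StratifiedShuffleSplit(
            n_splits=1, test_size=n_val, random_state=seed + 1
        )
        tr, val = next(s2.split(rest.reshape(-1, 1), labels[rest]))
    except ValueError as exc:
        raise StratificationError(str(exc)) from exc
    train, val = np.sort(rest[tr]), np.sort(rest[val])
    test = np.sort(idx[test])
    for part, name in ((train, "train"), (val, "validation"), (test, "test")):
        if len(np.unique(labels[part])) < 2:
            raise StratificationError(f"{name} split has a single class")
    return train, val, test


def split_hash(train, val, test) -> str:
    """Stable digest of a partition; used to verify paired designs."""
    payload = b"|".join(np.asarray(p, dtype=np.int64).tobytes() for p in (train, val, test))
    return hashlib.sha1(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# metrics


def rank_auc(labels, scores) -> float:
    """Mann-Whitney AUC: concordant-pair fraction with half credit for ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


def compute_metrics(
    labels, predictions, scores=None, model: str = "", split: str = "test", seed: int = 0
) -> EvalReport:
    """Confusion-matrix panel for binary labels (positive class = 1)."""
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    tp = int(((labels == 1) & (predictions == 1)).sum())
    fp = int(((labels == 0) & (predictions == 1)).sum())
    fn = int(((labels == 1) & (predictions == 0)).sum())
    tn = int(((labels == 0) & (predictions == 0)).sum())
    total = tp + fp + fn + tn
    accuracy = (tp + tn) / total if total else float("nan")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    auc = rank_auc(labels, scores) if scores is not None else float("nan")
    return EvalReport(
        model=model,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        auc=auc,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        split=split,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# the five algorithms, with small fixed tuning grids


def _model_grid(name: str, seed: int):
    if name == "RF":
        return [
            RandomForestClassifier(
                n_estimators=100, max_depth=d, class_weight="balanced", random_state=seed
            )
            for d in (None, 5)
        ]
    if name == "NB":
        return [GaussianNB()]
    if name == "GB":
        return [
            GradientBoostingClassifier(n_estimators=n, max_depth=2, random_state=seed)
            for n in (50, 100)
        ]
    if name == "NN":
        return [
            MLPClassifier(
                hidden_layer_sizes=(h,), max_iter=800, random_state=seed
            )
            for h in (8, 16)
        ]
    if name == "DT":
        return [
            DecisionTreeClassifier(
                max_depth=d, class_weight="balanced", random_state=seed
            )
            for d in (3, 5, None)
        ]
    raise ValueError(f"unknown model {name!r}")


def _fit_eval(clf, x_tr, y_tr, x_ev, y_ev, name, split, seed):
    import warnings

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            clf.fit(x_tr, y_tr)
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("model %s failed to fit: %s", name, exc)
            rep = compute_metrics(y_ev, np.zeros_like(y_ev), None, name, split, seed)
            rep.converged = False
            return rep
    preds = clf.predict(x_ev)
    scores = clf.predict_proba(x_ev)[:, 1]
    rep = compute_metrics(y_ev, preds, scores, name, split, seed)
    rep.converged = converged
    return rep


def run_bench(features, labels, splits, seed: int = 0, models=MODEL_NAMES):
    """Fit, tune and report the five algorithms.

    ``splits`` is the (train, val, test) index triple. Each model's grid
    is tuned by validation F1; the tuned model is refitted on train and
    reported on test. Returns a list of test-split EvalReports (one per
    model) with the validation report attached as ``.validation``.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    tr, val, test = splits
    scaler = StandardScaler().fit(x[tr])
    xs = scaler.transform(x)
    reports = []
    for name in models:
        best = None
        for clf in _model_grid(name, seed):
            rep = _fit_eval(clf, xs[tr], y[tr], xs[val], y[val], name, "validation", seed)
            if best is None or (rep.f1, rep.recall) > (best[0].f1, best[0].recall):
                best = (rep, clf)
        val_rep, clf = best
        test_rep = _fit_eval(clf, xs[tr], y[tr], xs[test], y[test], name, "test", seed)
        test_rep.validation = val_rep
        reports.append(test_rep)
    return reports


def select_classifier(reports) -> str:
    """Best model: argmax of validation F1, ties broken by higher recall
    then lexicographic name."""
    if not reports:
        raise ValueError("no reports")

    def key(rep):
        v = getattr(rep, "validation", rep)
        return (-v.f1, -v.recall, rep.model)

    winner = sorted(reports, key=key)[0]
    log.info("selected classifier %s (validation F1 tiebreak by recall)", winner.model)
    return winner.model
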