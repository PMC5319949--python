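"""Familiarity-stratified binary emotion classification.

Arousal and valence are each reduced to a binary target (positivity of
a [-1, 1] annotation, or a 1–9 rating thresholded at 4.5) and
classified per subject with 10-fold stratified cross-validation using
three classic algorithms:

``svm_puk``
    support vector machine with the Pearson VII universal kernel
    K(u, v) = 1 / (1 + (2 sqrt(2^{1/ω} − 1) ‖u−v‖ / σ)²)^ω, ω = σ = 1.
``mlp``
    multilayer perceptron, one hidden layer of
    (n_features + n_classes) / 2 units.
``c45``
    entropy-split decision tree with a minimum leaf size of 2
    (a C4.5-style learner).

Accuracies are reported against the *chance level* — the percentage of
windows in the majority class — because self-annotated emotion labels
are typically imbalanced.  The stratified evaluation runs each subject
separately within the low-familiarity, high-familiarity and combined
strata and compares strata with paired t-tests across subjects.

Windows from the same stimulus may share cross-validation folds
(plain within-subject 10-fold CV); temporally adjacent windows are
correlated, so absolute accuracies are optimistic — comparisons
between strata, which share this bias, are the meaningful output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import feature_columns

log = logging.getLogger(__name__)

__all__ = [
    "CLASSIFIERS",
    "binarize_labels",
    "chance_level",
    "crossval_classify",
    "EvalConfig",
    "EvalReport",
    "familiarity_stratified_eval",
    "puk_kernel",
]

CLASSIFIERS = ("svm_puk", "mlp", "c45")
SCHEMES = ("positivity", "deap45")

_TARGET_COLUMN = {"arousal": "arousal_class", "valence": "valence_class"}
_POSITIVE_NAME = {"arousal": "high", "valence": "positive"}


def binarize_labels(ratings: np.ndarray, scheme: str) -> np.ndarray:
    """Binarize emotion ratings; True is the high/positive class.

    ``positivity``: ratings in [-1, 1], positive values are high
    (exactly 0 is not positive, hence low/negative).  ``deap45``:
    ratings in [1, 9], values strictly above 4.5 are high.
    """
    ratings = np.asarray(ratings, dtype=float)
    if scheme == "positivity":
        if np.any(ratings < -1) or np.any(ratings > 1):
            raise ValueError("positivity scheme expects ratings in [-1, 1]")
        return ratings > 0.0
    if scheme == "deap45":
        if np.any(ratings < 1) or np.any(ratings > 9):
            raise ValueError("deap45 scheme expects ratings in [1, 9]")
        return ratings > 4.5
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def chance_level(labels) -> float:
    """Majority-class percentage of a label vector (the baseline).

    A 60%/40% split has a chance level of 60.0.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty labels")
    _, counts = np.unique(labels, return_counts=True)
    return 100.0 * counts.max() / labels.size


def puk_kernel(u: np.ndarray, v: np.ndarray, sigma: float = 1.0, omega: float = 1.0) -> np.ndarray:
    """Pearson VII universal kernel Gram matrix."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    d2 = (
        np.sum(u**2, axis=1)[:, None]
        + np.sum(v**2, axis=1)[None, :]
        - 2.0 * u @ v.T
    )
    np.maximum(d2, 0.0, out=d2)
    c = 2.0 * np.sqrt(2.0 ** (1.0 / omega) - 1.0) / sigma
    return 1.0 / (1.0 + c**2 * d2) ** omega


def _estimator(name: str, n_features: int, seed: int):
    if name == "svm_puk":
        # sigma grows with sqrt(p): on standardized features pairwise
        # squared distances scale with the dimension p, so a fixed-width
        # kernel would degenerate toward a constant Gram matrix.
        sigma = float(np.sqrt(n_features))
        clf = SVC(kernel=lambda u, v: puk_kernel(u, v, sigma=sigma), C=1.0)
    elif name == "mlp":
        hidden = max(2, (n_features + 2) // 2)
        clf = MLPClassifier(
            hidden_layer_sizes=(hidden,),
            max_iter=400,
            random_state=seed,
        )
    elif name == "c45":
        clf = DecisionTreeClassifier(
            criterion="entropy", min_samples_leaf=2, random_state=seed
        )
    else:
        raise ValueError(f"unknown classifier {name!r}; expected one of {CLASSIFIERS}")
    return make_pipeline(StandardScaler(), clf)


def crossval_classify(
    table: pd.DataFrame,
    feature_set: str,
    target: str,
    classifier: str = "svm_puk",
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Mean held-out accuracy (%) over seeded stratified k-fold CV.

    ``feature_set`` is ``'FD'`` or ``'PSD'``; ``target`` is
    ``'arousal'`` or ``'valence'``.  Every class must have at least
    ``folds`` rows.  A fold whose training part lost a class (cannot
    happen under stratification, guarded regardless) is logged and
    skipped.
    """
    cols = feature_columns(table, feature_set)
    X = table[cols].to_numpy(dtype=float)
    y = table[_TARGET_COLUMN[target]].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} rows < {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(X, y):
        if len(np.unique(y[train])) < len(classes):
            log.warning("fold lost a class during training; skipped")
            continue
        model = _estimator(classifier, X.shape[1], seed)
        model.fit(X[train], y[train])
        accs.append(float(np.mean(model.predict(X[test]) == y[test])))
    if not accs:
        raise ValueError("every fold was skipped")
    return 100.0 * float(np.mean(accs))


@dataclass
class EvalConfig:
    """Grid evaluated by :func:`familiarity_stratified_eval`."""

    strata: tuple[str, ...] = ("low", "high", "all")
    feature_sets: tuple[str, ...] = ("FD", "PSD")
    classifiers: tuple[str, ...] = CLASSIFIERS
    targets: tuple[str, ...] = ("arousal", "valence")
    folds: int = 10
    seed: int = 0


@dataclass
class EvalReport:
    """Stratified evaluation output.

    ``cells`` holds one row per stratum × feature set × classifier ×
    target with subject-averaged accuracy, SD, chance level and the
    above-chance margin; ``per_subject`` the underlying per-subject
    results; ``stratum_tests`` paired t-tests between strata on the
    per-subject above-chance margins.
    """

    cells: pd.DataFrame
    per_subject: pd.DataFrame = field(repr=False)
    stratum_tests: pd.DataFrame = field(repr=False)

    def cell(self, stratum: str, feature_set: str, classifier: str, target: str) -> pd.Series:
        m = self.cells
        sel = m[
            (m["stratum"] == stratum)
            & (m["feature_set"] == feature_set)
            & (m["classifier"] == classifier)
            & (m["target"] == target)
        ]
        if len(sel) != 1:
            raise KeyError((stratum, feature_set, classifier, target))
        return sel.iloc[0]


def familiarity_stratified_eval(table: pd.DataFrame, config: EvalConfig | None = None) -> EvalReport:
    """Within-subject CV accuracy per familiarity stratum.

    Each subject's windows are restricted to a stratum (``low``,
    ``high`` or ``all`` = no restriction) and classified with every
    requested feature set × classifier × target combination; folds
    shrink to the smallest class count when a subject-stratum is too
    small for the nominal fold count, and a subject-stratum whose
    target has fewer than 2 rows per class is skipped and logged.
    """
    config = config or EvalConfig()
    rows = []
    for subject, sub in table.groupby("subject_id"):
        for stratum in config.strata:
            part = sub if stratum == "all" else sub[sub["familiarity_group"] == stratum]
            if part.empty:
                log.warning("subject %s has no windows in stratum %s; skipped", subject, stratum)
                continue
            for target in config.targets:
                y = part[_TARGET_COLUMN[target]].to_numpy()
                classes, counts = np.unique(y, return_counts=True)
                if len(classes) < 2 or counts.min() < 2:
                    log.warning(
                        "subject %s stratum %s target %s lacks both classes; skipped",
                        subject, stratum, target,
                    )
                    continue
                folds = min(config.folds, int(counts.min()))
                chance = chance_level(y)
                for feature_set in config.feature_sets:
                    for classifier in config.classifiers:
                        acc = crossval_classify(
                            part, feature_set, target, classifier,
                            folds=folds, seed=config.seed,
                        )
                        rows.append(
                            {
                                "subject_id": subject,
                                "stratum": stratum,
                                "feature_set": feature_set,
                                "classifier": classifier,
                                "target": target,
                                "accuracy": acc,
                                "chance": chance,
                                "above_chance": acc - chance,
                                "n_windows": len(part),
                                "folds": folds,
                            }
                        )
    per_subject = pd.DataFrame(rows)
    if per_subject.empty:
        raise ValueError("no subject-stratum produced a usable evaluation")

    cell_rows = []
    for (stratum, fs, clf, target), grp in per_subject.groupby(
        ["stratum", "feature_set", "classifier", "target"], sort=False
    ):
        cell_rows.append(
            {
                "stratum": stratum,
                "feature_set": fs,
                "classifier": clf,
                "target": target,
                "mean_accuracy": grp["accuracy"].mean(),
                "sd_accuracy": grp["accuracy"].std(ddof=1) if len(grp) > 1 else 0.0,
                "mean_chance": grp["chance"].mean(),
                "above_chance": grp["accuracy"].mean() - grp["chance"].mean(),
                "n_subjects": len(grp),
            }
        )
    cells = pd.DataFrame(cell_rows)

    test_rows = []
    strata = list(config.strata)
    for (fs, clf, target), grp in per_subject.groupby(
        ["feature_set", "classifier", "target"], sort=False
    ):
        pivot = grp.pivot_table(
            index="subject_id", columns="stratum", values="above_chance"
        )
        for i, sa in enumerate(strata):
            for sb in strata[i + 1 :]:
                if sa not in pivot.columns or sb not in pivot.columns:
                    continue
                both = pivot[[sa, sb]].dropna()
                if len(both) < 2:
                    continue
                res = sps.ttest_rel(both[sa], both[sb])
                test_rows.append(
                    {
                        "feature_set": fs,
                        "classifier": clf,
                        "target": target,
                        "stratum_a": sa,
                        "stratum_b": sb,
                        "mean_diff": float((both[sa] - both[sb]).mean()),
                        "t": float(res.statistic),
                        "p": float(res.pvalue),
                        "n_subjects": len(both),
                    }
                )
    stratum_tests = pd.DataFrame(
        test_rows,
        columns=["feature_set", "classifier", "target", "stratum_a", "stratum_b",
                 "mean_diff", "t", "p", "n_subjects"],
    )
    return EvalReport(cells=cells, per_subject=per_subject, stratum_tests=stratum_tests)
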