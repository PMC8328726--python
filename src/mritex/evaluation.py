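"""Repeated random-split classification evaluation of feature families.

For each of ``repeats`` independent rounds the cohort is split into
stratified train/test parts, features are standardized on the train
part only, a linear classifier is fitted and its test accuracy and AUC
are recorded.  The report holds the per-repeat raw scores alongside the
mean +/- std summaries, so the summaries can always be recomputed and
audited.  The AUC is the Mann-Whitney statistic: the probability that a
random positive is scored above a random negative, ties counting 1/2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)

__all__ = [
    "Classifier",
    "EvalProtocol",
    "FamilyResult",
    "EvalReport",
    "auc",
    "repeated_split_eval",
    "family_comparison",
]


class Classifier(str, Enum):
    LOGISTIC = "logistic"
    LINEAR_SVM = "linear_svm"
    LDA = "lda"


@dataclass(frozen=True)
class EvalProtocol:
    repeats: int = 100
    test_fraction: float = 0.3
    stratified: bool = True
    classifier: Classifier = Classifier.LOGISTIC
    seed: int = 0
    standardize: bool = True

    def validate(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")

    def split_seeds(self) -> np.ndarray:
        """Per-repeat seeds derived from the master seed (audit trail)."""
        ss = np.random.SeedSequence(self.seed)
        return ss.generate_state(self.repeats) % (2**31)


@dataclass(frozen=True)
class FamilyResult:
    family: str
    accuracies: np.ndarray
    aucs: np.ndarray
    split_seeds: np.ndarray
    n_dropped_rows: int = 0

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def std_accuracy(self) -> float:
        return float(self.accuracies.std())

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def std_auc(self) -> float:
        return float(self.aucs.std())


@dataclass(frozen=True)
class EvalReport:
    results: Dict[str, FamilyResult]
    protocol: EvalProtocol

    @property
    def ranking(self) -> List[str]:
        """Families ordered best-first by mean accuracy (ties by AUC)."""
        return sorted(
            self.results,
            key=lambda f: (self.results[f].mean_accuracy, self.results[f].mean_auc),
            reverse=True,
        )

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "family": f,
                "mean_accuracy": r.mean_accuracy,
                "std_accuracy": r.std_accuracy,
                "mean_auc": r.mean_auc,
                "std_auc": r.std_auc,
            }
            for f, r in self.results.items()
        ]
        df = pd.DataFrame(rows).set_index("family")
        return df.loc[self.ranking]


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg), ties count 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _make_classifier(kind: Classifier):
    if kind == Classifier.LOGISTIC:
        return LogisticRegression(max_iter=2000)
    if kind == Classifier.LINEAR_SVM:
        return LinearSVC()
    return LinearDiscriminantAnalysis()


def _scores_for_auc(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)[:, 1]
    return clf.decision_function(X)


def repeated_split_eval(
    X: np.ndarray,
    labels: Sequence,
    protocol: EvalProtocol = EvalProtocol(),
    family: str = "features",
) -> FamilyResult:
    """Mean +/- std accuracy and AUC over repeated stratified splits.

    Rows containing undefined-feature sentinels (NaN) are dropped and
    logged before splitting.  Requires at least 4 samples per class.
    """
    protocol.validate()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    y = pd.factorize(np.asarray(labels), sort=True)[0]
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")

    keep = ~np.isnan(X).any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d rows with undefined features", n_dropped)
        X, y = X[keep], y[keep]
    counts = np.bincount(y)
    if counts.min() < 4:
        raise ValueError("need >= 4 samples per class for repeated splits")

    seeds = protocol.split_seeds()
    accs = np.empty(protocol.repeats)
    aucs = np.empty(protocol.repeats)
    for r, s in enumerate(seeds):
        X_tr, X_te, y_tr, y_te = train_test_split(
            X,
            y,
            test_size=protocol.test_fraction,
            random_state=int(s),
            stratify=y if protocol.stratified else None,
        )
        if protocol.standardize:
            scaler = StandardScaler().fit(X_tr)
            X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
        clf = _make_classifier(protocol.classifier)
        clf.fit(X_tr, y_tr)
        accs[r] = float(np.mean(clf.predict(X_te) == y_te))
        aucs[r] = auc(_scores_for_auc(clf, X_te), y_te)
    return FamilyResult(
        family=family,
        accuracies=accs,
        aucs=aucs,
        split_seeds=seeds,
        n_dropped_rows=n_dropped,
    )


def plot_family_comparison(report: "EvalReport", path) -> None:
    """Bar chart of mean accuracy per family with std error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.summary()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(df.index, df["mean_accuracy"], yerr=df["std_accuracy"], capsize=4)
    ax.set_ylabel("mean accuracy over repeats")
    ax.set_ylim(0, 1.05)
    ax.axhline(0.5, color="gray", lw=0.8, ls="--")
    fig.autofmt_xdate(rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def family_comparison(
    feature_table: pd.DataFrame,
    labels: Sequence,
    protocol: EvalProtocol = EvalProtocol(),
    families: Optional[Dict[str, List[str]]] = None,
) -> EvalReport:
    """Run the repeated-split protocol per feature family and for ALL.

    ``feature_table`` is the cohort feature matrix (one row per sample);
    ``families`` maps family name -> column list and defaults to the
    table's ``attrs['families']`` as produced by
    :func:`mritex.features.cohort_feature_table`.
    """
    if families is None:
        families = feature_table.attrs.get("families")
    if not families or len(families) < 2:
        raise ValueError("need at least two feature families to compare")
    results = {}
    for fam, cols in families.items():
        results[fam] = repeated_split_eval(
            feature_table[cols].to_numpy(), labels, protocol, family=fam
        )
    return EvalReport(results=results, protocol=protocol)
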