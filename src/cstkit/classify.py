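"""Nearest-centroid assignment of samples to community state types.

A sample's relative-abundance profile is scored against every reference
sub-CST centroid with Yue-Clayton theta; the centroid with the highest
score wins. The sub-CST is rolled up to the seven-CST scheme
(I, II, III, IV-A, IV-B, IV-C, V), and the winning score — together with
the margin over the runner-up — gauges confidence in the assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from .errors import DegenerateCompositionError, ValidationError
from .similarity import similarity_profile, theta_matrix
from .taxa_io import CentroidSet, CountTable, to_relative_abundance, union_vocabulary

#: Canonical 13 sub-CSTs, in the conventional reporting order.
SUB_CST_LABELS = (
    "I-A",
    "I-B",
    "II",
    "III-A",
    "III-B",
    "IV-A",
    "IV-B",
    "IV-C0",
    "IV-C1",
    "IV-C2",
    "IV-C3",
    "IV-C4",
    "V",
)

#: Seven-CST scheme obtained by collapsing the subtypes of I, III and IV-C.
CST_LABELS = ("I", "II", "III", "IV-A", "IV-B", "IV-C", "V")

_ROLLUP = {
    "I-A": "I",
    "I-B": "I",
    "II": "II",
    "III-A": "III",
    "III-B": "III",
    "IV-A": "IV-A",
    "IV-B": "IV-B",
    "IV-C0": "IV-C",
    "IV-C1": "IV-C",
    "IV-C2": "IV-C",
    "IV-C3": "IV-C",
    "IV-C4": "IV-C",
    "V": "V",
}


def rollup(sub_cst: str) -> str:
    """Collapse a sub-CST label to the seven-CST scheme.

    I-A/I-B -> I; III-A/III-B -> III; IV-C0..IV-C4 -> IV-C; II, V, IV-A and
    IV-B map to themselves.
    """
    try:
        return _ROLLUP[sub_cst]
    except KeyError:
        raise ValidationError(f"unknown sub-CST label {sub_cst!r}") from None


@dataclass
class ClassificationResult:
    """Assignment of one sample: winning sub-CST, rollup, and all scores."""

    sample_id: str
    sub_cst: str
    cst: str
    assigned_score: float
    score_array: pd.Series
    low_confidence: bool
    tied: bool = False


class YueClaytonNearestCentroid(BaseEstimator, ClassifierMixin):
    """Nearest-centroid classifier under Yue-Clayton theta similarity.

    Can be fit from labelled relative-abundance profiles (centroids are
    per-class means, as in training) or constructed directly from a
    reference :class:`CentroidSet` via :meth:`from_centroid_set`.

    Parameters
    ----------
    low_conf_threshold : float, default 0.5
        Assignments whose winning score falls below this are flagged
        low-confidence.
    margin : float, default 0.1
        Assignments whose top-two score gap falls below this are flagged
        low-confidence (the sample sits in the grey zone between types).

    Attributes
    ----------
    centroid_set_ : CentroidSet
        The reference centroids used for scoring.
    classes_ : ndarray of str
        Centroid labels, in file/training order.
    """

    def __init__(self, low_conf_threshold: float = 0.5, margin: float = 0.1):
        self.low_conf_threshold = low_conf_threshold
        self.margin = margin

    # -- construction ------------------------------------------------------
    def fit(self, X: pd.DataFrame, y) -> "YueClaytonNearestCentroid":
        """Compute per-class mean centroids from labelled profiles."""
        from .training import build_centroids

        X = _as_profile_frame(X)
        self.centroid_set_ = build_centroids(X, pd.Series(np.asarray(y), index=X.index))
        self.classes_ = np.asarray(self.centroid_set_.labels)
        return self

    @classmethod
    def from_centroid_set(cls, centroid_set: CentroidSet, **params) -> "YueClaytonNearestCentroid":
        """Build an already-fitted classifier around reference centroids."""
        est = cls(**params)
        est.centroid_set_ = centroid_set
        est.classes_ = np.asarray(centroid_set.labels)
        return est

    def _check_fitted(self) -> None:
        if not hasattr(self, "centroid_set_"):
            raise NotFittedError(
                "this YueClaytonNearestCentroid instance is not fitted yet"
            )

    # -- scoring -----------------------------------------------------------
    def predict_similarity(self, X: pd.DataFrame) -> pd.DataFrame:
        """theta of every sample against every centroid (samples x labels)."""
        self._check_fitted()
        X = _as_profile_frame(X)
        scores = theta_matrix(X, self.centroid_set_.centroids)
        return pd.DataFrame(scores, index=X.index, columns=self.classes_)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Winning sub-CST label per sample (ties -> first centroid in order)."""
        sims = self.predict_similarity(X)
        return self.classes_[np.argmax(sims.to_numpy(), axis=1)]

    def assign_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        """Full assignment table: subCST, CST, score, flags and all scores."""
        sims = self.predict_similarity(X)
        return _assignments_from_scores(sims, self.low_conf_threshold, self.margin)

    def score(self, X: pd.DataFrame, y) -> float:
        """Mean accuracy of sub-CST prediction against labels *y*."""
        return float(np.mean(self.predict(X) == np.asarray(y)))


def _as_profile_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.atleast_2d(np.asarray(X, dtype=float))
    return pd.DataFrame(arr)


def _assignments_from_scores(
    sims: pd.DataFrame, low_conf_threshold: float, margin: float
) -> pd.DataFrame:
    scores = sims.to_numpy()
    order = np.argsort(-scores, axis=1)
    best = order[:, 0]
    labels = sims.columns.to_numpy()
    # argsort is stable on the negated scores, so exact ties resolve to the
    # first centroid in file order; argmax would do the same, but we need the
    # runner-up anyway for the margin flag.
    assigned = labels[best]
    top = scores[np.arange(len(scores)), best]
    if scores.shape[1] > 1:
        second = scores[np.arange(len(scores)), order[:, 1]]
    else:
        second = np.full(len(scores), -np.inf)
    tied = top == second
    low_conf = (top < low_conf_threshold) | (top - second < margin)
    out = pd.DataFrame(index=sims.index)
    out["subCST"] = assigned
    out["CST"] = [rollup(s) if s in _ROLLUP else s for s in assigned]
    out["score"] = top
    out["low_confidence"] = low_conf
    out["tied"] = tied
    for label in sims.columns:
        out[f"{label}_sim"] = sims[label]
    return out


def assign(
    sample: pd.Series,
    centroids: CentroidSet,
    low_conf_threshold: float = 0.5,
    margin: float = 0.1,
    sample_id: str = "",
) -> ClassificationResult:
    """Assign one composition vector to its nearest centroid.

    Raises :class:`DegenerateCompositionError` (carrying *sample_id*) for an
    all-zero or off-simplex vector.
    """
    try:
        profile = similarity_profile(sample, centroids)
    except DegenerateCompositionError as exc:
        raise DegenerateCompositionError(f"sample {sample_id!r}: {exc}") from exc
    scores = profile.to_numpy()
    best = int(np.argmax(scores))  # ties -> first centroid in file order
    top = float(scores[best])
    second = float(np.partition(scores, -2)[-2]) if len(scores) > 1 else -np.inf
    sub = str(profile.index[best])
    return ClassificationResult(
        sample_id=sample_id,
        sub_cst=sub,
        cst=rollup(sub) if sub in _ROLLUP else sub,
        assigned_score=top,
        score_array=profile,
        low_confidence=(top < low_conf_threshold) or (top - second < margin),
        tied=top == second,
    )


@dataclass
class QCSummary:
    """Per-sub-CST similarity-score distributions and reference comparison."""

    scores: dict[str, list[float]]
    medians: dict[str, float]
    reference_medians: dict[str, float] | None = None
    flagged: list[str] = field(default_factory=list)
    gap: float = 0.2


def classify_table(
    table: CountTable,
    centroids: CentroidSet,
    low_conf_threshold: float = 0.5,
    margin: float = 0.1,
    denominator: str = "row_sum",
    reference_medians: pd.Series | None = None,
) -> tuple[pd.DataFrame, QCSummary, dict[str, str]]:
    """Classify every sample of a count table against reference centroids.

    Each sample is treated independently (classifying a single-row table
    gives the identical result as classifying the same sample inside any
    larger table). Per-sample failures (e.g. all-zero rows) are collected
    and reported; the run continues for the remaining samples.

    Returns
    -------
    (annotated, qc, failures)
        ``annotated`` preserves the input columns (``read_count`` plus taxa
        counts) and appends ``subCST``, ``CST``, ``score``,
        ``low_confidence`` and one ``<label>_sim`` column per centroid.
        ``failures`` maps sample id -> error message.
    """
    failures: dict[str, str] = {}
    if table.n_samples == 0:
        warnings.warn("empty count table: nothing to classify", UserWarning, stacklevel=2)
        empty = pd.DataFrame(index=table.counts.index)
        return empty, QCSummary(scores={}, medians={}), failures

    row_sums = table.counts.sum(axis=1)
    degenerate = row_sums <= 0
    for sid in table.counts.index[degenerate]:
        failures[str(sid)] = "all-zero taxa counts"
    ok = table.counts.index[~degenerate]

    sub = CountTable(table.counts.loc[ok], table.declared_totals.loc[ok])
    props, _ = to_relative_abundance(sub, denominator=denominator)
    clf = YueClaytonNearestCentroid.from_centroid_set(
        centroids, low_conf_threshold=low_conf_threshold, margin=margin
    )
    assignments = clf.assign_frame(props)

    annotated = table.counts.copy()
    annotated.insert(0, "read_count", table.declared_totals)
    annotated = annotated.join(assignments, how="left")

    qc = qc_report(assignments, reference_medians=reference_medians)
    return annotated, qc, failures


def qc_report(
    assignments: pd.DataFrame,
    reference_medians: pd.Series | None = None,
    gap: float = 0.2,
) -> QCSummary:
    """Summarise assigned-score distributions per sub-CST.

    When *reference_medians* (the training dataset's median assigned score
    per sub-CST) is given, sub-CSTs whose dataset median falls below the
    reference median by more than *gap* are flagged — a hint that taxon
    names are incongruent or that the dataset holds communities without a
    matching centroid. Without reference medians the summary is produced
    with a warning and no comparison.
    """
    if len(assignments) == 0:
        raise ValueError("need at least one classified sample")
    grouped = assignments.groupby("subCST")["score"]
    scores = {str(k): list(v) for k, v in grouped}
    medians = {str(k): float(v.median()) for k, v in grouped}
    if reference_medians is None:
        warnings.warn(
            "no reference medians supplied; QC report has no comparison",
            UserWarning,
            stacklevel=2,
        )
        return QCSummary(scores=scores, medians=medians, gap=gap)
    ref = {str(k): float(v) for k, v in reference_medians.items()}
    flagged = [
        label
        for label, med in medians.items()
        if label in ref and med < ref[label] - gap
    ]
    return QCSummary(
        scores=scores, medians=medians, reference_medians=ref, flagged=flagged, gap=gap
    )


def qc_figure(qc: QCSummary, path: str) -> None:
    """Render the QC report as a per-sub-CST score-distribution figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = sorted(qc.scores)
    data = [qc.scores[label] for label in labels]
    fig, ax = plt.subplots(figsize=(max(6, 0.8 * len(labels)), 4))
    ax.boxplot(data, tick_labels=labels)
    if qc.reference_medians:
        for i, label in enumerate(labels, start=1):
            if label in qc.reference_medians:
                ax.hlines(
                    qc.reference_medians[label], i - 0.35, i + 0.35,
                    colors="red", linestyles="dashed", linewidth=1,
                )
    ax.set_ylabel("similarity to assigned centroid (theta)")
    ax.set_xlabel("assigned sub-CST")
    ax.set_ylim(0, 1.05)
    fig.autofmt_xdate(rotation=45)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
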