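"""Evaluation metrics and baseline comparator estimators.

Regression accuracy is scored by R^2 (one minus the ratio of residual to
total sum of squares, which can be arbitrarily negative for a bad
estimator).  High/low biomarker classification — high iff the true
value is at or above the clinical threshold (300 exome mutations for
TMB, 10 indels for TIB) — is scored by the area under the
precision-recall curve swept over score thresholds, and by ROC AUC.

Three baselines are provided: naive count rescaling by exome/panel
length, the indel-fraction count rescaling for TIB, and an ordinary
least-squares regression of the biomarker on per-gene panel counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .mutation_data import BiomarkerSpec, CountTensor, GeneCatalog
from .panel_selection import Panel


@dataclass(frozen=True)
class EvalResult:
    """Bundle of regression and classification scores for one estimator."""

    r2: float
    auprc: float
    auroc: float
    n: int
    prevalence: float


def r_squared(truth: np.ndarray, pred: np.ndarray) -> float:
    """R^2 = 1 - SS_res / SS_tot; unbounded below for poor predictors."""
    truth = np.asarray(truth, float)
    pred = np.asarray(pred, float)
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ValueError("truth and predictions must be equal-length 1-d")
    if truth.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(((truth - truth.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("truth values are all equal; R^2 undefined")
    ss_res = float(((truth - pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def pr_curve_auprc(scores: np.ndarray,
                   labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Precision-recall curve and AUPRC for the rule "score >= t".

    Thresholds sweep the distinct scores (plus +infinity, whose 0/0
    precision point is dropped); tied scores flip together.  The area is
    the right-continuous step integral sum (r_k - r_{k-1}) * p_k over
    thresholds in decreasing order, so a perfect ranking scores 1 and a
    random one averages the positive-class prevalence.

    Returns an array of (threshold, recall, precision) rows and the area.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("no positive labels; precision-recall undefined")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    tp = np.cumsum(l_sorted)
    pp = np.arange(1, len(scores) + 1)
    # collapse ties: keep the last index of each run of equal scores
    last = np.flatnonzero(np.r_[np.diff(s_sorted) != 0, True])
    recall = tp[last] / n_pos
    precision = tp[last] / pp[last]
    curve = np.column_stack([s_sorted[last], recall, precision])
    r_prev = np.r_[0.0, recall[:-1]]
    auprc = float(((recall - r_prev) * precision).sum())
    return curve, auprc


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC (equivalently the normalized Mann-Whitney U statistic)."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for ROC AUC")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def high_class_labels(truth: np.ndarray, spec: BiomarkerSpec) -> np.ndarray:
    """High-biomarker class labels: true value >= the clinical threshold."""
    return np.asarray(truth, float) >= spec.class_threshold


def evaluate(truth: np.ndarray, pred: np.ndarray,
             spec: BiomarkerSpec) -> EvalResult:
    """Score predictions by R^2, AUPRC and ROC AUC against one biomarker."""
    labels = high_class_labels(truth, spec)
    _, auprc = pr_curve_auprc(pred, labels)
    return EvalResult(r2=r_squared(truth, pred), auprc=auprc,
                      auroc=roc_auc(pred, labels), n=len(truth),
                      prevalence=float(np.mean(labels)))


def count_estimator(test_counts: CountTensor, panel: Panel,
                    lengths: GeneCatalog, spec: BiomarkerSpec) -> np.ndarray:
    """Length-rescaled panel count: (l_G / l_P) * sum_{g in P, s in Sbar} M."""
    if len(panel) == 0:
        raise ValueError("count estimator undefined for an empty panel")
    rows = [test_counts.genes.index(g) for g in panel.genes]
    cols = [test_counts.group_index(s) for s in spec.target_groups]
    inside = test_counts.counts[:, rows][:, :, cols].sum(axis=(1, 2))
    return (lengths.total_length / panel.total_length) * inside.astype(float)


def tib_count_estimator(test_counts: CountTensor, train_counts: CountTensor,
                        panel: Panel, lengths: GeneCatalog,
                        indel_group: str = "indel") -> np.ndarray:
    """Indel-fraction count baseline for TIB.

    Rescales each test sample's total panel mutation count (all groups)
    by the exome/panel length ratio and by the training-set relative
    frequency of indel versus all non-synonymous mutations.
    """
    if len(panel) == 0:
        raise ValueError("count estimator undefined for an empty panel")
    total_train = float(train_counts.counts.sum())
    if total_train == 0:
        raise ValueError("training tensor has no mutations")
    indel_train = float(
        train_counts.counts[:, :, train_counts.group_index(indel_group)].sum())
    frac = indel_train / total_train
    rows = [test_counts.genes.index(g) for g in panel.genes]
    inside = test_counts.counts[:, rows].sum(axis=(1, 2)).astype(float)
    return (lengths.total_length / panel.total_length) * frac * inside


class LinearBaseline:
    """OLS regression of the biomarker on per-gene summed panel counts.

    With an empty panel this degrades to an intercept-only model; rank
    deficiency falls back to the minimum-norm least-squares solution
    with a warning.
    """

    def __init__(self, panel: Panel):
        self.panel = panel
        self.coef_: np.ndarray | None = None
        self.intercept_: float | None = None

    def _design(self, counts: CountTensor) -> np.ndarray:
        if len(self.panel) == 0:
            return np.empty((counts.n_samples, 0))
        rows = [counts.genes.index(g) for g in self.panel.genes]
        return counts.counts[:, rows].sum(axis=2).astype(float)

    def fit(self, train_counts: CountTensor,
            train_T: np.ndarray) -> "LinearBaseline":
        X = self._design(train_counts)
        y = np.asarray(train_T, float)
        A = np.column_stack([np.ones(len(y)), X])
        if len(y) <= X.shape[1] + 1 or np.linalg.matrix_rank(A) < A.shape[1]:
            warnings.warn("rank-deficient design; using the minimum-norm "
                          "least-squares fit", stacklevel=2)
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        return self

    def predict(self, counts: CountTensor) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("fit before predict")
        return self.intercept_ + self._design(counts) @ self.coef_


def linear_baseline(train_counts: CountTensor, train_T: np.ndarray,
                    panel: Panel) -> LinearBaseline:
    """Fit the OLS panel-count baseline and return the predictor."""
    return LinearBaseline(panel).fit(train_counts, train_T)
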