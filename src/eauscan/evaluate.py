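"""Tenfold cross-validation and the metric/confidence-interval report.

Each cross-validation round holds out ~10% of the images as a test set,
~15% as validation for early stopping and trains on the remaining ~75%; a
fresh model is built per fold and each image's probability is taken from
the single fold in which it was held out, accumulating into one prediction
vector over the whole dataset. Probabilities are thresholded at 0.5
(probability exactly 0.5 classifies as abnormal) and summarized as a
confusion matrix with the abnormal (cancer) class positive.

Proportion metrics carry 95% Wilson score intervals (z = 1.96); the AUC
interval uses DeLong's method. Undefined proportions (zero denominator)
are reported as None rather than raised.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Optional

import numpy as np
from sklearn import metrics as _skm
from sklearn.model_selection import GroupKFold, KFold, StratifiedGroupKFold, StratifiedKFold, train_test_split

log = logging.getLogger("eauscan")

Z95 = 1.96


# ---------------------------------------------------------------------------
# Fold planning

@dataclass
class FoldPlan:
    k: int
    folds: list[dict[str, np.ndarray]]  # each: {"train","val","test"} index arrays
    assignments: np.ndarray  # per-image test-fold index
    stratified: bool
    group_by_patient: bool
    seed: int

    def validate(self, n: int, patient_ids: Optional[np.ndarray] = None) -> None:
        """Audit the partition invariants (raises on violation)."""
        all_test = np.concatenate([f["test"] for f in self.folds])
        if sorted(all_test.tolist()) != list(range(n)):
            raise ValueError("test sets do not partition the dataset")
        for i, f in enumerate(self.folds):
            tr, va, te = (set(f[s].tolist()) for s in ("train", "val", "test"))
            if tr & va or tr & te or va & te:
                raise ValueError(f"fold {i}: train/val/test sets overlap")
            if tr | va | te != set(range(n)):
                raise ValueError(f"fold {i}: sets do not cover the dataset")
            if self.group_by_patient and patient_ids is not None:
                for a, b in ((tr, va), (tr, te), (va, te)):
                    shared = set(patient_ids[list(a)]) & set(patient_ids[list(b)])
                    if shared:
                        raise ValueError(f"fold {i}: patients {shared} span two sets")


def make_fold_plan(
    labels,
    patient_ids=None,
    k: int = 10,
    stratified: bool = True,
    group_by_patient: bool = False,
    seed: int = 0,
    val_fraction: float = 15.0 / 90.0,
) -> FoldPlan:
    """Partition image indices into k rounds of ~75/15/10 train/val/test splits."""
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} images, got {n}")
    groups = np.asarray(patient_ids) if patient_ids is not None else None
    if group_by_patient:
        if groups is None:
            raise ValueError("group_by_patient requires patient_ids")
        counts = np.unique(groups, return_counts=True)[1]
        if (counts > n / k).any():
            warnings.warn("a patient owns more than 1/k of all images; grouped folds will be unbalanced")
        splitter = (
            StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
            if stratified
            else GroupKFold(n_splits=k)
        )
        split_iter = splitter.split(np.zeros(n), labels, groups)
    elif stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n), labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n))

    folds = []
    assignments = np.full(n, -1, dtype=int)
    for fold_idx, (rest, test) in enumerate(split_iter):
        if group_by_patient:
            rest_groups = groups[rest]
            uniq = np.unique(rest_groups)
            rng = np.random.default_rng(seed + fold_idx)
            uniq = rng.permutation(uniq)
            n_val_groups = max(1, round(val_fraction * len(uniq)))
            val_groups = set(uniq[:n_val_groups].tolist())
            val_mask = np.isin(rest_groups, list(val_groups))
            val, train = rest[val_mask], rest[~val_mask]
        else:
            stratify = labels[rest] if stratified else None
            train, val = train_test_split(
                rest, test_size=val_fraction, stratify=stratify, random_state=seed + fold_idx
            )
        folds.append({"train": np.sort(train), "val": np.sort(val), "test": np.sort(test)})
        assignments[test] = fold_idx
    plan = FoldPlan(
        k=k,
        folds=folds,
        assignments=assignments,
        stratified=stratified,
        group_by_patient=group_by_patient,
        seed=seed,
    )
    plan.validate(n, groups)
    return plan


# ---------------------------------------------------------------------------
# Cross-validation driver

def run_cross_validation(
    images: list,
    labels,
    plan: FoldPlan,
    model_factory: Callable[[int], object],
) -> tuple[np.ndarray, list]:
    """Train a fresh model per fold; accumulate held-out probabilities.

    ``model_factory(fold_idx)`` must return an unfitted estimator exposing
    ``fit(X, y, X_val=, y_val=)`` and ``predict_proba``. Returns the
    accumulated prediction vector (one probability per image, taken from
    the fold where the image was in the test set) and per-fold histories.
    """
    labels = np.asarray(labels)
    n = len(labels)
    vector = np.full(n, np.nan)
    histories = []
    for fold_idx, fold in enumerate(plan.folds):
        tr, va, te = fold["train"], fold["val"], fold["test"]
        # leakage guard: a test image must never touch its fold's training
        if set(te.tolist()) & (set(tr.tolist()) | set(va.tolist())):
            raise RuntimeError(f"fold {fold_idx}: leakage between test and train/val sets")
        try:
            model = model_factory(fold_idx)
            model.fit(
                [images[i] for i in tr], labels[tr],
                X_val=[images[i] for i in va], y_val=labels[va],
            )
            probs = np.asarray(model.predict_proba([images[i] for i in te]))
            if probs.ndim == 2:
                probs = probs[:, -1]
        except Exception as exc:
            raise RuntimeError(f"cross-validation aborted in fold {fold_idx}: {exc}") from exc
        vector[te] = probs
        histories.append(getattr(model, "history_", None))
        log.info("fold %d/%d done (%d test images)", fold_idx + 1, plan.k, len(te))
    if np.isnan(vector).any():
        raise RuntimeError("prediction vector has gaps; folds did not cover the dataset")
    return vector, histories


# ---------------------------------------------------------------------------
# Confusion matrix and proportion metrics

@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def binarize_predictions(vector, threshold: float = 0.5) -> np.ndarray:
    """Probability >= threshold classifies as abnormal (1)."""
    return (np.asarray(vector, dtype=float) >= threshold).astype(int)


def confusion(labels, decisions) -> ConfusionMatrix:
    """Confusion counts with abnormal (label 1) as the positive class."""
    labels = np.asarray(labels).astype(int)
    decisions = np.asarray(decisions).astype(int)
    if labels.shape != decisions.shape:
        raise ValueError("labels and decisions length mismatch")
    if labels.size == 0:
        return ConfusionMatrix(0, 0, 0, 0)
    cm = _skm.confusion_matrix(labels, decisions, labels=[1, 0])
    return ConfusionMatrix(tp=int(cm[0, 0]), fn=int(cm[0, 1]), fp=int(cm[1, 0]), tn=int(cm[1, 1]))


def proportion_metrics(cm: ConfusionMatrix) -> dict[str, Optional[float]]:
    """Accuracy, sensitivity, specificity, precision and NPV as point values.

    A zero denominator yields None (undefined), not an exception.
    """
    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    return {
        "accuracy": ratio(cm.tp + cm.tn, cm.n),
        "sensitivity": ratio(cm.tp, cm.tp + cm.fn),
        "specificity": ratio(cm.tn, cm.fp + cm.tn),
        "precision": ratio(cm.tp, cm.tp + cm.fp),
        "npv": ratio(cm.tn, cm.tn + cm.fn),
    }


def metric_denominators(cm: ConfusionMatrix) -> dict[str, tuple[int, int]]:
    """(successes, trials) pairs behind each proportion metric."""
    return {
        "accuracy": (cm.tp + cm.tn, cm.n),
        "sensitivity": (cm.tp, cm.tp + cm.fn),
        "specificity": (cm.tn, cm.fp + cm.tn),
        "precision": (cm.tp, cm.tp + cm.fp),
        "npv": (cm.tn, cm.tn + cm.fn),
    }


def wilson_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion (z = 1.96 at 95%)."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not (0 <= successes <= trials):
        raise ValueError("successes must lie in [0, trials]")
    if level != 0.95:
        from scipy.stats import norm

        z = float(norm.ppf(0.5 + level / 2))
    else:
        z = Z95
    p = successes / trials
    denom = 1 + z**2 / trials
    center = (p + z**2 / (2 * trials)) / denom
    half = (z / denom) * np.sqrt(p * (1 - p) / trials + z**2 / (4 * trials**2))
    return (max(0.0, center - half), min(1.0, center + half))


# ---------------------------------------------------------------------------
# ROC / AUC

def roc_curve(labels, probabilities) -> list[tuple[float, float, float]]:
    """(fpr, tpr, threshold) points from (0,0) to (1,1); tied scores move together."""
    fpr, tpr, thr = _skm.roc_curve(np.asarray(labels).astype(int), np.asarray(probabilities, dtype=float))
    return list(zip(fpr.tolist(), tpr.tolist(), thr.tolist()))


def auc(roc: list[tuple[float, float, float]]) -> float:
    """Trapezoidal area under an ROC point list."""
    fpr = np.array([p[0] for p in roc])
    tpr = np.array([p[1] for p in roc])
    return float(np.trapezoid(tpr, fpr))


def delong_auc_ci(labels, probabilities, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """AUC with a DeLong confidence interval (normal approximation on the
    structural-component variance)."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(probabilities, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("DeLong CI requires both classes present")
    # placement values via midranks
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    a = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    from scipy.stats import norm

    z = float(norm.ppf(0.5 + level / 2))
    return a, (max(0.0, a - z * se), min(1.0, a + z * se))


# ---------------------------------------------------------------------------
# Report

@dataclass
class MetricsReport:
    cm: ConfusionMatrix
    metrics: dict[str, Optional[float]]
    cis: dict[str, Optional[tuple[float, float]]]
    auc: Optional[float]
    auc_ci: Optional[tuple[float, float]]
    roc: list[tuple[float, float, float]]
    n: dict[str, tuple[int, int]] = field(default_factory=dict)

    def render_table(self) -> str:
        """CSV table of metric, value and 95% CI at 3 decimals (half-up)."""

        def fmt(x: Optional[float]) -> str:
            if x is None:
                return "NA"
            return str(Decimal(repr(float(x))).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))

        buf = io.StringIO()
        buf.write("metric,value,ci_lower,ci_upper\n")
        if self.auc is not None:
            lo, hi = self.auc_ci if self.auc_ci else (None, None)
            buf.write(f"auc,{fmt(self.auc)},{fmt(lo)},{fmt(hi)}\n")
        else:
            buf.write("auc,NA,NA,NA\n")
        for name in ("accuracy", "sensitivity", "specificity", "precision", "npv"):
            value = self.metrics[name]
            ci = self.cis[name]
            lo, hi = ci if ci else (None, None)
            buf.write(f"{name},{fmt(value)},{fmt(lo)},{fmt(hi)}\n")
        return buf.getvalue()


def metrics_report(labels, vector, threshold: float = 0.5) -> MetricsReport:
    """Assemble the full report: confusion, Wilson-bounded proportions, ROC, AUC."""
    labels = np.asarray(labels).astype(int)
    vector = np.asarray(vector, dtype=float)
    if not np.isfinite(vector).all() or (vector < 0).any() or (vector > 1).any():
        raise ValueError("prediction vector must contain finite probabilities in [0, 1]")
    cm = confusion(labels, binarize_predictions(vector, threshold))
    mets = proportion_metrics(cm)
    denoms = metric_denominators(cm)
    cis = {
        name: (wilson_ci(k, n) if n > 0 else None) for name, (k, n) in denoms.items()
    }
    both_classes = 0 < labels.sum() < len(labels)
    if both_classes:
        roc = roc_curve(labels, vector)
        a, a_ci = delong_auc_ci(labels, vector)
    else:
        roc, a, a_ci = [], None, None
    return MetricsReport(cm=cm, metrics=mets, cis=cis, auc=a, auc_ci=a_ci, roc=roc, n=denoms)
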