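"""Subject-independent evaluation: leave-one-out / leave-one-subject-out
cross-validation, confusion-matrix metrics with inter-class spread,
one-vs-rest ROC with micro/macro averaging, probability timelines and t-SNE
projection.

Fold predictions are pooled before computing the report (rather than
averaging per-fold matrices), so the confusion matrix entries sum to N and
accuracy equals the pooled trace ratio. Per-fold training seeds are derived
from the master seed so each fold is independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from sklearn.manifold import TSNE
from sklearn.metrics import auc, roc_curve

from .simulate import Recording


@dataclass(frozen=True)
class CVPlan:
    """Cross-validation plan.

    ``mode='loro'`` is leave-one-recording-out (k = N, every recording is the
    test set exactly once); ``mode='loso'`` groups folds by subject so no
    subject spans train and test of the same fold — the subject-independent
    protocol.
    """

    mode: str = "loso"

    def __post_init__(self) -> None:
        if self.mode not in ("loro", "loso"):
            raise ValueError("mode must be 'loro' or 'loso'")

    def folds(self, groups: Sequence[str]) -> list[np.ndarray]:
        groups = np.asarray(groups)
        n = groups.size
        if self.mode == "loro":
            return [np.array([i]) for i in range(n)]
        return [np.flatnonzero(groups == g) for g in
                sorted(set(groups.tolist()))]


@dataclass
class EvalReport:
    """Pooled cross-validation report."""

    labels: list[str]
    confusion_matrix: np.ndarray
    accuracy: float
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    macro_std: dict[str, float]
    per_class_auc: dict[str, float] = field(default_factory=dict)
    micro_auc: float = float("nan")
    macro_auc: float = float("nan")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["confusion_matrix"] = self.confusion_matrix.tolist()
        return d


def _take(X, idx: np.ndarray):
    if isinstance(X, (tuple, list)):
        return tuple(np.asarray(a)[idx] for a in X)
    return np.asarray(X)[idx]


def confusion_matrix_counts(y_true: np.ndarray, y_pred: np.ndarray,
                            labels: Sequence[str]) -> np.ndarray:
    """Counts with rows = true class, columns = predicted class."""
    index = {lab: i for i, lab in enumerate(labels)}
    cm = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


def prf_metrics(cm: np.ndarray, labels: Sequence[str] | None = None) -> dict:
    """Per-class one-vs-rest precision/recall/F1 plus unweighted macro means
    and the inter-class standard deviation of each metric. 0/0 cases map
    to 0."""
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero")
    k = cm.shape[0]
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    diag = np.diag(cm).astype(float)
    col = cm.sum(axis=0).astype(float)
    row = cm.sum(axis=1).astype(float)
    precision = np.divide(diag, col, out=np.zeros(k), where=col > 0)
    recall = np.divide(diag, row, out=np.zeros(k), where=row > 0)
    pr = precision + recall
    f1 = np.divide(2 * precision * recall, pr, out=np.zeros(k), where=pr > 0)
    per_class = {lab: {"precision": float(precision[i]),
                       "recall": float(recall[i]), "f1": float(f1[i])}
                 for i, lab in enumerate(labels)}
    macro = {"precision": float(precision.mean()), "recall": float(recall.mean()),
             "f1": float(f1.mean())}
    spread = {"precision": float(precision.std()), "recall": float(recall.std()),
              "f1": float(f1.std())}
    return {"per_class": per_class, "macro": macro, "macro_std": spread,
            "accuracy": float(diag.sum() / total)}


def roc_ovr(proba: np.ndarray, y_true: np.ndarray,
            labels: Sequence[str]) -> dict:
    """One-vs-rest ROC per class (empirical curve over all distinct score
    thresholds, trapezoidal AUC), plus micro (pooled binarized decisions)
    and macro (unweighted mean of per-class AUCs) averages. Classes absent
    from ``y_true`` get NaN AUC and are flagged."""
    proba = np.asarray(proba, dtype=float)
    y_true = np.asarray(y_true)
    curves: dict[str, dict] = {}
    aucs: dict[str, float] = {}
    missing: list[str] = []
    binary_all = []
    score_all = []
    for i, lab in enumerate(labels):
        pos = (y_true == lab).astype(int)
        binary_all.append(pos)
        score_all.append(proba[:, i])
        if pos.sum() == 0 or pos.sum() == pos.size:
            aucs[lab] = float("nan")
            missing.append(lab)
            continue
        fpr, tpr, _ = roc_curve(pos, proba[:, i])
        curves[lab] = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
        aucs[lab] = float(auc(fpr, tpr))
    pooled_true = np.concatenate(binary_all)
    pooled_score = np.concatenate(score_all)
    fpr_mi, tpr_mi, _ = roc_curve(pooled_true, pooled_score)
    micro = float(auc(fpr_mi, tpr_mi))
    finite = [v for v in aucs.values() if np.isfinite(v)]
    macro = float(np.mean(finite)) if finite else float("nan")
    return {"curves": curves, "per_class_auc": aucs, "micro_auc": micro,
            "macro_auc": macro, "undefined_classes": missing}


def run_cv(X, y: Sequence[str], groups: Sequence[str],
           model_builder: Callable[[int], object], plan: CVPlan,
           master_seed: int = 0) -> tuple[EvalReport, dict]:
    """Re-build and re-train the model on every fold, pool the predictions,
    and compute the EvalReport.

    ``model_builder(fold_seed)`` must return an unfitted estimator with
    fit / predict_proba / classes_. Per-fold seeds are
    ``SeedSequence([master_seed, fold])`` draws, kept below 2**31.
    """
    y = np.asarray(y)
    groups = np.asarray(groups)
    labels = sorted(set(y.tolist()))
    folds = plan.folds(groups)
    n = y.size
    assigned = np.concatenate(folds)
    if sorted(assigned.tolist()) != list(range(n)):
        raise ValueError("every recording must be in exactly one test fold")
    proba = np.zeros((n, len(labels)))
    y_pred = np.empty(n, dtype=y.dtype)
    fold_accuracies = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if plan.mode == "loso" and set(groups[train_idx]) & set(groups[test_idx]):
            raise AssertionError("subject leakage between train and test")
        if np.unique(y[train_idx]).size < 2:
            raise ValueError(f"fold {f}: training split has a single class")
        fold_seed = int(np.random.SeedSequence([master_seed, f])
                        .generate_state(1, dtype=np.uint32)[0] % (2**31))
        model = model_builder(fold_seed)
        model.fit(_take(X, train_idx), y[train_idx])
        p = model.predict_proba(_take(X, test_idx))
        # align the model's class ordering with the pooled label ordering
        order = [list(model.classes_).index(lab) for lab in labels]
        proba[test_idx] = p[:, order]
        y_pred[test_idx] = np.asarray(labels)[np.argmax(p[:, order], axis=1)]
        fold_accuracies.append(float(np.mean(y_pred[test_idx] == y[test_idx])))
    cm = confusion_matrix_counts(y, y_pred, labels)
    prf = prf_metrics(cm, labels)
    roc = roc_ovr(proba, y, labels)
    report = EvalReport(labels=labels, confusion_matrix=cm,
                        accuracy=prf["accuracy"], per_class=prf["per_class"],
                        macro=prf["macro"], macro_std=prf["macro_std"],
                        per_class_auc=roc["per_class_auc"],
                        micro_auc=roc["micro_auc"], macro_auc=roc["macro_auc"])
    details = {"proba": proba, "y_pred": y_pred, "folds": folds,
               "fold_accuracies": fold_accuracies, "roc": roc}
    return report, details


def probability_timeline(model, recording: Recording, window: float,
                         stride: float, input_builder: Callable,
                         n_interp: int = 200) -> dict:
    """Sliding-window class probabilities over one recording.

    ``input_builder(recording)`` must map a trimmed recording to the model's
    X convention. Discrete window probabilities are smoothed with monotone
    cubic interpolation, clipped to [0, 1] and renormalized so the curves
    sum to one at every time point; per-class means are reported alongside.
    """
    if stride <= 0:
        raise ValueError("stride must be positive")
    duration = recording.duration
    if duration < window:
        raise ValueError("recording shorter than window")
    starts = []
    t0 = 0.0
    while t0 + window <= duration + 1e-9:
        starts.append(t0)
        t0 += stride
    centres = np.array([s + window / 2 for s in starts])
    probs = []
    n_total = recording.time.size
    for s in starts:
        i0 = int(round(s * recording.sampling_rate))
        i1 = int(round((s + window) * recording.sampling_rate))
        i1 = min(i1, n_total)
        sub = dataclasses.replace(
            recording,
            time=recording.time[:i1 - i0],
            phase_trace=recording.phase_trace[i0:i1],
            ecg_trace=None)
        probs.append(model.predict_proba(input_builder(sub))[0])
    probs = np.asarray(probs)
    if len(starts) == 1:
        grid = centres
        smooth = probs
    else:
        grid = np.linspace(centres[0], centres[-1], n_interp)
        smooth = np.stack([PchipInterpolator(centres, probs[:, j])(grid)
                           for j in range(probs.shape[1])], axis=1)
        smooth = np.clip(smooth, 0.0, None)
        smooth /= smooth.sum(axis=1, keepdims=True)
    return {"window_centres": centres, "window_proba": probs,
            "times": grid, "proba": smooth,
            "mean_proba": probs.mean(axis=0)}


def export_report(report: EvalReport, details: dict, out_dir) -> None:
    """Write an EvalReport to disk: JSON summary, confusion-matrix and ROC
    CSVs, and PNG figures (confusion matrix heat map, ROC curves)."""
    import json
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2,
                                                sort_keys=True))
    pd.DataFrame(report.confusion_matrix, index=report.labels,
                 columns=report.labels).to_csv(out / "confusion_matrix.csv")
    rows = []
    for lab, curve in details["roc"]["curves"].items():
        for fpr, tpr in zip(curve["fpr"], curve["tpr"]):
            rows.append({"class": lab, "fpr": fpr, "tpr": tpr})
    pd.DataFrame(rows).to_csv(out / "roc_curves.csv", index=False)

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(report.confusion_matrix, cmap="Blues")
    ax.set_xticks(range(len(report.labels)), report.labels, rotation=45)
    ax.set_yticks(range(len(report.labels)), report.labels)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(len(report.labels)):
        for j in range(len(report.labels)):
            ax.text(j, i, report.confusion_matrix[i, j], ha="center",
                    va="center", fontsize=8)
    fig.colorbar(im, shrink=0.8)
    fig.tight_layout()
    fig.savefig(out / "confusion_matrix.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 4))
    for lab, curve in details["roc"]["curves"].items():
        ax.plot(curve["fpr"], curve["tpr"],
                label=f"{lab} (AUC {report.per_class_auc[lab]:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "roc_curves.png", dpi=120)
    plt.close(fig)


def tsne_project(inputs: np.ndarray, dims: int = 2, perplexity: float = 15.0,
                 seed: int = 0) -> np.ndarray:
    """2-D (or 3-D) t-SNE embedding with fixed perplexity and seed; the
    perplexity is lowered automatically for very small sample counts."""
    X = np.asarray(inputs, dtype=float)
    if X.ndim > 2:
        X = X.reshape(X.shape[0], -1)
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 samples")
    if np.unique(X, axis=0).shape[0] < n:
        import warnings
        warnings.warn("duplicate rows in t-SNE input", RuntimeWarning)
    perp = min(perplexity, (n - 1) / 3)
    emb = TSNE(n_components=dims, perplexity=perp, init="pca",
               random_state=seed).fit_transform(X)
    return emb
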