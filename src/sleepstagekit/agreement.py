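"""Epoch- and parameter-level agreement statistics.

Implements the validation battery used to compare a stage classifier against
ground-truth hypnograms: confusion matrices, Cohen's kappa, macro F1,
balanced accuracy and per-class sensitivity/specificity/precision (computed
directly from the confusion matrix by their defining formulas), subject-wise
k-fold assignment, Bland-Altman agreement for per-night sleep parameters and
stratified performance tables.

Conventions: kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from
the row/column marginals; F1 is macro-averaged (unweighted mean of per-class
F1, with per-class values also reported); balanced accuracy is the mean
per-class recall; Bland-Altman differences are estimate - reference, so a
positive bias means the estimator overestimates, and the 95% limits of
agreement are bias +- 1.96 * sd of the paired differences (single night per
subject, no repeated-measures correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SCHEME_LABELS


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (K, K) int; entry (i, j): true class i predicted j
    labels: tuple

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class AgreementReport:
    kappa: float
    macro_f1: float
    balanced_accuracy: float
    per_class: pd.DataFrame  # sensitivity, specificity, precision, f1 per class
    level: str = "epoch_pooled"  # or "subject_mean"
    class_scheme: str = "five_class"
    kappa_defined: bool = True


@dataclass
class BlandAltmanResult:
    parameter: str
    mean_bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_nights: int


@dataclass
class FoldAssignment:
    assignment: dict  # subject_id -> fold index
    k: int
    seed: int

    def fold(self, i: int) -> list:
        return sorted(s for s, f in self.assignment.items() if f == i)


def confusion(true_labels, pred_labels, scheme_or_labels="five_class") -> ConfusionMatrix:
    """Count matrix with entry (i, j) = # epochs of true class i predicted as j."""
    if isinstance(scheme_or_labels, str):
        labels = SCHEME_LABELS[scheme_or_labels]
    else:
        labels = tuple(scheme_or_labels)
    true_labels = np.asarray(true_labels, dtype=object)
    pred_labels = np.asarray(pred_labels, dtype=object)
    if len(true_labels) != len(pred_labels):
        raise ValueError("true and predicted label sequences differ in length")
    index = {lab: i for i, lab in enumerate(labels)}
    bad = set(true_labels) | set(pred_labels)
    if not bad <= set(labels):
        raise ValueError(f"labels outside scheme alphabet: {sorted(bad - set(labels))}")
    k = len(labels)
    cm = np.zeros((k, k), dtype=int)
    ti = np.fromiter((index[t] for t in true_labels), dtype=int, count=len(true_labels))
    pi = np.fromiter((index[p] for p in pred_labels), dtype=int, count=len(pred_labels))
    np.add.at(cm, (ti, pi), 1)
    return ConfusionMatrix(cm, labels)


def agreement_metrics(cm: ConfusionMatrix, level="epoch_pooled", scheme="") -> AgreementReport:
    """Kappa, macro F1, balanced accuracy and per-class rates from a matrix."""
    c = cm.counts.astype(float)
    n = c.sum()
    if n <= 0:
        raise ValueError("confusion matrix is empty")
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    p_o = np.trace(c) / n
    p_e = float((row * col).sum() / n**2)
    kappa_defined = not np.isclose(p_e, 1.0)
    kappa = (p_o - p_e) / (1.0 - p_e) if kappa_defined else float("nan")

    tp = np.diag(c)
    fn = row - tp
    fp = col - tp
    tn = n - row - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(row > 0, tp / row, np.nan)  # recall
        spec = np.where((tn + fp) > 0, tn / (tn + fp), np.nan)
        prec = np.where(col > 0, tp / col, np.nan)
        f1 = np.where(
            (2 * tp + fp + fn) > 0, 2 * tp / (2 * tp + fp + fn), np.nan
        )
    per_class = pd.DataFrame(
        {"sensitivity": sens, "specificity": spec, "precision": prec, "f1": f1},
        index=list(cm.labels),
    )
    macro_f1 = float(np.nanmean(f1))
    balanced_acc = float(np.nanmean(sens))
    return AgreementReport(
        kappa=float(kappa),
        macro_f1=macro_f1,
        balanced_accuracy=balanced_acc,
        per_class=per_class,
        level=level,
        class_scheme=scheme,
        kappa_defined=kappa_defined,
    )


def evaluate_labels(true_labels, pred_labels, scheme="five_class") -> AgreementReport:
    """Convenience: confusion + metrics in one call (epoch-pooled)."""
    return agreement_metrics(
        confusion(true_labels, pred_labels, scheme), level="epoch_pooled", scheme=scheme
    )


def subject_level_report(truths: dict, preds: dict, scheme="five_class"):
    """Per-subject metrics averaged across subjects (mean +- between-subject sd).

    ``truths``/``preds`` map subject_id -> label sequence.  Subjects whose
    truth contains a single class are excluded from the kappa mean (kappa is
    undefined there) but kept for F1/balanced accuracy.  Returns
    ``(summary DataFrame, per-subject DataFrame)``; the summary rows are
    labelled ``subject_mean``, alongside an ``epoch_pooled`` row computed on
    the concatenated sequences.
    """
    if not truths:
        raise ValueError("no subjects")
    rows = []
    for sid in sorted(truths):
        rep = evaluate_labels(truths[sid], preds[sid], scheme)
        rows.append(
            {
                "subject_id": sid,
                "kappa": rep.kappa if rep.kappa_defined and len(set(truths[sid])) > 1 else np.nan,
                "macro_f1": rep.macro_f1,
                "balanced_accuracy": rep.balanced_accuracy,
            }
        )
    per_subject = pd.DataFrame(rows).set_index("subject_id")
    mean = per_subject.mean()
    sd = per_subject.std(ddof=1).fillna(0.0)  # singleton sd reported as 0
    pooled_true = np.concatenate([np.asarray(truths[s], dtype=object) for s in sorted(truths)])
    pooled_pred = np.concatenate([np.asarray(preds[s], dtype=object) for s in sorted(truths)])
    pooled = evaluate_labels(pooled_true, pooled_pred, scheme)
    summary = pd.DataFrame(
        {
            "kappa": [mean["kappa"], sd["kappa"], pooled.kappa],
            "macro_f1": [mean["macro_f1"], sd["macro_f1"], pooled.macro_f1],
            "balanced_accuracy": [
                mean["balanced_accuracy"],
                sd["balanced_accuracy"],
                pooled.balanced_accuracy,
            ],
        },
        index=["subject_mean", "subject_sd", "epoch_pooled"],
    )
    return summary, per_subject


def bland_altman(reference_values, estimated_values, parameter="") -> BlandAltmanResult:
    """Bland-Altman bias and 95% limits of agreement on paired values."""
    ref = np.asarray(reference_values, dtype=float)
    est = np.asarray(estimated_values, dtype=float)
    if ref.shape != est.shape:
        raise ValueError("paired arrays must have identical shape")
    if ref.size < 2:
        raise ValueError("Bland-Altman needs at least 2 paired values")
    d = est - ref
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        parameter=parameter,
        mean_bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n_nights=int(ref.size),
    )


def make_folds(subject_ids, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Subject-wise k-fold partition; fold sizes differ by at most one."""
    subjects = sorted(set(subject_ids))
    if len(subjects) < k:
        raise ValueError(f"need at least {k} subjects for {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    assignment = {subjects[j]: int(i % k) for i, j in enumerate(order)}
    return FoldAssignment(assignment, k, seed)


def stratified_report(
    per_subject: pd.DataFrame, strata: dict, min_n: int = 3
) -> pd.DataFrame:
    """Per-stratum mean +- sd of subject-level metrics.

    ``per_subject`` is indexed by subject_id (as from subject_level_report);
    ``strata`` maps subject_id -> stratum label.  Strata smaller than
    ``min_n`` are flagged.
    """
    missing = set(per_subject.index) - set(strata)
    if missing:
        raise ValueError(f"subjects without stratum label: {sorted(missing)}")
    df = per_subject.copy()
    df["stratum"] = [strata[s] for s in df.index]
    rows = []
    for stratum, grp in df.groupby("stratum"):
        metrics = grp.drop(columns="stratum")
        row = {"stratum": stratum, "n": len(grp), "flagged_small": len(grp) < min_n}
        for m in metrics.columns:
            row[f"{m}_mean"] = metrics[m].mean()
            row[f"{m}_sd"] = metrics[m].std(ddof=1) if len(grp) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")


def bland_altman_plot(reference_values, estimated_values, parameter, path):
    """Render a Bland-Altman plot (mean vs difference, bias and LoA lines)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(reference_values, estimated_values, parameter)
    ref = np.asarray(reference_values, dtype=float)
    est = np.asarray(estimated_values, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((ref + est) / 2, est - ref, s=12, alpha=0.6)
    ax.axhline(res.mean_bias, color="k", lw=1.2, label=f"bias {res.mean_bias:.2f}")
    for y in (res.loa_low, res.loa_high):
        ax.axhline(y, color="k", lw=0.8, ls="--")
    ax.set_xlabel("mean of reference and estimate")
    ax.set_ylabel("estimate - reference")
    ax.set_title(parameter)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return res


def confusion_matrix_plot(cm: ConfusionMatrix, path, normalize: bool = True):
    """Render a confusion matrix heat map (row-normalised by default)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = cm.counts.astype(float)
    shown = counts
    if normalize:
        row = counts.sum(axis=1, keepdims=True)
        shown = np.divide(counts, row, out=np.zeros_like(counts), where=row > 0)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(shown, cmap="Blues", vmin=0)
    ax.set_xticks(range(len(cm.labels)), cm.labels)
    ax.set_yticks(range(len(cm.labels)), cm.labels)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(len(cm.labels)):
        for j in range(len(cm.labels)):
            ax.text(j, i, f"{shown[i, j]:.2f}" if normalize else f"{int(counts[i, j])}",
                    ha="center", va="center", fontsize=8)
    fig.colorbar(im, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
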