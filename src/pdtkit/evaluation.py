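"""LOOCV orchestration, confusion-matrix metrics, ROC/AUC and group statistics.

With 26 subjects, leave-one-out cross-validation is the natural evaluation:
each subject is held out once, the pipeline is trained on the remaining
n - 1, and the held-out decision scores are pooled into one ROC curve.
Feature selection can be *pooled* (run once on the full cohort, the same
subset applied to every fold — what small-sample studies typically report,
optimistically biased) or *nested* (re-run inside every training fold —
unbiased, slower).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .classifiers import NEGATIVE, POSITIVE, ClassifierSpec, LabeledDataset
from .errors import ContractError, DataError

__all__ = [
    "FoldPrediction",
    "EvalReport",
    "loocv",
    "confusion_metrics",
    "roc_auc",
    "compare_groups",
    "relative_improvement",
    "mean_relative_improvement",
    "evaluate_pipeline",
]


@dataclass
class FoldPrediction:
    """Held-out result for one LOOCV fold."""

    index: int
    subject_id: str | None
    score: float
    predicted: int
    actual: int
    subset: tuple[int, ...] | None = None  # columns used (nested/pooled FS)


def _resolve_factory(spec) -> Callable[[], object]:
    if isinstance(spec, ClassifierSpec):
        return spec.make
    if callable(spec):
        return spec
    raise ContractError("spec must be a ClassifierSpec or a zero-arg model factory")


def loocv(
    data: LabeledDataset,
    spec,
    *,
    subset: Sequence[int] | None = None,
    nested_fs: bool = False,
    patience: int = 5,
    merit: str = "auto",
) -> list[FoldPrediction]:
    """Leave-one-out cross-validation: one held-out prediction per subject.

    ``subset`` fixes the feature columns for every fold (pooled selection);
    ``nested_fs=True`` re-runs best-first wrapper selection on each training
    fold instead.  Exactly one of the two may be given.
    """
    if subset is not None and nested_fs:
        raise ContractError("give either a fixed subset or nested_fs, not both")
    if data.n < 3:
        raise DataError(f"LOOCV needs at least 3 subjects, got {data.n}")
    if not data.both_classes:
        raise DataError("LOOCV needs both classes present")
    factory = _resolve_factory(spec)

    results: list[FoldPrediction] = []
    all_idx = np.arange(data.n)
    for i in range(data.n):
        train = data.rows(all_idx[all_idx != i])
        if not train.both_classes:
            raise DataError(
                f"training fold {i} (holding out "
                f"{data.subject_ids[i] if data.subject_ids else i}) has a single class"
            )
        cols: tuple[int, ...] | None
        if nested_fs:
            from .feature_selection import best_first_select  # lazy: avoids cycle

            chosen, _ = best_first_select(train, spec, patience=patience, merit=merit)
            cols = chosen.indices if chosen.indices else tuple(range(data.m))
        elif subset is not None:
            cols = tuple(subset)
        else:
            cols = None

        fold_train = train.subset(cols) if cols is not None else train
        model = factory()
        model.fit(fold_train)
        x_test = data.X[i : i + 1, list(cols)] if cols is not None else data.X[i : i + 1]
        score = float(np.asarray(model.decision_score(x_test)).ravel()[0])
        pred = int(np.asarray(model.predict(x_test)).ravel()[0])
        results.append(
            FoldPrediction(
                index=i,
                subject_id=data.subject_ids[i] if data.subject_ids else None,
                score=score,
                predicted=pred,
                actual=int(data.y[i]),
                subset=cols,
            )
        )
    return results


def confusion_metrics(actual: Sequence[int], predicted: Sequence[int]) -> dict:
    """Confusion counts and derived rates for +/-1 labels.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/n, F = 2 P R / (P + R).  Zero denominators yield NaN
    with a warning rather than an exception.
    """
    a = np.asarray(actual, int)
    p = np.asarray(predicted, int)
    if a.size == 0:
        raise ContractError("empty prediction set")
    if a.shape != p.shape:
        raise ContractError("actual and predicted must have equal length")
    tp = int(np.sum((a == POSITIVE) & (p == POSITIVE)))
    fn = int(np.sum((a == POSITIVE) & (p == NEGATIVE)))
    tn = int(np.sum((a == NEGATIVE) & (p == NEGATIVE)))
    fp = int(np.sum((a == NEGATIVE) & (p == POSITIVE)))

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
            return float("nan")
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    prec = ratio(tp, tp + fp, "precision")
    acc = (tp + tn) / a.size
    if np.isnan(prec) or np.isnan(sens) or prec + sens == 0:
        warnings.warn("F-measure undefined; reporting NaN")
        f = float("nan")
    else:
        f = 2 * prec * sens / (prec + sens)
    return {
        "tp": tp,
        "fn": fn,
        "tn": tn,
        "fp": fp,
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "accuracy": acc,
        "f_measure": f,
    }


def roc_auc(actual: Sequence[int], scores: Sequence[float]) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC (ties contribute 1/2 a concordance).

    Returns ``(points, auc)`` where points is an (k, 2) array of (FPR, TPR)
    running from (0, 0) to (1, 1).
    """
    a = np.asarray(actual, int)
    s = np.asarray(scores, float)
    if not np.all(np.isfinite(s)):
        raise DataError("scores must be finite")
    if not ({NEGATIVE, POSITIVE} <= set(np.unique(a))):
        raise DataError("both classes must be present for ROC analysis")
    fpr, tpr, _ = roc_curve(a, s, pos_label=POSITIVE, drop_intermediate=False)
    return np.column_stack([fpr, tpr]), float(_trapezoid_auc(fpr, tpr))


def compare_groups(
    frame: pd.DataFrame,
    feature_names: Sequence[str] | None = None,
    *,
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-feature patient-vs-control comparison (Welch two-sample t test).

    ``frame`` is the canonical feature matrix (``group`` column plus the 12
    features).  Returns one row per feature: group means/SDs, t, p, and —
    when ``correction`` names a statsmodels method (e.g. ``"holm"``) — an
    adjusted p column.  Degenerate variance yields NaN with a warning.
    """
    from .features import FEATURE_NAMES  # local: features imports classifiers only

    names = list(feature_names) if feature_names is not None else list(FEATURE_NAMES)
    pat = frame[frame["group"] == "patient"]
    ctl = frame[frame["group"] == "control"]
    if len(pat) < 2 or len(ctl) < 2:
        raise DataError("need at least 2 subjects per group")
    rows = []
    for name in names:
        x, z = pat[name].to_numpy(float), ctl[name].to_numpy(float)
        if np.var(x) == 0 and np.var(z) == 0:
            warnings.warn(f"{name}: degenerate variance in both groups; t/p set to NaN")
            t_stat, p_val = float("nan"), float("nan")
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                t_stat, p_val = stats.ttest_ind(x, z, equal_var=False)
        rows.append(
            {
                "feature": name,
                "patient_mean": float(np.mean(x)),
                "patient_sd": float(np.std(x, ddof=1)),
                "control_mean": float(np.mean(z)),
                "control_sd": float(np.std(z, ddof=1)),
                "t": float(t_stat),
                "p": float(p_val),
            }
        )
    out = pd.DataFrame(rows)
    if correction is not None:
        from statsmodels.stats.multitest import multipletests

        ok = out["p"].notna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method=correction)[1]
        out["p_adj"] = adj
    return out


def relative_improvement(before: float, after: float) -> float:
    """Percent change 100 (after - before) / before, rounded to 2 decimals."""
    if before <= 0:
        raise ContractError(f"before must be positive, got {before}")
    return round(100.0 * (after - before) / before, 2)


def mean_relative_improvement(pairs: Sequence[tuple[float, float]]) -> float:
    """Mean of the per-pair relative improvements, in percent (2 decimals)."""
    if len(pairs) == 0:
        raise ContractError("no (before, after) pairs given")
    vals = [100.0 * (a - b) / b for b, a in pairs]
    return round(float(np.mean(vals)), 2)


@dataclass
class EvalReport:
    """One classifier x FS-mode LOOCV evaluation."""

    classifier: str
    fs_mode: str  # "none" | "pooled" | "nested"
    n: int
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f_measure: float
    auc: float
    roc: list[tuple[float, float]]
    folds: list[FoldPrediction] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "fs_mode": self.fs_mode,
            "n": self.n,
            "confusion": {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "f_measure": self.f_measure,
            "auc": self.auc,
            "roc": [list(p) for p in self.roc],
            "selected_subsets": sorted(
                {tuple(f.subset) for f in self.folds if f.subset is not None}
            ),
        }


def evaluate_pipeline(
    data: LabeledDataset,
    spec: ClassifierSpec,
    *,
    fs_mode: str = "none",
    patience: int = 5,
    merit: str = "auto",
) -> EvalReport:
    """LOOCV-evaluate one classifier with the requested feature-selection mode."""
    if fs_mode == "none":
        folds = loocv(data, spec)
    elif fs_mode == "pooled":
        from .feature_selection import best_first_select

        chosen, _ = best_first_select(data, spec, patience=patience, merit=merit)
        cols = chosen.indices if chosen.indices else tuple(range(data.m))
        folds = loocv(data, spec, subset=cols)
    elif fs_mode == "nested":
        folds = loocv(data, spec, nested_fs=True, patience=patience, merit=merit)
    else:
        raise ContractError(f"fs_mode must be none|pooled|nested, got {fs_mode!r}")

    actual = [f.actual for f in folds]
    predicted = [f.predicted for f in folds]
    scores = [f.score for f in folds]
    cm = confusion_metrics(actual, predicted)
    points, auc_val = roc_auc(actual, scores)
    return EvalReport(
        classifier=spec.family,
        fs_mode=fs_mode,
        n=data.n,
        tp=cm["tp"],
        fn=cm["fn"],
        tn=cm["tn"],
        fp=cm["fp"],
        sensitivity=cm["sensitivity"],
        specificity=cm["specificity"],
        precision=cm["precision"],
        accuracy=cm["accuracy"],
        f_measure=cm["f_measure"],
        auc=auc_val,
        roc=[(float(x), float(y)) for x, y in points],
        folds=folds,
    )
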