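"""Threshold-free multi-label metrics and lead-setup comparison arithmetic.

AUCs are reported on the percent scale, macro-averaged over the 20
diagnostic classes, with normal-approximation 95% confidence intervals
over repeated seeded runs.  Operating points use Youden's J
(sensitivity + specificity - 1) at the best ROC threshold.  Setups are
compared by relative percentage difference of mean AUCs against a
reference setup (the 12-lead standard).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .ptbxl import CLASS_NAMES

logger = logging.getLogger(__name__)


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve on the [0, 1] scale.

    Equals the Mann-Whitney probability: the fraction of
    (positive, negative) pairs where the positive outscores the
    negative, ties counted 1/2.  Requires both classes present.
    """
    labels = np.asarray(labels).ravel()
    scores = np.asarray(scores, dtype=np.float64).ravel()
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    n_pos = int(np.sum(labels == 1))
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("AUC undefined: need at least one positive and one negative")
    return float(roc_auc_score(labels, scores))


def macro_average(per_class_values) -> float:
    """Unweighted mean over defined (non-NaN) class values."""
    vals = np.asarray(per_class_values, dtype=np.float64)
    defined = vals[~np.isnan(vals)]
    if defined.size == 0:
        raise ValueError("macro average undefined: no class has a defined value")
    if defined.size < vals.size:
        logger.warning(
            "macro average over %d of %d classes (others undefined on this split)",
            defined.size, vals.size,
        )
    return float(defined.mean())


def ci_over_runs(values) -> tuple[float, float, float]:
    """(mean, lower, upper): normal-approximation 95% CI over run values.

    half-width = 1.96 * sd / sqrt(n), sd with the n-1 denominator.
    """
    vals = np.asarray(values, dtype=np.float64)
    if vals.size < 2:
        raise ValueError("confidence interval needs at least 2 runs")
    mean = float(vals.mean())
    half = 1.96 * float(vals.std(ddof=1)) / math.sqrt(vals.size)
    return mean, mean - half, mean + half


def bootstrap_ci_over_runs(
    values, n_boot: int = 10_000, seed: int = 0
) -> tuple[float, float, float]:
    """Percentile-bootstrap alternative to :func:`ci_over_runs`."""
    vals = np.asarray(values, dtype=np.float64)
    if vals.size < 2:
        raise ValueError("confidence interval needs at least 2 runs")
    rng = np.random.default_rng(seed)
    means = rng.choice(vals, size=(n_boot, vals.size), replace=True).mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(vals.mean()), float(lo), float(hi)


def best_threshold(labels: np.ndarray, scores: np.ndarray) -> tuple[float, float, float]:
    """Operating point maximizing Youden's J on the ROC curve.

    Returns (threshold, sensitivity, specificity); classification is
    score >= threshold.  Ties on J are broken by higher sensitivity,
    then by lower threshold.
    """
    labels = np.asarray(labels).ravel()
    scores = np.asarray(scores, dtype=np.float64).ravel()
    n_pos = int(np.sum(labels == 1))
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("best threshold undefined for single-class labels")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    j = tpr - fpr
    # lexicographic: max J, then max sensitivity, then min threshold
    order = sorted(
        range(len(j)), key=lambda i: (-j[i], -tpr[i], thresholds[i])
    )
    best = order[0]
    return float(thresholds[best]), float(tpr[best]), float(1.0 - fpr[best])


def relative_percentage_difference(value: float, reference: float) -> float:
    """100 * (value - reference) / reference, to one decimal."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return round(100.0 * (value - reference) / reference, 1)


@dataclass
class EvalReport:
    """Run-aggregated per-class and macro AUCs (percent scale) for one setup."""

    setup_name: str
    class_names: tuple[str, ...]
    auc_mean: np.ndarray                      # (20,) percent
    auc_lower: np.ndarray
    auc_upper: np.ndarray
    macro_mean: float
    macro_lower: float
    macro_upper: float
    n_runs: int
    thresholds: np.ndarray | None = None      # per-class best threshold
    sensitivity: np.ndarray | None = None
    specificity: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = list(self.class_names) + ["Avg"]
        df = pd.DataFrame(
            {
                "auc_mean": np.append(self.auc_mean, self.macro_mean),
                "auc_lower": np.append(self.auc_lower, self.macro_lower),
                "auc_upper": np.append(self.auc_upper, self.macro_upper),
            },
            index=pd.Index(rows, name="class"),
        )
        if self.thresholds is not None:
            df["best_threshold"] = np.append(self.thresholds, np.nan)
            df["sensitivity"] = np.append(self.sensitivity, np.nan)
            df["specificity"] = np.append(self.specificity, np.nan)
        return df


def evaluate_runs(
    run_scores: list[np.ndarray],
    labels: np.ndarray,
    setup_name: str = "",
    class_names: tuple[str, ...] = CLASS_NAMES,
) -> EvalReport:
    """Aggregate per-run score matrices into an :class:`EvalReport`.

    ``run_scores`` holds one (n_records, 20) score matrix per seeded run;
    ``labels`` the common (n_records, 20) binary target.  Classes without
    both a positive and a negative on the split are reported as NaN and
    excluded from the macro average.
    """
    labels = np.asarray(labels)
    n_classes = labels.shape[1]
    n_runs = len(run_scores)
    if n_runs == 0:
        raise ValueError("no runs to evaluate")
    per_run_auc = np.full((n_runs, n_classes), np.nan)
    for r, scores in enumerate(run_scores):
        for c in range(n_classes):
            if 0 < labels[:, c].sum() < len(labels):
                per_run_auc[r, c] = 100.0 * roc_auc(labels[:, c], scores[:, c])
    per_run_macro = np.array([macro_average(per_run_auc[r]) for r in range(n_runs)])

    if n_runs > 1:
        defined_any = ~np.all(np.isnan(per_run_auc), axis=0)
        mean = np.full(n_classes, np.nan)
        mean[defined_any] = np.nanmean(per_run_auc[:, defined_any], axis=0)
    else:
        mean = per_run_auc[0]
    if n_runs >= 2:
        lower = np.empty(n_classes)
        upper = np.empty(n_classes)
        for c in range(n_classes):
            col = per_run_auc[:, c]
            if np.all(np.isnan(col)):
                lower[c] = upper[c] = np.nan
            else:
                _, lower[c], upper[c] = ci_over_runs(col[~np.isnan(col)])
        macro_mean, macro_lo, macro_hi = ci_over_runs(per_run_macro)
    else:
        lower = upper = mean.copy()
        macro_mean = macro_lo = macro_hi = float(per_run_macro[0])

    # operating points from the run-averaged scores
    mean_scores = np.mean(np.stack(run_scores), axis=0)
    thr = np.full(n_classes, np.nan)
    sens = np.full(n_classes, np.nan)
    spec = np.full(n_classes, np.nan)
    for c in range(n_classes):
        if 0 < labels[:, c].sum() < len(labels):
            thr[c], sens[c], spec[c] = best_threshold(labels[:, c], mean_scores[:, c])

    return EvalReport(
        setup_name=setup_name,
        class_names=class_names,
        auc_mean=mean,
        auc_lower=lower,
        auc_upper=upper,
        macro_mean=macro_mean,
        macro_lower=macro_lo,
        macro_upper=macro_hi,
        n_runs=n_runs,
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
    )


@dataclass
class ComparisonTable:
    """Relative percentage AUC differences of setups against a reference."""

    reference: str
    class_names: tuple[str, ...]
    per_class: dict[str, np.ndarray]          # setup -> (20,) percent differences
    average: dict[str, float]                 # setup -> difference of macro means
    mean_per_class: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = list(self.class_names) + ["Avg"]
        data = {
            name: np.append(vals, self.average[name])
            for name, vals in self.per_class.items()
        }
        return pd.DataFrame(data, index=pd.Index(rows, name="class"))


def build_comparison(
    reports: dict[str, EvalReport], reference: str = "12lead"
) -> ComparisonTable:
    """Per-class and average relative percentage differences vs a reference.

    The headline "average" difference compares macro-mean AUCs; the mean
    of per-class differences is also recorded since the two summaries
    need not coincide.
    """
    if reference not in reports:
        raise ValueError(f"reference setup {reference!r} missing from reports")
    ref = reports[reference]
    per_class: dict[str, np.ndarray] = {}
    average: dict[str, float] = {}
    mean_per_class: dict[str, float] = {}
    for name, rep in reports.items():
        diffs = np.array(
            [
                relative_percentage_difference(v, r)
                if not (np.isnan(v) or np.isnan(r))
                else np.nan
                for v, r in zip(rep.auc_mean, ref.auc_mean)
            ]
        )
        per_class[name] = diffs
        average[name] = relative_percentage_difference(rep.macro_mean, ref.macro_mean)
        mean_per_class[name] = round(float(np.nanmean(diffs)), 1)
    return ComparisonTable(
        reference=reference,
        class_names=ref.class_names,
        per_class=per_class,
        average=average,
        mean_per_class=mean_per_class,
    )
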