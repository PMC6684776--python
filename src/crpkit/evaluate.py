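"""Model evaluation and analytical-method validation statistics.

Classification metrics follow the confusion-matrix conventions of two-class
herbal authentication with a class-modelling twist: predictions may be a
class label or ``"unassigned"`` (SIMCA only).  For a chosen positive class:

* sensitivity = TP / (TP + FN), where an unassigned positive counts as a
  false negative (it was not recovered);
* specificity = TN / (TN + FP), where an unassigned negative is excluded —
  it was not falsely called positive;
* ER (error rate) = (FP + FN) / n_total and NER (non-error rate) = 1 - ER,
  i.e. the fraction of samples mis-called into the wrong class, with
  unassigned positives counted against the model and unassigned negatives
  not.  This is the counting that reproduces published two-class
  authentication tables from their prediction counts; the macro mean
  (sensitivity + specificity)/2 is also exposed as ``balanced_ner``.

Rates are held at full precision and rounded only for reporting (2
decimals for rates, 4 for RMSE-type quantities).

Also here: venetian-blinds cross-validation, RMSEC/RMSECV/RMSEP helpers,
and calibration-curve statistics (LOD/LOQ from the residual sd and slope,
RSD% and spike-recovery accuracy%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classify import UNASSIGNED

__all__ = [
    "ConfusionSummary",
    "FitQuality",
    "CalibrationCurve",
    "venetian_blinds",
    "rmse_set",
    "rsq",
    "rmsep_deviation",
    "confusion_summary",
    "linear_calibration",
    "calibration_passes_qc",
    "rsd_percent",
    "rsd_from_summary",
    "accuracy_percent",
]


def venetian_blinds(n: int, n_blocks: int = 10) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cross-validation folds assigning sample i to block i mod n_blocks."""
    if not 2 <= n_blocks <= n:
        raise ValueError(f"n_blocks must be in [2, {n}]")
    idx = np.arange(n)
    folds = []
    for b in range(n_blocks):
        test = idx[idx % n_blocks == b]
        train = idx[idx % n_blocks != b]
        folds.append((train, test))
    return folds


def rmse_set(y_true, y_pred) -> float:
    """Root-mean-square error sqrt(sum (y-yhat)^2 / n)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def rsq(y_true, y_pred) -> float:
    """Squared Pearson correlation between observed and predicted."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size < 2:
        raise ValueError("need at least 2 points")
    r = np.corrcoef(y_true, y_pred)[0, 1]
    return float(r ** 2)


def rmsep_deviation(rmsec: float, rmsep: float) -> float:
    """Percent deviation between prediction and calibration error:
    100 * (RMSEP - RMSEC) / RMSEP."""
    if rmsep <= 0:
        raise ValueError("rmsep must be > 0")
    return 100.0 * (rmsep - rmsec) / rmsep


@dataclass
class FitQuality:
    rmsec: float
    rmsecv: float
    rmsep: float
    r2_cal: float
    r2_cv: float
    r2_val: float
    n_latent: int

    @property
    def deviation_pct(self) -> float:
        return rmsep_deviation(self.rmsec, self.rmsep)


@dataclass
class ConfusionSummary:
    """Two-class confusion counts (with unassigned) and derived rates."""

    positive_class: str
    negative_class: str
    counts: dict[str, dict[str, int]]  # true class -> {pred class/unassigned: n}
    sensitivity: float
    specificity: float
    ner: float
    er: float
    balanced_ner: float
    accuracy_pct: float
    n_unassigned: int

    def rounded(self) -> dict[str, float]:
        """Report-precision view (2 decimals for rates)."""
        return {
            "sensitivity": round(self.sensitivity, 2),
            "specificity": round(self.specificity, 2),
            "ner": round(self.ner, 2),
            "er": round(self.er, 2),
        }


def confusion_summary(true_labels, predicted_labels, positive_class: str,
                      class_set=None) -> ConfusionSummary:
    """Build the confusion summary for two-class predictions.

    ``predicted_labels`` may contain ``"unassigned"``; any other label
    outside the class set raises.
    """
    y = np.asarray([str(c) for c in true_labels], dtype=object)
    p = np.asarray([str(c) for c in predicted_labels], dtype=object)
    if y.shape != p.shape:
        raise ValueError("label arrays differ in length")
    classes = sorted(set(y)) if class_set is None else [str(c) for c in class_set]
    if len(classes) != 2:
        raise ValueError("confusion_summary handles exactly two true classes")
    positive_class = str(positive_class)
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class!r} not in {classes}")
    negative_class = [c for c in classes if c != positive_class][0]
    allowed = set(classes) | {UNASSIGNED}
    bad = (set(y) | set(p)) - allowed
    if bad:
        raise ValueError(f"unknown label(s): {sorted(bad)}")

    counts = {c: {k: 0 for k in classes + [UNASSIGNED]} for c in classes}
    for t, q in zip(y, p):
        counts[t][q] += 1

    n = y.size
    tp = counts[positive_class][positive_class]
    fn_assigned = counts[positive_class][negative_class]
    na_pos = counts[positive_class][UNASSIGNED]
    tn = counts[negative_class][negative_class]
    fp = counts[negative_class][positive_class]
    na_neg = counts[negative_class][UNASSIGNED]

    n_pos = tp + fn_assigned + na_pos
    sensitivity = tp / n_pos if n_pos else float("nan")
    denom_spec = tn + fp
    specificity = tn / denom_spec if denom_spec else float("nan")
    er = (fp + fn_assigned + na_pos) / n
    ner = 1.0 - er
    balanced = (sensitivity + specificity) / 2.0
    accuracy_pct = 100.0 * (tp + tn) / n
    return ConfusionSummary(
        positive_class=positive_class,
        negative_class=negative_class,
        counts=counts,
        sensitivity=sensitivity,
        specificity=specificity,
        ner=ner,
        er=er,
        balanced_ner=balanced,
        accuracy_pct=accuracy_pct,
        n_unassigned=na_pos + na_neg,
    )


@dataclass
class CalibrationCurve:
    slope: float
    intercept: float
    r2: float
    residual_sd: float
    lod: float
    loq: float
    conc_range: tuple[float, float]


def linear_calibration(concentrations, responses) -> CalibrationCurve:
    """Ordinary least-squares calibration line with LOD/LOQ.

    sigma is the residual standard deviation sqrt(SSE / (n-2)); the limit of
    detection is 3.3*sigma/slope and the limit of quantification
    10*sigma/slope.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.unique(x).size < 2:
        raise ValueError("concentrations have zero spread")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sse = float(resid @ resid)
    sigma = np.sqrt(sse / (x.size - 2))
    if slope == 0:
        raise ValueError("zero slope: curve not reportable")
    r = np.corrcoef(x, y)[0, 1]
    return CalibrationCurve(
        slope=float(slope), intercept=float(intercept), r2=float(r ** 2),
        residual_sd=float(sigma),
        lod=float(3.3 * sigma / abs(slope)),
        loq=float(10.0 * sigma / abs(slope)),
        conc_range=(float(x.min()), float(x.max())),
    )


def calibration_passes_qc(curve: CalibrationCurve, min_r2: float = 0.9990) -> bool:
    """Default QC acceptance policy for a calibration curve: r² >= 0.9990."""
    return curve.r2 >= min_r2


def rsd_percent(values) -> float:
    """Relative standard deviation: 100 * sample SD (n-1) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("RSD needs at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def rsd_from_summary(mean: float, sd: float) -> float:
    """RSD% from a reported mean +/- SD pair."""
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return 100.0 * sd / mean


def accuracy_percent(observed_mean: float, spiked: float) -> float:
    """Spike-recovery accuracy: 100 * (observed - spiked) / spiked."""
    if spiked <= 0:
        raise ValueError("spiked concentration must be > 0")
    return 100.0 * (observed_mean - spiked) / spiked
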