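"""Metrics, fold aggregation and repeated-measures model comparison.

Per-image keypoint error is the RMSE over the two coordinates,
sqrt((dx^2 + dy^2) / 2), in model-input (224x224) pixel space. AGA errors
are MAE and RMSE in degrees over test images. Methods are compared across
cross-validation folds with a repeated-measures ANOVA (folds as subjects),
Holm-Bonferroni-adjusted paired t-tests, and Hedges' g effect sizes.

Conventions (fixed so that the statistics are reproducible):

* eta squared is the classic SS_method / SS_total;
* Hedges' g uses the equal-n pooled SD sqrt((s_a^2 + s_b^2) / 2) and the
  small-sample correction J = 1 - 3 / (4 df - 1) with df = 2n - 2, on
  fold-level values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .geometry import KeypointTriplet

__all__ = [
    "keypoint_error",
    "aga_errors",
    "dsc",
    "FoldMetricsTable",
    "aggregate_folds",
    "overall_keypoint_mean",
    "rm_anova",
    "holm_bonferroni",
    "hedges_g",
    "pairwise_comparisons",
    "subgroup_metrics",
    "ComparisonReport",
]

logger = logging.getLogger(__name__)

KEYPOINT_METRICS = ("rmse_lv", "rmse_rv", "rmse_a")


def keypoint_error(pred: KeypointTriplet, true: KeypointTriplet) -> dict[str, float]:
    """Per-keypoint coordinate RMSE: sqrt((dx^2 + dy^2) / 2), pixels."""
    out = {}
    for name in ("LV", "RV", "A"):
        p, t = getattr(pred, name), getattr(true, name)
        out[name] = math.sqrt(((p.x - t.x) ** 2 + (p.y - t.y) ** 2) / 2.0)
    return out


def aga_errors(
    preds: Sequence[float], trues: Sequence[float]
) -> tuple[float, float]:
    """(MAE, RMSE) of the anterior glottic angle in degrees."""
    preds = np.asarray(preds, dtype=float)
    trues = np.asarray(trues, dtype=float)
    if preds.shape != trues.shape:
        raise ValueError("prediction/truth length mismatch")
    if preds.size == 0:
        raise ValueError("no decodable AGA pairs")
    d = preds - trues
    return float(np.mean(np.abs(d))), float(np.sqrt(np.mean(d**2)))


def dsc(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Dice similarity coefficient 2TP / (2TP + FP + FN) on binary masks.

    Two empty masks count as perfect agreement (returns 1, logged)."""
    p = np.asarray(pred_mask).astype(bool)
    t = np.asarray(true_mask).astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = np.sum(p & t)
    denom = 2 * tp + np.sum(p & ~t) + np.sum(~p & t)
    if denom == 0:
        logger.info("both masks empty; DSC = 1 by convention")
        return 1.0
    return float(2 * tp / denom)


@dataclass
class FoldMetricsTable:
    """Tidy per-fold summaries: one row per (fold, method, metric) with the
    mean and SD over the fold's test images plus undecodable counts."""

    frame: pd.DataFrame  # columns: fold, method, metric, mean, sd, n, n_missing

    REQUIRED = ("fold", "method", "metric", "mean")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"metrics table missing columns {missing}")

    def matrix(self, metric: str) -> pd.DataFrame:
        """folds x methods matrix of fold means for one metric."""
        sub = self.frame[self.frame.metric == metric]
        mat = sub.pivot(index="fold", columns="method", values="mean")
        if mat.isna().any().any():
            raise ValueError(f"incomplete cells for metric {metric!r}")
        return mat


def aggregate_folds(table: FoldMetricsTable) -> pd.DataFrame:
    """Unweighted mean over fold means, per (method, metric)."""
    return (
        table.frame.groupby(["method", "metric"])["mean"]
        .mean()
        .unstack("metric")
    )


def overall_keypoint_mean(table: FoldMetricsTable, method: str) -> float:
    """Mean of the three per-keypoint cross-fold means for one method."""
    agg = aggregate_folds(table)
    return float(np.mean([agg.loc[method, m] for m in KEYPOINT_METRICS]))


@dataclass
class ComparisonReport:
    F: float
    df: tuple[int, int]
    p: float
    eta_sq: float
    pairwise: list[dict]


def rm_anova(matrix: pd.DataFrame | np.ndarray) -> ComparisonReport:
    """One-within-factor repeated-measures ANOVA on a folds x methods
    matrix of fold-level means.

    Two-way decomposition without replication: the method effect is tested
    against the fold-by-method residual, F = MS_method / MS_error with
    df = (m - 1, (m - 1)(n - 1)). Effect size is classic eta squared,
    SS_method / SS_total. Missing cells raise (no imputation).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a folds x methods matrix with >= 2 of each")
    if np.isnan(x).any():
        raise ValueError("missing cells in the fold x method matrix")
    n, m = x.shape
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    ss_method = float(n * ((x.mean(axis=0) - grand) ** 2).sum())
    ss_subject = float(m * ((x.mean(axis=1) - grand) ** 2).sum())
    ss_error = ss_total - ss_method - ss_subject
    df_method = m - 1
    df_error = (m - 1) * (n - 1)
    ms_method = ss_method / df_method
    ms_error = ss_error / df_error
    if ms_error <= 0:
        if ss_method <= 1e-12 * max(ss_total, 1.0):
            # no method effect and no residual: define F = 0 (e.g. all
            # methods identical up to a per-fold shift)
            return ComparisonReport(
                F=0.0, df=(df_method, df_error), p=1.0,
                eta_sq=0.0, pairwise=[],
            )
        raise ValueError("zero residual variance; F undefined")
    f = ms_method / ms_error
    p = float(sps.f.sf(f, df_method, df_error))
    eta = ss_method / ss_total if ss_total > 0 else 0.0
    return ComparisonReport(F=f, df=(df_method, df_error), p=p, eta_sq=eta, pairwise=[])


def holm_bonferroni(raw_p: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    raw_p = np.asarray(raw_p, dtype=float)
    if raw_p.size == 0:
        raise ValueError("empty p-value list")
    return multipletests(raw_p, method="holm")[1]


def hedges_g(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Bias-corrected standardized mean difference on equal-n samples.

    g = (mean_a - mean_b) / s_pooled * J with
    s_pooled = sqrt((s_a^2 + s_b^2) / 2) (sample SDs) and
    J = 1 - 3 / (4 df - 1), df = 2n - 2.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need equal-length samples with n >= 2")
    s_pooled = math.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if s_pooled == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("zero pooled SD with unequal means")
    df = 2 * a.size - 2
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float((a.mean() - b.mean()) / s_pooled * j)


def pairwise_comparisons(matrix: pd.DataFrame) -> list[dict]:
    """All method pairs: paired t-test p (Holm-adjusted over the family)
    and Hedges' g on the fold-level values. g is signed as
    (second-named - first-named) so that a positive g means the
    first-named method has the smaller error."""
    methods = list(matrix.columns)
    pairs, raw = [], []
    for i in range(len(methods)):
        for j in range(i + 1, len(methods)):
            a = matrix[methods[i]].to_numpy()
            b = matrix[methods[j]].to_numpy()
            t, p = sps.ttest_rel(a, b)
            pairs.append(
                {
                    "pair": (methods[i], methods[j]),
                    "t": float(t),
                    "p_raw": float(p),
                    "hedges_g": hedges_g(b, a),
                }
            )
            raw.append(float(p))
    adj = holm_bonferroni(raw)
    for d, p_h in zip(pairs, adj):
        d["p_holm"] = float(p_h)
    return pairs


def compare_methods(matrix: pd.DataFrame) -> ComparisonReport:
    """RM-ANOVA plus Holm-adjusted pairwise comparisons."""
    report = rm_anova(matrix)
    report.pairwise = pairwise_comparisons(matrix)
    return report


def subgroup_metrics(
    flags: Sequence[bool],
    per_image_values: Sequence[float],
    labels: tuple[str, str] = ("oncologic", "non_oncologic"),
) -> dict[str, dict]:
    """Split per-image metric values by a boolean flag and summarize each
    subgroup (mean, sd, n); an empty subgroup is marked absent."""
    flags = np.asarray(flags, dtype=bool)
    vals = np.asarray(per_image_values, dtype=float)
    if flags.shape != vals.shape:
        raise ValueError("flags and values must align")
    out = {}
    for label, sel in ((labels[0], flags), (labels[1], ~flags)):
        if sel.sum() == 0:
            out[label] = {"absent": True, "n": 0}
        else:
            sub = vals[sel]
            out[label] = {
                "absent": False,
                "n": int(sel.sum()),
                "mean": float(sub.mean()),
                "sd": float(sub.std(ddof=1)) if sel.sum() > 1 else 0.0,
            }
    return out
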