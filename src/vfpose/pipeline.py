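"""End-to-end experiment orchestration.

Ties the modules together into the full study protocol: patient-grouped
k-fold cross-validation in which each requested method (heatmap
regression, direct coordinate regression, glottal segmentation) is
trained per fold, evaluated on the fold's test patients, and the
per-fold metric summaries are aggregated and compared with the
repeated-measures machinery.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import FoldSplit, FrameRecord, augment, make_patient_folds, resize_frame
from .geometry import compute_aga
from .stats import (
    ComparisonReport,
    FoldMetricsTable,
    aggregate_folds,
    compare_methods,
    dsc,
    keypoint_error,
)
from .training import (
    ModelConfig,
    TrainConfig,
    build_network,
    decode_predictions,
    predict,
    train,
)

__all__ = ["ExperimentConfig", "run_experiment", "method_loss", "REPORT_SCALE"]

logger = logging.getLogger(__name__)

# pixel errors are conventionally reported in 224x224 space regardless of
# the training resolution
REPORT_SCALE = 224

METHOD_LOSSES = {"heatmap": "wmse", "direct": "coord_mse", "segmentation": "dice"}


def method_loss(method: str) -> str:
    return METHOD_LOSSES[method]


@dataclass
class ExperimentConfig:
    methods: tuple[str, ...] = ("heatmap", "direct", "segmentation")
    k_folds: int = 5
    val_fraction: float = 0.2
    seed: int = 0
    input_size: int = 224
    encoder_width_multiplier: float = 1.0
    max_epochs: int = 200
    patience: int = 10
    batch_size: int = 8
    learning_rate: float = 1e-3
    augment: bool = True

    def model_config(self, method: str) -> ModelConfig:
        return ModelConfig(
            variant=method,
            input_size=self.input_size,
            encoder_width_multiplier=self.encoder_width_multiplier,
        )

    def train_config(self, method: str, fold: int) -> TrainConfig:
        return TrainConfig(
            max_epochs=self.max_epochs,
            patience=self.patience,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            loss=method_loss(method),
            # decorrelate folds/methods while staying reproducible
            seed=(self.seed * 1000 + fold * 10 + list(METHOD_LOSSES).index(method))
            % (2**31),
            augment=self.augment,
        )


def _prepare(records: Sequence[FrameRecord], size: int):
    imgs, tris = [], []
    for r in records:
        im, tr = resize_frame(r.image, r.triplet, size)
        imgs.append(im)
        tris.append(tr)
    return imgs, tris


def _select(ids, records, imgs, tris):
    idx = [i for i, r in enumerate(records) if r.frame_id in ids]
    return [imgs[i] for i in idx], [tris[i] for i in idx], idx


def _summary_rows(fold, method, per_metric: dict[str, list[float]], n_missing: int):
    rows = []
    for metric, vals in per_metric.items():
        vals = np.asarray(vals, dtype=float)
        rows.append(
            {
                "fold": fold,
                "method": method,
                "metric": metric,
                "mean": float(vals.mean()) if vals.size else math.nan,
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n": int(vals.size),
                "n_missing": n_missing,
            }
        )
    return rows


def evaluate_fold(
    records: Sequence[FrameRecord],
    imgs: list,
    tris: list,
    split: FoldSplit,
    method: str,
    config: ExperimentConfig,
) -> tuple[list[dict], pd.DataFrame]:
    """Train one method on one fold and summarize its test metrics.

    Returns (summary rows, per-image tidy frame). Undecodable predictions
    (degenerate segmentation masks) are excluded from means and counted.
    """
    mc = config.model_config(method)
    tc = config.train_config(method, split.fold_index)
    tr_i, tr_t, _ = _select(split.train_ids, records, imgs, tris)
    va_i, va_t, _ = _select(split.val_ids, records, imgs, tris)
    te_i, te_t, te_idx = _select(split.test_ids, records, imgs, tris)

    net = build_network(mc, seed=tc.seed)
    train(net, (tr_i, tr_t), (va_i, va_t), mc, tc, augment_fn=augment)
    outputs = predict(net, te_i, mc)
    decoded = decode_predictions(outputs, mc)

    scale = REPORT_SCALE / config.input_size
    per_metric: dict[str, list[float]] = {
        "rmse_lv": [], "rmse_rv": [], "rmse_a": [], "aga_mae": [], "aga_rmse": [],
    }
    if method == "segmentation":
        per_metric["dsc"] = []
    per_image = []
    n_missing = 0
    for pos, (pred, true) in enumerate(zip(decoded, te_t)):
        rec = records[te_idx[pos]]
        if pred is None:
            n_missing += 1
            per_image.append(
                {"frame_id": rec.frame_id, "fold": split.fold_index,
                 "method": method, "missing": True}
            )
            continue
        err = keypoint_error(pred, true)
        aga_err = compute_aga(pred) - compute_aga(true)
        row = {
            "frame_id": rec.frame_id,
            "fold": split.fold_index,
            "method": method,
            "missing": False,
            "oncologic": rec.oncologic,
            "rmse_lv": err["LV"] * scale,
            "rmse_rv": err["RV"] * scale,
            "rmse_a": err["A"] * scale,
            "aga_abs_err": abs(aga_err),
        }
        per_metric["rmse_lv"].append(row["rmse_lv"])
        per_metric["rmse_rv"].append(row["rmse_rv"])
        per_metric["rmse_a"].append(row["rmse_a"])
        per_metric["aga_mae"].append(abs(aga_err))
        per_metric["aga_rmse"].append(aga_err**2)  # squared; root taken below
        if method == "segmentation":
            from .geometry import triangle_mask

            pred_mask = (outputs[pos][0] >= 0.5).astype(np.uint8)
            row["dsc"] = dsc(pred_mask, triangle_mask(true, mc.input_size, mc.input_size))
            per_metric["dsc"].append(row["dsc"])
        per_image.append(row)

    # fold-level AGA RMSE is the root of the mean squared error over images
    sq = per_metric.pop("aga_rmse")
    rows = _summary_rows(split.fold_index, method, per_metric, n_missing)
    rows.append(
        {
            "fold": split.fold_index,
            "method": method,
            "metric": "aga_rmse",
            "mean": float(np.sqrt(np.mean(sq))) if sq else math.nan,
            "sd": 0.0,
            "n": len(sq),
            "n_missing": n_missing,
        }
    )
    if n_missing:
        logger.warning(
            "fold %d %s: %d undecodable predictions excluded",
            split.fold_index, method, n_missing,
        )
    return rows, pd.DataFrame(per_image)


def run_experiment(
    records: Sequence[FrameRecord],
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full cross-validated comparison.

    Returns a dict with the FoldMetricsTable, cross-fold aggregates,
    per-metric ComparisonReports (when >= 2 methods trained), per-image
    results and a list of (method, fold) failures. Per-fold summaries are
    checkpointed to out_dir so an interrupted run resumes.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    imgs, tris = _prepare(records, config.input_size)
    folds = make_patient_folds(
        records, k=config.k_folds, val_fraction=config.val_fraction, seed=config.seed
    )
    for f in folds:
        f.validate(records)

    all_rows: list[dict] = []
    per_image_frames: list[pd.DataFrame] = []
    failures: list[tuple[str, int]] = []
    for method in config.methods:
        for split in folds:
            ckpt = (
                out_dir / f"fold{split.fold_index}_{method}.json" if out_dir else None
            )
            if ckpt and ckpt.exists():
                with open(ckpt) as fh:
                    rows = json.load(fh)
                logger.info("resuming %s fold %d from checkpoint", method, split.fold_index)
            else:
                try:
                    rows, per_image = evaluate_fold(
                        records, imgs, tris, split, method, config
                    )
                    per_image_frames.append(per_image)
                except Exception:
                    logger.exception(
                        "fold %d method %s failed", split.fold_index, method
                    )
                    failures.append((method, split.fold_index))
                    continue
                if ckpt:
                    with open(ckpt, "w") as fh:
                        json.dump(rows, fh)
            all_rows.extend(rows)

    table = FoldMetricsTable(pd.DataFrame(all_rows))
    result: dict = {
        "table": table,
        "aggregates": aggregate_folds(table),
        "comparisons": {},
        "per_image": pd.concat(per_image_frames, ignore_index=True)
        if per_image_frames
        else pd.DataFrame(),
        "failures": failures,
    }

    trained = [m for m in config.methods if not any(f[0] == m for f in failures)]
    if len(trained) >= 2:
        df = table.frame
        kp = (
            df[df.metric.isin(("rmse_lv", "rmse_rv", "rmse_a")) & df.method.isin(trained)]
            .groupby(["fold", "method"])["mean"]
            .mean()
            .unstack("method")[list(trained)]
        )
        result["comparisons"]["keypoint_rmse"] = compare_methods(kp)
        for metric in ("aga_mae", "aga_rmse"):
            mat = table.matrix(metric)[list(trained)]
            result["comparisons"][metric] = compare_methods(mat)
    else:
        logger.warning("fewer than 2 methods trained; skipping ANOVA")

    if out_dir:
        table.frame.to_csv(out_dir / "fold_metrics.csv", index=False)
        result["aggregates"].to_csv(out_dir / "aggregates.csv")
        if len(result["per_image"]):
            result["per_image"].to_csv(out_dir / "per_image.csv", index=False)
    return result
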