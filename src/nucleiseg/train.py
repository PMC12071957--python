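"""Training, evaluation and the ablation harness.

Thin functional surface over :class:`~nucleiseg.segmenter.UNetSegmenter`:
``train`` runs the seeded hybrid-loss loop on preprocessed records,
``evaluate`` produces a :class:`~nucleiseg.metrics.MetricReport` with pixel
and object-level statistics, and ``run_ablation`` builds every architecture
variant, always reporting exact parameter counts and optionally short-run
metrics, as a CSV shaped like the ablation table (minus hardware timing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import ArchConfig, TrainConfig
from .metrics import MetricReport
from .model import NetworkHandle, VARIANTS, assemble_variant, count_parameters
from .pipeline import ImageRecord
from .segmenter import UNetSegmenter


def _records_to_arrays(records: list[ImageRecord]) -> tuple[np.ndarray, np.ndarray]:
    for r in records:
        if r.merged_mask is None:
            raise ValueError(f"record {r.image_id} has no ground-truth mask")
    X = np.stack([np.asarray(r.image, dtype=np.float32) for r in records])
    y = np.stack([r.merged_mask.astype(np.float32) for r in records])
    return X, y


def train(config: TrainConfig, train_records: list[ImageRecord],
          val_records: list[ImageRecord] | None = None,
          variant: str = "full") -> tuple[NetworkHandle, dict]:
    """Fit the network on preprocessed records; returns the trained handle
    and the per-epoch history.  Fully reproducible given the config seed."""
    X, y = _records_to_arrays(train_records)
    sw = np.array([r.weight for r in train_records], dtype=np.float64)
    validation = None
    if val_records:
        validation = _records_to_arrays(val_records)
    est = UNetSegmenter.from_train_config(config, variant=variant)
    est.fit(X, y, sample_weight=sw, validation=validation)
    if config.checkpoint_path:
        save_checkpoint(est.net_, config.checkpoint_path)
    return est.net_, est.history_


def label_instances(mask: np.ndarray) -> list[np.ndarray]:
    """Split a binary mask into connected-component instance masks."""
    labels, n = ndimage.label(np.asarray(mask) > 0)
    return [(labels == i).astype(np.uint8) for i in range(1, n + 1)]


def evaluate(handle: NetworkHandle, records: list[ImageRecord],
             threshold: float = 0.5, iou_threshold: float = 0.5,
             fom_mode: str = "precision_recall") -> MetricReport:
    """Score the network on labeled records: per-image and mean accuracy,
    precision, recall, F1, DSC, IoU, FoM and object detection rate at
    IoU > ``iou_threshold``."""
    report = MetricReport(fom_mode=fom_mode)
    for rec in records:
        if rec.merged_mask is None:
            raise ValueError(f"record {rec.image_id} is unlabeled")
        x = np.asarray(rec.image, dtype=np.float32)[None, None]
        probs = handle.net.forward(x, training=False)[0, 0]
        pred = (probs >= threshold).astype(np.uint8)
        report.add_image(rec.image_id, pred, rec.merged_mask,
                         pred_instances=label_instances(pred),
                         gt_instances=rec.instance_masks,
                         iou_threshold=iou_threshold)
    return report


@dataclass
class AblationResult:
    """One row of the ablation table."""

    variant: str
    n_parameters: int
    dsc: float = float("nan")
    accuracy: float = float("nan")
    report: MetricReport | None = None


ABLATION_LABELS = {
    "full": "Full Proposed Model (All Modules)",
    "no_depthwise": "w/o Depthwise Separable Convs",
    "no_residual": "w/o Residual Connections",
    "no_attention": "w/o Spatial Attention",
    "no_reduction": "w/o Channel Reduction/Expansion",
    "baseline_unet": "Baseline U-Net",
}

#: presentation order of the ablation table
ABLATION_ORDER = ("full", "no_depthwise", "no_residual", "no_attention",
                  "no_reduction", "baseline_unet")


def run_ablation(base_config: ArchConfig,
                 records: list[ImageRecord] | None = None,
                 train_config: TrainConfig | None = None,
                 csv_path: str | Path | None = None) -> list[AblationResult]:
    """Build every variant; report exact parameter counts, and — when records
    and a train config are supplied — seeded short-run DSC/accuracy."""
    results = []
    for variant in ABLATION_ORDER:
        handle = assemble_variant(base_config, variant)
        res = AblationResult(variant=variant, n_parameters=count_parameters(handle))
        if records is not None and train_config is not None:
            handle, _ = train(train_config, records, variant=variant)
            report = evaluate(handle, records)
            agg = report.aggregate()
            res.dsc, res.accuracy, res.report = agg["dsc"], agg["accuracy"], report
        results.append(res)
    if csv_path is not None:
        frame = pd.DataFrame([
            {"Model Variant": ABLATION_LABELS[r.variant], "DSC": r.dsc,
             "Accuracy": r.accuracy, "Parameters": r.n_parameters,
             "Parameters (M)": round(r.n_parameters / 1e6, 1)}
            for r in results])
        frame.to_csv(csv_path, index=False)
    return results


def save_checkpoint(handle: NetworkHandle, path: str | Path) -> None:
    """Persist weights + config + variant to an .npz checkpoint."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = json.dumps({"config": {k: (list(v) if isinstance(v, tuple) else v)
                                  for k, v in handle.config.to_dict().items()},
                       "variant": handle.variant})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **handle.net.state_dict())


def load_checkpoint(path: str | Path) -> NetworkHandle:
    """Rebuild the network recorded in a checkpoint and load its weights."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    config = ArchConfig.from_dict(meta["config"])
    handle = assemble_variant(config, meta["variant"])
    handle.net.load_state_dict(state)
    return handle
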