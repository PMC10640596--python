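"""Two-stage training and batch inference.

Stage 1 pretrains the backbone + shared head on slice-level classification
alone (binary cross-entropy on the slice row).  Stage 2 fine-tunes the whole
model: every step evaluates the network on a batch and on its horizontally
flipped copy and minimises the symmetric weak-supervision loss (slice BCE on
both orientations, the column constraint on both orientations, and the flip
consistency term), restricted to the configured ablation subset.

All randomness (init, shuffling) flows from ``TrainConfig.seed``; runs are
bit-reproducible on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .geometry import RingPrediction, ScanGeometry, column_ring_weights, columns_to_rings
from .losses import ALLOWED_TERM_SETS, loss_slice_bce, loss_total
from .model import ColumnHeadModel, HeadConfig, Prediction, model_forward
from .nn import SGDMomentum

__all__ = [
    "SliceSample",
    "Dataset",
    "TrainConfig",
    "pretrain_classifier",
    "finetune",
    "predict_slices",
    "predictions_to_frame",
]


@dataclass
class SliceSample:
    """One training/evaluation slice: image, slice label, optional ground truth."""

    image: np.ndarray | str | Path
    y0: np.ndarray
    column_mask: np.ndarray | None = None
    pixel_mask: np.ndarray | None = None
    volume_id: int = 0
    slice_index: int = 0

    def load_image(self) -> np.ndarray:
        if isinstance(self.image, (str, Path)):
            arr = np.asarray(Image.open(self.image).convert("L"), dtype=np.float32) / 255.0
            return arr
        return np.asarray(self.image, dtype=np.float32)


class Dataset:
    """An ordered collection of slices, optionally linked to a scan geometry."""

    def __init__(self, samples: Sequence[SliceSample], geometry: ScanGeometry | None = None):
        self.samples = list(samples)
        self.geometry = geometry
        for s in self.samples:
            y = np.asarray(s.y0)
            if not np.all((y == 0) | (y == 1)):
                raise ValueError("slice labels must be binary")

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, i: int) -> SliceSample:
        return self.samples[i]

    def images(self) -> np.ndarray:
        return np.stack([s.load_image() for s in self.samples])

    def labels(self) -> np.ndarray:
        return np.stack([np.asarray(s.y0, dtype=np.int64) for s in self.samples])

    @classmethod
    def from_synthetic(cls, samples, geometry: ScanGeometry) -> "Dataset":
        return cls(
            [
                SliceSample(
                    image=s.image,
                    y0=s.y0,
                    column_mask=s.column_masks,
                    pixel_mask=s.pixel_masks,
                    volume_id=s.volume_id,
                    slice_index=s.slice_index,
                )
                for s in samples
            ],
            geometry=geometry,
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyper-parameters.

    Defaults follow the published training recipe: batches of 32 slices,
    SGD with momentum 0.9, base learning rate 5e-3 scaled by 0.99 after every
    epoch, 10 fine-tuning epochs.  ``loss_terms`` selects the ablation
    subset; only the nested subsets {l1}, {l1,l2}, {l1,l2,l3} are valid.
    """

    batch_size: int = 32
    momentum: float = 0.9
    base_lr: float = 5e-3
    pretrain_lr: float | None = None
    lr_decay: float = 0.99
    epochs: int = 10
    pretrain_epochs: int = 3
    loss_terms: tuple[str, ...] = ("l1", "l2", "l3")
    seed: int = 0
    backbone_name: str = "conv1792"
    log_path: str | Path | None = None

    def __post_init__(self) -> None:
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if frozenset(self.loss_terms) not in ALLOWED_TERM_SETS:
            raise ValueError(
                f"loss_terms {sorted(set(self.loss_terms))} must be one of "
                "{l1}, {l1,l2}, {l1,l2,l3}"
            )

    def lr_at_epoch(self, epoch: int) -> float:
        return self.base_lr * self.lr_decay**epoch


def _batches(n: int, batch_size: int, rng: np.random.Generator) -> Iterable[np.ndarray]:
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def _log_step(path, record: dict) -> None:
    if path is None:
        return
    with open(path, "a") as fh:
        fh.write(json.dumps(record) + "\n")


def pretrain_classifier(ds: Dataset, cfg: TrainConfig, model: ColumnHeadModel | None = None) -> ColumnHeadModel:
    """Stage 1: slice-level multilabel classification with BCE only."""
    if len(ds) == 0:
        raise ValueError("dataset is empty")
    images, labels = ds.images(), ds.labels()
    if model is None:
        model = _build_model(cfg, n_markers=labels.shape[1], image_size=images.shape[-1])
    rng = np.random.default_rng(cfg.seed)
    lr0 = cfg.pretrain_lr if cfg.pretrain_lr is not None else cfg.base_lr
    opt = SGDMomentum(model.parameters(), lr=lr0, momentum=cfg.momentum)
    step = 0
    for epoch in range(cfg.pretrain_epochs):
        opt.lr = lr0 * cfg.lr_decay**epoch
        for idx in _batches(len(ds), cfg.batch_size, rng):
            pred = model_forward(model, images[idx])
            loss = loss_slice_bce(pred, labels[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite pretraining loss at step {step}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            _log_step(cfg.log_path, {"stage": "pretrain", "step": step, "l1": float(loss.data)})
            step += 1
    return model


def finetune(ds: Dataset, init: ColumnHeadModel, cfg: TrainConfig) -> ColumnHeadModel:
    """Stage 2: optimise the symmetric weak-supervision loss on flipped pairs."""
    if len(ds) == 0:
        raise ValueError("dataset is empty")
    images, labels = ds.images(), ds.labels()
    model = init
    rng = np.random.default_rng(cfg.seed + 1)
    opt = SGDMomentum(model.parameters(), lr=cfg.base_lr, momentum=cfg.momentum)
    step = 0
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr_at_epoch(epoch)
        for idx in _batches(len(ds), cfg.batch_size, rng):
            batch = images[idx]
            pred = model_forward(model, batch)
            pred_flip = model_forward(model, batch[:, :, ::-1])
            breakdown = loss_total(pred, pred_flip, labels[idx], terms=cfg.loss_terms)
            if not np.isfinite(breakdown.total):
                raise RuntimeError(
                    f"non-finite loss at step {step}: {breakdown.to_dict()}"
                )
            opt.zero_grad()
            breakdown.total_tensor.backward()
            opt.step()
            _log_step(cfg.log_path, {"stage": "finetune", "step": step, **breakdown.to_dict()})
            step += 1
    return model


def _build_model(cfg: TrainConfig, n_markers: int, image_size: int) -> ColumnHeadModel:
    if cfg.backbone_name == "tiny":
        head = HeadConfig.tiny(n_markers=n_markers, image_size=image_size)
    else:
        head = HeadConfig(n_markers=n_markers, backbone_name=cfg.backbone_name)
    return ColumnHeadModel(head, seed=cfg.seed)


def train(ds: Dataset, cfg: TrainConfig) -> ColumnHeadModel:
    """Convenience: pretrain then finetune with one config."""
    model = pretrain_classifier(ds, cfg)
    return finetune(ds, model, cfg)


def predict_slices(
    ds: Dataset,
    model: ColumnHeadModel,
    geom: ScanGeometry | None = None,
    batch_size: int = 32,
) -> tuple[list[Prediction], list[RingPrediction]]:
    """Run the model on every slice and map columns onto the ETDRS rings."""
    geom = geom or ds.geometry
    if geom is None:
        raise ValueError("a ScanGeometry is required for ring mapping")
    images = ds.images()
    probs = []
    for i in range(0, len(ds), batch_size):
        probs.append(model.predict_proba(images[i : i + batch_size]))
    yhat = np.concatenate(probs)  # N x (1+C) x B
    preds, ring_preds = [], []
    for i, sample in enumerate(ds.samples):
        if not (0 <= sample.slice_index < geom.n_slices):
            raise IndexError(
                f"slice {i} (volume {sample.volume_id}, index {sample.slice_index}) "
                f"has no geometry entry"
            )
        w = column_ring_weights(geom, sample.slice_index)
        pred = Prediction(yhat[i])
        preds.append(pred)
        ring_preds.append(columns_to_rings(w, pred.column_probs()))
    return preds, ring_preds


def predictions_to_frame(
    ds: Dataset,
    preds: list[Prediction],
    ring_preds: list[RingPrediction],
    geom: ScanGeometry,
    marker_names: Sequence[str] = ("IRF", "SRF"),
) -> pd.DataFrame:
    """Long-format table: slice_id, target (slice/col_i/ring_*), marker, probability."""
    rows = []
    for i, (sample, pred, rp) in enumerate(zip(ds.samples, preds, ring_preds)):
        slice_id = f"v{sample.volume_id:03d}_s{sample.slice_index:03d}"
        arr = pred.array
        for b, marker in enumerate(marker_names):
            rows.append({"slice_id": slice_id, "target": "slice", "marker": marker, "probability": arr[0, b]})
            for c in range(pred.n_columns):
                rows.append({"slice_id": slice_id, "target": f"col_{c}", "marker": marker, "probability": arr[1 + c, b]})
            for j, dmm in enumerate(geom.ring_diameters_mm):
                rows.append(
                    {
                        "slice_id": slice_id,
                        "target": f"ring_{dmm:g}mm",
                        "marker": marker,
                        "probability": rp.probabilities[j, b] if rp.valid[j] else np.nan,
                    }
                )
    return pd.DataFrame(rows)
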