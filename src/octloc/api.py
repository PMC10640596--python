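"""High-level modelling interface.

``MarkerLocalizationModel`` bundles a dataset, a scan geometry and a training
configuration; ``fit()`` runs the two training stages and returns a
``MarkerLocalizationResults`` object carrying the fitted network, the loss
history, column/ring diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .evaluate import build_enface
from .geometry import ScanGeometry
from .model import ColumnHeadModel
from .train import Dataset, TrainConfig, finetune, predict_slices, pretrain_classifier

__all__ = ["MarkerLocalizationModel", "MarkerLocalizationResults"]


class MarkerLocalizationModel:
    """Weakly supervised column/ring localization model for B-scan markers.

    Parameters
    ----------
    dataset : Dataset
        Training slices with slice-level binary labels.
    geometry : ScanGeometry, optional
        Needed for ring-level prediction; defaults to the dataset's geometry.
    config : TrainConfig, optional
        Optimisation settings (defaults follow the published recipe).
    marker_names : sequence of str
        Names for the B marker channels.
    """

    def __init__(
        self,
        dataset: Dataset,
        geometry: ScanGeometry | None = None,
        config: TrainConfig | None = None,
        marker_names=("IRF", "SRF"),
    ):
        self.dataset = dataset
        self.geometry = geometry or dataset.geometry
        self.config = config or TrainConfig()
        self.marker_names = tuple(marker_names)

    def fit(self) -> "MarkerLocalizationResults":
        model = pretrain_classifier(self.dataset, self.config)
        model = finetune(self.dataset, model, self.config)
        return MarkerLocalizationResults(self, model)


class MarkerLocalizationResults:
    """Fitted model plus diagnostics."""

    def __init__(self, spec: MarkerLocalizationModel, network: ColumnHeadModel):
        self.model = spec
        self.network = network

    # ------------------------------------------------------------ predict
    def predict(self, dataset: Dataset | None = None):
        """Per-slice column predictions and ring predictions."""
        ds = dataset or self.model.dataset
        return predict_slices(ds, self.network, self.model.geometry)

    def enface(self, dataset: Dataset, image_width_px: int | None = None):
        """En-face probability map of one volume-ordered dataset."""
        geom = self.model.geometry
        preds, _ = self.predict(dataset)
        cols = [p.column_probs() for p in preds]
        width = image_width_px or dataset.samples[0].load_image().shape[1]
        return build_enface(cols, geom.lateral_um_per_px, geom.slice_spacing_um, width)

    # ---------------------------------------------------------- summaries
    def evaluate(self, dataset: Dataset | None = None) -> pd.DataFrame:
        """Column-level ROC AUC / AP per marker (requires column masks)."""
        from sklearn.metrics import average_precision_score, roc_auc_score

        ds = dataset or self.model.dataset
        preds, _ = self.predict(ds)
        rows = []
        for b, name in enumerate(self.model.marker_names):
            y = np.concatenate([s.column_mask[b] for s in ds.samples])
            p = np.concatenate([pred.column_probs()[:, b] for pred in preds])
            if len(np.unique(y)) < 2:
                rows.append({"marker": name, "column_auc": np.nan, "column_ap": np.nan, "positives": int(y.sum())})
            else:
                rows.append(
                    {
                        "marker": name,
                        "column_auc": float(roc_auc_score(y, p)),
                        "column_ap": float(average_precision_score(y, p)),
                        "positives": int(y.sum()),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self, eval_dataset: Dataset | None = None) -> str:
        cfg = self.model.config
        net = self.network.config
        n_params = sum(p.data.size for p in self.network.parameters())
        buf = io.StringIO()
        buf.write("Weakly supervised marker localization\n")
        buf.write("=" * 53 + "\n")
        buf.write(f"backbone: {net.backbone_name}  (D_z={net.feature_channels}, C={net.n_columns})\n")
        buf.write(f"markers: {', '.join(self.model.marker_names)}  parameters: {n_params}\n")
        buf.write(
            f"training: {cfg.pretrain_epochs} pretrain + {cfg.epochs} finetune epochs, "
            f"batch {cfg.batch_size}, lr {cfg.base_lr:g} (x{cfg.lr_decay:g}/epoch), "
            f"loss terms {{{', '.join(sorted(set(cfg.loss_terms)))}}}\n"
        )
        try:
            table = self.evaluate(eval_dataset)
            buf.write("-" * 53 + "\n")
            buf.write(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
            buf.write("\n")
        except (TypeError, AttributeError):
            buf.write("(no column masks available for evaluation)\n")
        return buf.getvalue()
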