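"""Evaluation: column labels from masks, ROC/AP metrics, en-face maps,
physical area quantification and method-agreement statistics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .geometry import RingPrediction, ScanGeometry

__all__ = [
    "EnFaceMap",
    "AgreementReport",
    "column_pixel_spans",
    "column_labels_from_mask",
    "ring_metrics",
    "build_enface",
    "enface_area_mm2",
    "bland_altman",
    "write_enface_tiff",
]


@dataclass
class EnFaceMap:
    """Top-down S x C probability grid for one volume and one or more markers.

    ``grid`` has shape (B, S, C): marker, slice (row), column.  Physical
    resolution metadata converts cells into areas.
    """

    grid: np.ndarray
    lateral_um_per_px: float
    slice_spacing_um: float
    image_width_px: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim == 2:
            self.grid = self.grid[None]
        if np.nanmin(self.grid) < 0 or np.nanmax(self.grid) > 1:
            raise ValueError("en-face probabilities must lie in [0, 1]")

    @property
    def n_markers(self) -> int:
        return self.grid.shape[0]

    @property
    def n_slices(self) -> int:
        return self.grid.shape[1]

    @property
    def n_columns(self) -> int:
        return self.grid.shape[2]


@dataclass
class AgreementReport:
    """Bland–Altman and correlation summary between two area measurements.

    Differences are predicted − reference; limits of agreement are
    ``mean ± 1.96·sd``.  Slope/intercept/R² are from the least-squares fit of
    predicted on reference.
    """

    pred_areas: np.ndarray
    ref_areas: np.ndarray
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    pearson_r: float
    slope: float
    intercept: float
    r_squared: float


def column_pixel_spans(width: int, n_columns: int) -> list[tuple[int, int]]:
    """Half-open pixel spans of each column.

    When ``width`` is not divisible by ``n_columns``, spans have width
    ``floor(width / C)`` and the remainder is distributed one pixel at a time
    to the rightmost columns (deterministic).
    """
    if n_columns < 1 or width < n_columns:
        raise ValueError("need width >= n_columns >= 1")
    base = width // n_columns
    rem = width - base * n_columns
    widths = [base + (1 if c >= n_columns - rem else 0) for c in range(n_columns)]
    edges = np.cumsum([0] + widths)
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def column_labels_from_mask(mask: np.ndarray, n_columns: int) -> np.ndarray:
    """Binary column labels: column c is positive iff any mask pixel falls in it."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D image")
    labels = np.zeros(n_columns, dtype=np.int64)
    if not mask.any():
        return labels
    for c, (a, b) in enumerate(column_pixel_spans(mask.shape[1], n_columns)):
        labels[c] = int(mask[:, a:b].any())
    return labels


def ring_metrics(
    preds: Sequence[RingPrediction],
    labels: np.ndarray,
    geom: ScanGeometry,
    marker_names: Sequence[str] = ("IRF", "SRF"),
) -> pd.DataFrame:
    """ROC AUC and AP per (ring, marker) over slices where the ring is valid.

    ``labels`` has shape (S, R, B).  A "Present" row gives slice-level
    metrics using the ring-union label (marker anywhere in the slice) against
    the maximum valid ring probability.  Classes with a single label value
    get NaN metrics and a warning.
    """
    labels = np.asarray(labels)
    probs = np.stack([p.probabilities for p in preds])  # S x R x B
    valid = np.stack([p.valid for p in preds])  # S x R
    rows = []
    ring_names = [f"{d:g}mm" for d in geom.ring_diameters_mm]
    for j, ring in enumerate(ring_names):
        sel = valid[:, j]
        for b, marker in enumerate(marker_names):
            y, p = labels[sel, j, b], probs[sel, j, b]
            rows.append({"ring": ring, "marker": marker, **_auc_ap(y, p)})
    # slice-level: union over valid rings
    any_label = (labels * valid[:, :, None]).max(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        any_prob = np.where(valid[:, :, None], probs, np.nan)
        any_prob = np.nanmax(any_prob, axis=1)
    for b, marker in enumerate(marker_names):
        rows.append({"ring": "Present", "marker": marker, **_auc_ap(any_label[:, b], any_prob[:, b])})
    return pd.DataFrame(rows)


def _auc_ap(y: np.ndarray, p: np.ndarray) -> dict:
    y = np.asarray(y).astype(int)
    if y.size == 0 or len(np.unique(y)) < 2:
        warnings.warn("metric undefined: class with no positives (or no negatives)")
        return {"auc": np.nan, "ap": np.nan, "n": int(y.size), "positives": int(y.sum())}
    return {
        "auc": float(roc_auc_score(y, p)),
        "ap": float(average_precision_score(y, p)),
        "n": int(y.size),
        "positives": int(y.sum()),
    }


def build_enface(
    volume_column_probs: Sequence[np.ndarray],
    lateral_um_per_px: float,
    slice_spacing_um: float,
    image_width_px: int,
) -> EnFaceMap:
    """Stack per-slice column probabilities (each C x B) into an S x C map per marker.

    Slices must be ordered by position; no smoothing is applied across them.
    """
    arrs = []
    for s, p in enumerate(volume_column_probs):
        if p is None:
            raise ValueError(f"missing column probabilities for slice {s}")
        arrs.append(np.asarray(p, dtype=float))
    stack = np.stack(arrs)  # S x C x B
    grid = stack.transpose(2, 0, 1)  # B x S x C
    return EnFaceMap(
        grid=grid,
        lateral_um_per_px=lateral_um_per_px,
        slice_spacing_um=slice_spacing_um,
        image_width_px=image_width_px,
    )


def enface_area_mm2(emap: EnFaceMap, threshold: float = 0.5) -> np.ndarray:
    """Physical area (mm²) of cells with probability >= threshold, per marker.

    One cell covers ``(image_width_px / C) * lateral_um_per_px`` laterally and
    ``slice_spacing_um`` sagittally.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    for name in ("lateral_um_per_px", "slice_spacing_um", "image_width_px"):
        if not getattr(emap, name):
            raise ValueError(f"missing resolution metadata: {name}")
    cell_mm2 = (
        (emap.image_width_px / emap.n_columns) * emap.lateral_um_per_px / 1000.0
    ) * (emap.slice_spacing_um / 1000.0)
    counts = (emap.grid >= threshold).sum(axis=(1, 2))
    return counts * cell_mm2


def bland_altman(pred_areas: Sequence[float], ref_areas: Sequence[float]) -> AgreementReport:
    """Agreement between predicted and reference per-volume areas."""
    pred = np.asarray(pred_areas, dtype=float)
    ref = np.asarray(ref_areas, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValueError("pred and ref must be paired 1-D sequences")
    if pred.size < 2:
        raise ValueError("need at least two paired measurements")
    diff = pred - ref
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    if np.ptp(ref) == 0 or np.ptp(pred) == 0:
        r = np.nan
        slope, intercept, r2 = np.nan, np.nan, np.nan
    else:
        r = float(stats.pearsonr(pred, ref).statistic)
        fit = stats.linregress(ref, pred)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    return AgreementReport(
        pred_areas=pred,
        ref_areas=ref,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_lower=mean_diff - 1.96 * sd_diff,
        loa_upper=mean_diff + 1.96 * sd_diff,
        pearson_r=r,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
    )


def write_enface_tiff(emap: EnFaceMap, path: str | Path) -> None:
    """16-bit single-channel TIFF per marker (probability x 65535) + JSON sidecar."""
    path = Path(path)
    data = np.round(emap.grid * 65535).astype(np.uint16)
    tifffile.imwrite(path.with_suffix(".tiff"), data)
    sidecar = {
        "lateral_um_per_px": emap.lateral_um_per_px,
        "slice_spacing_um": emap.slice_spacing_um,
        "image_width_px": emap.image_width_px,
        "axes": "marker,slice,column",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
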