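"""ETDRS ring geometry on B-scan columns.

The ETDRS grid is a set of concentric circles (diameters 1, 3 and 6 mm by
convention) centered on the fovea.  A B-scan at signed distance ``d`` from the
fovea-centered horizontal axis intersects ring ``j`` (the annulus between
radii ``r_{j-1}`` and ``r_j``, with ``r_0 = 0``) in zero, one or two vertical
stripes given by the circle-chord rule: the disc of radius ``r`` covers the
lateral interval ``|x - x_f| < sqrt(r^2 - d^2)`` whenever ``|d| < r``.

Everything lateral is measured in millimetres from the *left edge* of the
B-scan; intervals are half-open ``[a, b)``; columns are the ``C`` equal-width
strips tied to the width of the network's feature map, indexed from the left.
Rings are indexed from the innermost (ring 1 = central 1 mm disc).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScanGeometry",
    "RingLayout",
    "ColumnRingWeights",
    "RingPrediction",
    "ring_stripes",
    "column_ring_weights",
    "columns_to_rings",
    "ring_predictions_to_frame",
]


@dataclass(frozen=True)
class ScanGeometry:
    """Physical layout of a C-scan and the ETDRS ring diameters.

    Parameters
    ----------
    scan_width_mm : float
        Lateral extent of one B-scan in mm.
    slice_positions_mm : sequence of float
        Signed distance of each B-scan from the fovea-centered horizontal
        axis, in mm (0 = the slice through the fovea).
    fovea_lateral_mm : float, optional
        Lateral coordinate of the fovea center; defaults to the scan center.
    ring_diameters_mm : sequence of float
        Ordered ring diameters; default the clinical 1/3/6 mm grid.
    n_columns : int
        Number of equal-width columns ``C`` the slice is partitioned into.
    lateral_um_per_px : float
        Lateral pixel size in micrometres.
    slice_spacing_um : float
        Spacing between consecutive B-scans in micrometres.
    """

    scan_width_mm: float
    slice_positions_mm: tuple[float, ...]
    fovea_lateral_mm: float | None = None
    ring_diameters_mm: tuple[float, ...] = (1.0, 3.0, 6.0)
    n_columns: int = 16
    lateral_um_per_px: float = 11.72
    slice_spacing_um: float = 120.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "slice_positions_mm", tuple(float(p) for p in self.slice_positions_mm))
        object.__setattr__(self, "ring_diameters_mm", tuple(float(d) for d in self.ring_diameters_mm))
        if self.scan_width_mm <= 0:
            raise ValueError("scan_width_mm must be positive")
        if self.n_columns < 1:
            raise ValueError("n_columns must be >= 1")
        diam = np.asarray(self.ring_diameters_mm)
        if diam.size == 0 or np.any(diam <= 0) or np.any(np.diff(diam) <= 0):
            raise ValueError("ring_diameters_mm must be positive and strictly increasing")
        if self.fovea_lateral_mm is None:
            object.__setattr__(self, "fovea_lateral_mm", self.scan_width_mm / 2.0)

    @property
    def n_slices(self) -> int:
        return len(self.slice_positions_mm)

    @property
    def n_rings(self) -> int:
        return len(self.ring_diameters_mm)

    @property
    def ring_radii_mm(self) -> tuple[float, ...]:
        return tuple(d / 2.0 for d in self.ring_diameters_mm)

    @property
    def column_edges_mm(self) -> np.ndarray:
        return np.linspace(0.0, self.scan_width_mm, self.n_columns + 1)

    def slice_distance_mm(self, slice_index: int) -> float:
        if not (0 <= slice_index < self.n_slices):
            raise IndexError(f"slice_index {slice_index} out of range [0, {self.n_slices})")
        return self.slice_positions_mm[slice_index]

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_mapping(cls, m: dict) -> "ScanGeometry":
        """Build from a plain dict as read from YAML/JSON.

        Slice positions may be given explicitly (``slice_positions_mm``) or as
        ``n_slices`` + ``slice_spacing_um`` + ``centered: true``, in which
        case slices are evenly spaced and centered on the fovea axis.
        """
        m = dict(m)
        if "slice_positions_mm" in m:
            positions = [float(p) for p in m.pop("slice_positions_mm")]
        else:
            n = int(m.pop("n_slices"))
            spacing_mm = float(m["slice_spacing_um"]) / 1000.0
            if not m.pop("centered", True):
                raise ValueError("implicit slice positions require centered: true")
            positions = [(i - (n - 1) / 2.0) * spacing_mm for i in range(n)]
        known = {
            "scan_width_mm",
            "fovea_lateral_mm",
            "ring_diameters_mm",
            "n_columns",
            "lateral_um_per_px",
            "slice_spacing_um",
        }
        kwargs = {k: m[k] for k in known if k in m}
        if "ring_diameters_mm" in kwargs:
            kwargs["ring_diameters_mm"] = tuple(kwargs["ring_diameters_mm"])
        return cls(scan_width_mm=float(m["scan_width_mm"]), slice_positions_mm=tuple(positions), **{k: v for k, v in kwargs.items() if k != "scan_width_mm"})

    @classmethod
    def from_file(cls, path: str | Path) -> "ScanGeometry":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        return cls.from_mapping(data)

    def to_mapping(self) -> dict:
        return {
            "scan_width_mm": self.scan_width_mm,
            "slice_positions_mm": list(self.slice_positions_mm),
            "fovea_lateral_mm": self.fovea_lateral_mm,
            "ring_diameters_mm": list(self.ring_diameters_mm),
            "n_columns": self.n_columns,
            "lateral_um_per_px": self.lateral_um_per_px,
            "slice_spacing_um": self.slice_spacing_um,
        }

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_mapping(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_mapping(), sort_keys=False))


@dataclass(frozen=True)
class RingLayout:
    """Vertical stripes each ring occupies in one B-scan.

    ``stripes[j]`` is a list of 0, 1 or 2 half-open lateral intervals
    ``(a, b)`` in mm for ring ``j`` (0-based from the innermost ring).
    """

    slice_index: int
    stripes: tuple[tuple[tuple[float, float], ...], ...]


@dataclass(frozen=True)
class ColumnRingWeights:
    """Fraction of each column's width lying inside each ring (C x R)."""

    w: np.ndarray
    slice_index: int

    @property
    def n_columns(self) -> int:
        return self.w.shape[0]

    @property
    def n_rings(self) -> int:
        return self.w.shape[1]


@dataclass(frozen=True)
class RingPrediction:
    """Per-ring marker probabilities with a visibility flag per ring.

    ``probabilities`` has shape R x B; rows of rings that are not visible in
    the slice (``valid[j] is False``) are NaN and carry no probability.
    """

    probabilities: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        p = self.probabilities[self.valid]
        if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
            raise ValueError("ring probabilities outside [0, 1]")


def _interval_clip(a: float, b: float, lo: float, hi: float) -> tuple[float, float] | None:
    a, b = max(a, lo), min(b, hi)
    return (a, b) if b > a else None


def ring_stripes(geom: ScanGeometry, slice_index: int) -> RingLayout:
    """Compute the lateral stripes each ETDRS ring occupies in a slice.

    For a slice at signed distance ``d`` from the fovea and ring ``j`` with
    inner/outer radii ``r_{j-1} < r_j``: the ring is absent when
    ``|d| >= r_j``; it is the single stripe ``|x - x_f| < h_j`` when
    ``r_{j-1} <= |d| < r_j``; otherwise it is the two stripes
    ``h_{j-1} <= |x - x_f| < h_j``, where ``h_k = sqrt(r_k^2 - d^2)``.
    Stripes are clipped to ``[0, scan_width_mm)``.
    """
    d = abs(geom.slice_distance_mm(slice_index))
    xf = float(geom.fovea_lateral_mm)
    radii = geom.ring_radii_mm
    stripes: list[tuple[tuple[float, float], ...]] = []
    prev_r = 0.0
    for r in radii:
        if d >= r:
            stripes.append(())
        else:
            h = float(np.sqrt(r * r - d * d))
            if d >= prev_r:
                ivs = [_interval_clip(xf - h, xf + h, 0.0, geom.scan_width_mm)]
            else:
                h_prev = float(np.sqrt(prev_r * prev_r - d * d))
                ivs = [
                    _interval_clip(xf - h, xf - h_prev, 0.0, geom.scan_width_mm),
                    _interval_clip(xf + h_prev, xf + h, 0.0, geom.scan_width_mm),
                ]
            stripes.append(tuple(iv for iv in ivs if iv is not None))
        prev_r = r
    return RingLayout(slice_index=slice_index, stripes=tuple(stripes))


def column_ring_weights(geom: ScanGeometry, slice_index: int) -> ColumnRingWeights:
    """Fractional membership of each column in each ring for one slice.

    ``w[c, j]`` is the length of the intersection of column ``c`` with the
    stripes of ring ``j``, divided by the column width.  A slice farther from
    the fovea than the outermost radius yields an all-zero matrix.
    """
    layout = ring_stripes(geom, slice_index)
    edges = geom.column_edges_mm
    width = edges[1] - edges[0]
    w = np.zeros((geom.n_columns, geom.n_rings))
    for j, ivs in enumerate(layout.stripes):
        for a, b in ivs:
            lo = np.minimum(np.maximum(edges[:-1], a), b)
            hi = np.minimum(np.maximum(edges[1:], a), b)
            w[:, j] += (hi - lo) / width
    return ColumnRingWeights(w=w, slice_index=slice_index)


def columns_to_rings(weights: ColumnRingWeights, column_probs: np.ndarray) -> RingPrediction:
    """Aggregate column probabilities into ring probabilities.

    Each ring takes the maximum over columns of the column probability scaled
    by the column's fractional membership in the ring, so a column fully
    inside a ring contributes its probability unchanged and a column outside
    contributes nothing.  Rings with no overlapping column are flagged
    invalid and carry NaN.
    """
    p = np.asarray(column_probs, dtype=float)
    if p.ndim == 1:
        p = p[:, None]
    if p.shape[0] != weights.n_columns:
        raise ValueError(f"column_probs has {p.shape[0]} columns, weights expect {weights.n_columns}")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("column probabilities must lie in [0, 1]")
    w = weights.w  # C x R
    contrib = w[:, :, None] * p[:, None, :]  # C x R x B
    probs = contrib.max(axis=0)
    valid = (w > 0).any(axis=0)
    probs = np.where(valid[:, None], probs, np.nan)
    return RingPrediction(probabilities=probs, valid=valid)


def ring_predictions_to_frame(
    preds: Sequence[RingPrediction],
    geom: ScanGeometry,
    marker_names: Sequence[str] = ("IRF", "SRF"),
) -> pd.DataFrame:
    """Tabulate ring predictions as rows (slice_index, ring, marker, probability, valid)."""
    rows = []
    for s, rp in enumerate(preds):
        for j in range(geom.n_rings):
            ring = f"ring_{geom.ring_diameters_mm[j]:g}mm"
            for b, marker in enumerate(marker_names):
                rows.append(
                    {
                        "slice_index": s,
                        "ring": ring,
                        "marker": marker,
                        "probability": rp.probabilities[j, b],
                        "valid": bool(rp.valid[j]),
                    }
                )
    return pd.DataFrame(rows)
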