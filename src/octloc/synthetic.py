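"""Synthetic OCT-like B-scans with fluid-like markers at known positions.

Real OCT slices show a bright, layered retina band on a dark background with
multiplicative speckle.  Intraretinal fluid appears as dark blobs inside the
band; subretinal fluid as pockets hugging the lower retinal boundary.  The
generator emulates exactly those cues: a curved, layered band; dark elliptic
inclusions for the IRF-like marker; bright elongated sub-band pockets for the
SRF-like marker.  Every sample carries its full ground truth (pixel masks,
column masks, slice labels, distance from the fovea), which the clinical data
this stands in for does not — the generator is the test bed for the method,
not a physical speckle simulation.

All randomness flows from the config seed; the same seed reproduces the same
dataset bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .evaluate import column_labels_from_mask
from .geometry import ScanGeometry

__all__ = [
    "MarkerSpec",
    "SynthConfig",
    "SyntheticSample",
    "Blob",
    "render_slice",
    "generate_slice",
    "generate_volume",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class MarkerSpec:
    """How one marker class looks and where it occurs.

    ``polarity`` is "dark" (intensity suppressed inside the blob, IRF-like)
    or "bright" (intensity raised, SRF-like).  ``lateral`` chooses the blob
    center distribution along x: "uniform" across the scan or "central"
    (Gaussian around the scan center), the latter mimicking markers that
    rarely reach the outer rings.  Semi-axis ranges are in pixels.
    """

    name: str
    presence_prob: float = 0.5
    max_count: int = 3
    semiaxis_y: tuple[int, int] = (4, 9)
    semiaxis_x: tuple[int, int] = (5, 12)
    contrast: float = 0.55
    polarity: str = "dark"
    lateral: str = "uniform"

    def __post_init__(self) -> None:
        if not (0.0 <= self.presence_prob <= 1.0):
            raise ValueError("presence_prob must be in [0, 1]")
        if not (0.0 < self.contrast <= 1.0):
            raise ValueError("contrast must be in (0, 1]")
        if self.polarity not in ("dark", "bright"):
            raise ValueError("polarity must be 'dark' or 'bright'")
        if self.lateral not in ("uniform", "central"):
            raise ValueError("lateral must be 'uniform' or 'central'")


def _default_markers() -> tuple[MarkerSpec, ...]:
    return (
        MarkerSpec(name="IRF", presence_prob=0.5, max_count=2, semiaxis_y=(6, 11), semiaxis_x=(9, 15), contrast=0.65, polarity="dark", lateral="uniform"),
        MarkerSpec(name="SRF", presence_prob=0.05, max_count=1, semiaxis_y=(4, 7), semiaxis_x=(14, 24), contrast=0.5, polarity="bright", lateral="central"),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic benchmark."""

    height: int = 128
    width: int = 128
    n_volumes: int = 8
    slices_per_volume: int = 8
    scan_width_mm: float = 6.0
    slice_spacing_um: float = 750.0
    n_columns: int = 8
    markers: tuple[MarkerSpec, ...] = field(default_factory=_default_markers)
    speckle_sigma: float = 0.08
    n_layers: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.height, self.width, self.n_volumes, self.slices_per_volume, self.n_columns) < 1:
            raise ValueError("sizes must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for m in self.markers:
            if m.semiaxis_y[1] * 2 >= self.height or m.semiaxis_x[1] * 2 >= self.width:
                raise ValueError(f"marker '{m.name}' blob larger than image")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def geometry(self) -> ScanGeometry:
        n = self.slices_per_volume
        spacing_mm = self.slice_spacing_um / 1000.0
        positions = tuple((i - (n - 1) / 2.0) * spacing_mm for i in range(n))
        return ScanGeometry(
            scan_width_mm=self.scan_width_mm,
            slice_positions_mm=positions,
            n_columns=self.n_columns,
            lateral_um_per_px=self.scan_width_mm * 1000.0 / self.width,
            slice_spacing_um=self.slice_spacing_um,
        )


@dataclass(frozen=True)
class Blob:
    """One fluid pocket instance in one slice (pixel coordinates)."""

    marker: int
    cy: float
    cx: float
    ay: float
    ax: float

    def footprint(self, height: int, width: int) -> np.ndarray:
        yy, xx = np.mgrid[0:height, 0:width]
        return ((yy - self.cy) / self.ay) ** 2 + ((xx - self.cx) / self.ax) ** 2 <= 1.0


@dataclass
class SyntheticSample:
    """A B-scan with its labels and ground-truth masks."""

    image: np.ndarray  # H x W float32 in [0, 1]
    y0: np.ndarray  # B, binary
    pixel_masks: np.ndarray  # B x H x W bool
    column_masks: np.ndarray  # B x C binary
    distance_mm: float = 0.0
    volume_id: int = 0
    slice_index: int = 0


def _background(cfg: SynthConfig, rng: np.random.Generator):
    """Curved layered retina band on a dark floor; returns image and band bounds."""
    h, w = cfg.height, cfg.width
    x = np.arange(w)
    curve = (h * 0.05) * np.sin(np.pi * x / w + rng.uniform(0, np.pi))
    # band position/thickness and mean reflectivity kept near-constant across
    # slices so that fluid, not background drift, dominates column statistics
    top = h * rng.uniform(0.24, 0.28) + curve
    bot = top + h * 0.47
    yy = np.arange(h)[:, None]
    depth = (yy - top[None, :]) / (bot - top)[None, :]
    inside = (depth >= 0) & (depth < 1)
    edges = np.sort(rng.uniform(0.05, 0.95, size=cfg.n_layers - 1))
    levels = rng.uniform(0.50, 0.66, size=cfg.n_layers)
    # normalize the depth-weighted mean so slice-to-slice reflectivity drift
    # stays well below the intensity deficit of a fluid pocket
    widths = np.diff(np.concatenate([[0.0], edges, [1.0]]))
    levels += 0.58 - float(levels @ widths)
    layer_idx = np.searchsorted(edges, np.clip(depth, 0, 1 - 1e-6))
    img = np.where(inside, levels[layer_idx], 0.12).astype(np.float32)
    return img, top, bot


def _draw_blobs(cfg: SynthConfig, rng: np.random.Generator, top: np.ndarray, bot: np.ndarray, forced: list[Blob] | None):
    """Sample blob instances for one slice (or take forced ones)."""
    if forced is not None:
        return list(forced)
    blobs: list[Blob] = []
    h, w = cfg.height, cfg.width
    for b, spec in enumerate(cfg.markers):
        if rng.uniform() >= spec.presence_prob:
            continue
        count = int(rng.integers(1, spec.max_count + 1))
        for _ in range(count):
            ax = float(rng.uniform(*spec.semiaxis_x))
            ay = float(rng.uniform(*spec.semiaxis_y))
            if spec.lateral == "central":
                cx = float(np.clip(rng.normal(w / 2.0, w / 8.0), ax + 1, w - ax - 2))
            else:
                cx = float(rng.uniform(ax + 1, w - ax - 2))
            j = int(np.clip(round(cx), 0, w - 1))
            if spec.polarity == "bright":
                cy = float(bot[j] - ay * 0.5)  # pocket hugging the lower boundary
            else:
                lo, hi = top[j] + ay + 1, bot[j] - ay - 1
                cy = float(rng.uniform(lo, max(lo + 1, hi)))
            blobs.append(Blob(marker=b, cy=cy, cx=cx, ay=ay, ax=ax))
    return blobs


def render_slice(cfg: SynthConfig, rng: np.random.Generator, blobs: list[Blob] | None = None, distance_mm: float = 0.0) -> SyntheticSample:
    """Composite a background and a given (or sampled) set of blobs.

    Ground truths are derived from the rasterized footprints, so the slice
    label is 1 exactly when at least one pixel of the marker survives
    rasterization, and the column mask follows the at-least-one-pixel rule.
    """
    img, top, bot = _background(cfg, rng)
    blobs = _draw_blobs(cfg, rng, top, bot, blobs)
    h, w = cfg.height, cfg.width
    masks = np.zeros((cfg.n_markers, h, w), dtype=bool)
    for blob in blobs:
        fp = blob.footprint(h, w)
        spec = cfg.markers[blob.marker]
        if spec.polarity == "dark":
            img = np.where(fp, img * (1.0 - spec.contrast), img)
        else:
            img = np.where(fp, np.clip(img + spec.contrast, 0, 1), img)
        masks[blob.marker] |= fp
    speckle = 1.0 + cfg.speckle_sigma * rng.standard_normal((h, w))
    img = np.clip(img * speckle, 0.0, 1.0).astype(np.float32)
    y0 = masks.any(axis=(1, 2)).astype(np.int64)
    cols = np.stack([column_labels_from_mask(m, cfg.n_columns) for m in masks])
    return SyntheticSample(image=img, y0=y0, pixel_masks=masks, column_masks=cols, distance_mm=distance_mm)


def generate_slice(cfg: SynthConfig, rng: np.random.Generator | int | None = None) -> SyntheticSample:
    """Draw one independent labelled B-scan."""
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    return render_slice(cfg, rng)


@dataclass(frozen=True)
class _Pocket:
    marker: int
    slice_range: tuple[int, int]  # inclusive
    cx: float
    ax: float
    ay: float


def _sample_pockets(cfg: SynthConfig, rng: np.random.Generator) -> list[_Pocket]:
    pockets: list[_Pocket] = []
    s = cfg.slices_per_volume
    w = cfg.width
    for b, spec in enumerate(cfg.markers):
        # expected slice-level prevalence ~ presence_prob (pocket spans several slices)
        span = min(s, int(rng.integers(2, 5)))
        n_pockets = rng.binomial(max(1, s // span), spec.presence_prob)
        for _ in range(n_pockets):
            s0 = int(rng.integers(0, max(1, s - span + 1)))
            ax = float(rng.uniform(*spec.semiaxis_x))
            ay = float(rng.uniform(*spec.semiaxis_y))
            if spec.lateral == "central":
                cx = float(np.clip(rng.normal(w / 2.0, w / 8.0), ax + 1, w - ax - 2))
            else:
                cx = float(rng.uniform(ax + 1, w - ax - 2))
            pockets.append(_Pocket(marker=b, slice_range=(s0, s0 + span - 1), cx=cx, ax=ax, ay=ay))
    return pockets


def generate_volume(cfg: SynthConfig, rng: np.random.Generator | int | None = None, volume_id: int = 0) -> tuple[list[SyntheticSample], ScanGeometry]:
    """Generate one C-scan whose fluid pockets span consecutive slices.

    A pocket keeps its lateral position (with sub-pixel jitter) across its
    slice range, so the en-face ground truth is a spatially coherent patch.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    geom = cfg.geometry()
    pockets = _sample_pockets(cfg, rng)
    samples = []
    for s in range(cfg.slices_per_volume):
        blobs = []
        for p in pockets:
            if p.slice_range[0] <= s <= p.slice_range[1]:
                spec = cfg.markers[p.marker]
                cx = p.cx + float(rng.normal(0.0, 0.5))
                blobs.append(Blob(marker=p.marker, cy=-1.0, cx=cx, ay=p.ay, ax=p.ax))
        sample = _render_with_band_anchored_blobs(cfg, rng, blobs, geom.slice_positions_mm[s])
        sample.volume_id = volume_id
        sample.slice_index = s
        samples.append(sample)
    return samples, geom


def _render_with_band_anchored_blobs(cfg: SynthConfig, rng: np.random.Generator, blobs: list[Blob], distance_mm: float) -> SyntheticSample:
    """Render a slice, anchoring blob depth to the background band."""
    img, top, bot = _background(cfg, rng)
    h, w = cfg.height, cfg.width
    resolved = []
    for blob in blobs:
        spec = cfg.markers[blob.marker]
        j = int(np.clip(round(blob.cx), 0, w - 1))
        if spec.polarity == "bright":
            cy = float(bot[j] - blob.ay * 0.5)
        else:
            lo, hi = top[j] + blob.ay + 1, bot[j] - blob.ay - 1
            cy = float(rng.uniform(lo, max(lo + 1, hi)))
        resolved.append(Blob(marker=blob.marker, cy=cy, cx=blob.cx, ay=blob.ay, ax=blob.ax))
    masks = np.zeros((cfg.n_markers, h, w), dtype=bool)
    for blob in resolved:
        fp = blob.footprint(h, w)
        spec = cfg.markers[blob.marker]
        if spec.polarity == "dark":
            img = np.where(fp, img * (1.0 - spec.contrast), img)
        else:
            img = np.where(fp, np.clip(img + spec.contrast, 0, 1), img)
        masks[blob.marker] |= fp
    speckle = 1.0 + cfg.speckle_sigma * rng.standard_normal((h, w))
    img = np.clip(img * speckle, 0.0, 1.0).astype(np.float32)
    y0 = masks.any(axis=(1, 2)).astype(np.int64)
    cols = np.stack([column_labels_from_mask(m, cfg.n_columns) for m in masks])
    return SyntheticSample(image=img, y0=y0, pixel_masks=masks, column_masks=cols, distance_mm=distance_mm)


def generate_dataset(cfg: SynthConfig) -> tuple[list[SyntheticSample], ScanGeometry]:
    """All volumes of the configured dataset, seeded from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    samples: list[SyntheticSample] = []
    geom = cfg.geometry()
    for v in range(cfg.n_volumes):
        vol, geom = generate_volume(cfg, rng, volume_id=v)
        samples.extend(vol)
    return samples, geom


def write_dataset(samples: list[SyntheticSample], geom: ScanGeometry, out_dir: str | Path, cfg: SynthConfig | None = None) -> dict:
    """Write images/masks as PNG, labels as CSV, geometry as YAML, manifest as JSON."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    marker_names = [m.name for m in cfg.markers] if cfg else [f"m{b}" for b in range(samples[0].y0.size)]
    rows = []
    files = []
    for i, s in enumerate(samples):
        slice_id = f"v{s.volume_id:03d}_s{s.slice_index:03d}"
        img_path = out / "images" / f"{slice_id}.png"
        Image.fromarray((s.image * 255).astype(np.uint8)).save(img_path)
        files.append(str(img_path.relative_to(out)))
        for b, name in enumerate(marker_names):
            mask_path = out / "masks" / f"{slice_id}_{name}.png"
            Image.fromarray((s.pixel_masks[b] * 255).astype(np.uint8)).save(mask_path)
            files.append(str(mask_path.relative_to(out)))
        row = {"slice_id": slice_id, "volume_id": s.volume_id, "slice_index": s.slice_index, "distance_mm": s.distance_mm}
        row.update({name.lower(): int(s.y0[b]) for b, name in enumerate(marker_names)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
    geom.to_file(out / "geometry.yaml")
    manifest = {
        "n_samples": len(samples),
        "markers": marker_names,
        "seed": cfg.seed if cfg else None,
        "files": files,
        "labels": "labels.csv",
        "geometry": "geometry.yaml",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
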