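"""Weak-supervision loss terms.

Training sees only slice-level presence labels ``y0 in {0,1}^B``.  Three
terms shape the column outputs anyway:

* ``l1`` — plain binary cross-entropy on the slice-level row, summed over
  markers.
* ``l2`` — the multiple-instance constraint tying columns to the slice
  label: when marker ``b`` is absent, every column is pushed down
  (mean over columns of ``-log(1 - yhat_cb)``); when present, at least one
  column must fire (``-log max_c yhat_cb``).
* ``l3`` — flip consistency: the column probabilities of a horizontally
  flipped input must be the flipped column probabilities, enforced with a
  symmetric Bernoulli KL divergence per (column, marker) pair.

The total loss is ``l1 + l1' + l2 + l2' + l3`` evaluated on a slice and its
horizontal flip.  Probabilities are clamped to ``[eps, 1-eps]`` before any
logarithm; losses are summed over markers and averaged over the batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Prediction
from .nn import Tensor, as_tensor

__all__ = [
    "EPS",
    "LossBreakdown",
    "loss_slice_bce",
    "loss_column_constraint",
    "loss_flip_symmetry",
    "loss_total",
    "ALLOWED_TERM_SETS",
]

EPS = 1e-7

# ablation nesting: l2 requires l1, l3 requires l2
ALLOWED_TERM_SETS = (frozenset({"l1"}), frozenset({"l1", "l2"}), frozenset({"l1", "l2", "l3"}))


@dataclass
class LossBreakdown:
    """Per-term loss values; ``total`` is the sum of the active terms."""

    l1: float
    l1_flip: float
    l2: float
    l2_flip: float
    l3: float
    total: float
    total_tensor: Tensor | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("l1", "l1_flip", "l2", "l2_flip", "l3", "total")}


def _as_batched(pred) -> Tensor:
    """Accept Prediction / Tensor / ndarray of shape (..., 1+C, B); add batch dim."""
    t = pred.yhat if isinstance(pred, Prediction) else as_tensor(pred)
    if t.ndim == 2:
        t = t.reshape(1, *t.shape)
    if t.ndim != 3:
        raise ValueError(f"prediction must be (1+C) x B or batched, got shape {t.shape}")
    return t


def _check_labels(y0: np.ndarray, n_markers: int, batch: int) -> np.ndarray:
    y = np.asarray(y0, dtype=np.float32)
    if y.ndim == 1:
        y = np.broadcast_to(y, (batch, y.shape[0]))
    if y.shape != (batch, n_markers):
        raise ValueError(f"labels shape {y.shape} incompatible with predictions ({batch}, {n_markers})")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("slice labels must be binary")
    return y


def _maybe_float(value: Tensor, want_tensor: bool):
    return value if want_tensor else float(value.data)


def loss_slice_bce(pred, y0) -> float | Tensor:
    """l1: binary cross-entropy of the slice-level row, summed over markers."""
    want_tensor = isinstance(pred, Prediction) or isinstance(pred, Tensor)
    t = _as_batched(pred)
    n, _, b = t.shape
    y = _check_labels(y0, b, n)
    p = t[:, 0, :].clip(EPS, 1.0 - EPS)
    bce = -(y * p.log() + (1.0 - y) * (1.0 - p).log())
    return _maybe_float(bce.sum(axis=1).mean(), want_tensor)


def loss_column_constraint(pred, y0) -> float | Tensor:
    """l2: column-level multiple-instance constraint from the slice label."""
    want_tensor = isinstance(pred, Prediction) or isinstance(pred, Tensor)
    t = _as_batched(pred)
    n, c1, b = t.shape
    if c1 < 2:
        raise ValueError("prediction has no column rows")
    y = _check_labels(y0, b, n)
    p = t[:, 1:, :].clip(EPS, 1.0 - EPS)  # N x C x B
    absent = -((1.0 - p).log().mean(axis=1)) * (1.0 - y)  # N x B
    # log of max == max of log (log is monotone); max keeps ties at lowest index
    present = -(p.amax(axis=1).log()) * y
    return _maybe_float((absent + present).sum(axis=1).mean(), want_tensor)


def _bernoulli_kl(p: Tensor, q: Tensor) -> Tensor:
    return p * (p.log() - q.log()) + (1.0 - p) * ((1.0 - p).log() - (1.0 - q).log())


def loss_flip_symmetry(pred, pred_flip) -> float | Tensor:
    """l3: symmetric Bernoulli KL between column rows and their mirrored pair.

    ``pred_flip`` is the model output on the horizontally flipped image; its
    column ``c`` should match column ``C-1-c`` of ``pred``.  The slice-level
    row is excluded.
    """
    want_tensor = isinstance(pred, (Prediction, Tensor)) or isinstance(pred_flip, (Prediction, Tensor))
    t = _as_batched(pred)
    tf = _as_batched(pred_flip)
    if t.shape != tf.shape:
        raise ValueError(f"prediction shapes differ: {t.shape} vs {tf.shape}")
    p = t[:, 1:, :].clip(EPS, 1.0 - EPS)
    q = tf[:, 1:, :].clip(EPS, 1.0 - EPS)
    q_rev = q.flip(axis=1)  # column C-1-c of the flipped prediction
    p_rev = p.flip(axis=1)
    kl = _bernoulli_kl(p, q_rev) + _bernoulli_kl(q, p_rev)
    return _maybe_float((0.5 * kl).sum(axis=(1, 2)).mean(), want_tensor)


def loss_total(pred, pred_flip, y0, terms=("l1", "l2", "l3")) -> LossBreakdown:
    """Symmetric total loss on a slice and its horizontal flip.

    ``terms`` selects the ablation configuration; only the nested subsets
    {l1}, {l1,l2} and {l1,l2,l3} are accepted.
    """
    term_set = frozenset(terms)
    if term_set not in ALLOWED_TERM_SETS:
        raise ValueError(f"loss terms {sorted(term_set)} not one of the supported nested subsets")
    zero = Tensor(np.zeros((), dtype=np.float32))
    l1 = loss_slice_bce(pred, y0)
    l1f = loss_slice_bce(pred_flip, y0)
    l2 = loss_column_constraint(pred, y0) if "l2" in term_set else zero
    l2f = loss_column_constraint(pred_flip, y0) if "l2" in term_set else zero
    l3 = loss_flip_symmetry(pred, pred_flip) if "l3" in term_set else zero

    tensors = [as_tensor(v) for v in (l1, l1f, l2, l2f, l3)]
    total = tensors[0]
    for t in tensors[1:]:
        total = total + t
    return LossBreakdown(
        l1=float(tensors[0].data),
        l1_flip=float(tensors[1].data),
        l2=float(tensors[2].data),
        l2_flip=float(tensors[3].data),
        l3=float(tensors[4].data),
        total=float(total.data),
        total_tensor=total,
    )
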