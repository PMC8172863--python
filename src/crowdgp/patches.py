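"""Patch-level utilities for mask-annotated images.

Region annotations arrive as integer label masks (0 = unlabeled/other,
1..K = classes).  Patches are extracted on a grid and receive the label of
the dominant class when it covers at least half of the patch; dense
prediction slides a window across the image (typically with very high
overlap) and averages the per-window class distributions pixel-wise; DICE
scores the overlap between predicted and reference regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class LabelMask:
    """2-D integer class-label image.

    ``grid`` holds values in {0..K} with 0 meaning unlabeled/other; ``note``
    carries free-form resolution metadata.
    """

    grid: np.ndarray
    note: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or self.grid.shape[0] < 1 or self.grid.shape[1] < 1:
            raise ValueError("mask grid must be 2-D and non-empty")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("mask grid must be integer-valued")
        if self.grid.min() < 0:
            raise ValueError("mask labels must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass(frozen=True)
class PatchRecord:
    """One extracted patch: 0-based top-left corner, side length, label.

    The patch covers the half-open window [row0, row0+size) x [col0,
    col0+size) and lies fully inside the source mask.
    """

    row0: int
    col0: int
    size: int
    label: int


def _window_starts(extent: int, size: int, stride: int) -> list[int]:
    """Window start offsets; a final window is shifted inward to touch the
    border when the stride does not land there exactly."""
    starts = list(range(0, extent - size + 1, stride))
    if starts[-1] != extent - size:
        starts.append(extent - size)
    return starts


def extract_patches(
    mask: LabelMask, patch_size: int, stride: int
) -> list[PatchRecord]:
    """Extract labeled patches on a stride grid.

    A patch is labeled with class k when at least half of its pixels carry
    label k and k is the only such class; exact 50/50 two-class ties and
    patches with no qualifying class are discarded.
    """
    H, W = mask.shape
    if patch_size > min(H, W):
        raise ValueError(
            f"patch_size {patch_size} exceeds mask extent {min(H, W)}"
        )
    if stride < 1:
        raise ValueError("stride must be >= 1")
    K = int(mask.grid.max())
    half = patch_size * patch_size / 2.0
    out: list[PatchRecord] = []
    for r in _window_starts(H, patch_size, stride):
        for c in _window_starts(W, patch_size, stride):
            window = mask.grid[r : r + patch_size, c : c + patch_size]
            counts = np.bincount(window.ravel(), minlength=K + 1)[1:]
            qualifying = np.flatnonzero(counts >= half)
            if qualifying.size == 1:
                out.append(
                    PatchRecord(r, c, patch_size, int(qualifying[0]) + 1)
                )
    return out


def majority_vote(masks: Sequence[LabelMask]) -> LabelMask:
    """Pixel-wise modal label across annotators.

    Unlabeled (0) votes are ignored unless every vote is 0; ties are broken
    toward the smallest class index so the result is deterministic and
    independent of annotator order.
    """
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise ValueError(
                f"shape mismatch between masks: {shape} vs {m.shape}"
            )
    K = max(int(m.grid.max()) for m in masks)
    if K == 0:
        return LabelMask(np.zeros(shape, dtype=int))
    counts = np.zeros((K, *shape), dtype=int)
    for m in masks:
        for k in range(1, K + 1):
            counts[k - 1] += m.grid == k
    winner = np.argmax(counts, axis=0) + 1  # argmax tie -> smallest class
    any_vote = counts.sum(axis=0) > 0
    return LabelMask(np.where(any_vote, winner, 0))


def dense_prediction(
    model,
    feature_provider: Callable[[int, int, int], np.ndarray],
    mask_shape: tuple[int, int],
    patch_size: int,
    overlap: float,
    mc_samples: int = 100,
    seed: int = 0,
    annotator: int | None = None,
) -> LabelMask:
    """Sliding-window dense class map.

    The stride is ``max(1, round(patch_size * (1 - overlap)))``; each pixel's
    class distribution is the arithmetic mean of the predicted distributions
    of all windows covering it, and the pixel label is the argmax.
    ``feature_provider(row0, col0, size)`` returns the feature vector of one
    window.  When ``annotator`` is given, the map shows how that annotator
    would label the image (true-class prediction pushed through their
    posterior-mean confusion matrix) instead of the inferred true labels.
    """
    from .model import predict, predict_annotator

    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    H, W = mask_shape
    stride = max(1, int(round(patch_size * (1.0 - overlap))))
    positions = [
        (r, c)
        for r in _window_starts(H, patch_size, stride)
        for c in _window_starts(W, patch_size, stride)
    ]
    feats = np.asarray(
        [feature_provider(r, c, patch_size) for r, c in positions], dtype=float
    )
    if annotator is None:
        probs = predict(model, feats, mc_samples=mc_samples, seed=seed)
    else:
        probs = predict_annotator(
            model, feats, annotator, mc_samples=mc_samples, seed=seed
        )
    K = probs.shape[1]
    acc = np.zeros((H, W, K))
    cover = np.zeros((H, W))
    for (r, c), p in zip(positions, probs):
        acc[r : r + patch_size, c : c + patch_size] += p
        cover[r : r + patch_size, c : c + patch_size] += 1.0
    mean = acc / cover[:, :, None]
    return LabelMask(np.argmax(mean, axis=2).astype(int) + 1)


def dice(pred: LabelMask, ref: LabelMask, class_k: int) -> float:
    """DICE overlap 2|P∩R| / (|P|+|R|) for one class.

    Returns 1.0 (logged) when the class is absent from both masks.
    """
    if pred.shape != ref.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape} vs ref {ref.shape}"
        )
    p = pred.grid == class_k
    r = ref.grid == class_k
    denom = int(p.sum()) + int(r.sum())
    if denom == 0:
        log.info("class %d absent from both masks; DICE defined as 1.0", class_k)
        return 1.0
    return 2.0 * float(np.logical_and(p, r).sum()) / denom
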