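"""Overlapping sliding-window tiling and whole-image map reconstruction.

Fundus images are far larger than what an encoder-decoder network can take
in one pass, so the image is cut into fixed-size square regions of interest
(RoIs) laid on a regular grid with a configurable overlap fraction, and the
per-patch probability predictions are later averaged back onto a full-image
canvas: overlapping contributions are summed and divided by the per-pixel
overlap count, then thresholded into a binary segmentation mask.

Coordinates are 0-based and row-major; windows are half-open
``[r, r + w) x [c, c + w)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Patch side length used by the reference pipeline, in pixels.
DEFAULT_WINDOW = 576
#: Fraction of each window shared with its neighbour along each axis.
DEFAULT_OVERLAP = 0.30


@dataclass(frozen=True)
class TilingConfig:
    """Sliding-window geometry and the black-patch discard rule."""

    window: int = DEFAULT_WINDOW
    overlap: float = DEFAULT_OVERLAP
    black_tol: int = 0

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError(f"window must be positive, got {self.window}")
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError(f"overlap must be in [0, 1), got {self.overlap}")
        if self.stride < 1:
            raise ValueError("stride floor(window*(1-overlap)) must be >= 1")

    @property
    def stride(self) -> int:
        return int(np.floor(self.window * (1.0 - self.overlap)))


@dataclass(frozen=True)
class TilingPlan:
    """The list of window origins covering an image."""

    image_size: tuple[int, int]
    origins: tuple[tuple[int, int], ...]
    window: int

    def __len__(self) -> int:
        return len(self.origins)


def _axis_origins(size: int, window: int, stride: int) -> list[int]:
    """Regular origins 0, s, 2s, ... plus an edge-anchored final origin."""
    last = size - window
    origins = list(range(0, last + 1, stride))
    if origins[-1] != last:
        origins.append(last)
    return origins


def compute_grid(image_size: tuple[int, int], config: TilingConfig) -> TilingPlan:
    """Lay out the overlapping sliding-window grid for an image.

    Along each axis the origins advance by ``stride = floor(window *
    (1 - overlap))``; if the last regular window does not reach the image
    edge, one extra window anchored flush to the edge is appended, so the
    plan always covers every pixel.

    Raises
    ------
    ValueError
        If the image is smaller than the window on either axis.
    """
    h, w = image_size
    win = config.window
    if h < win or w < win:
        raise ValueError(
            f"image size {image_size} is smaller than the {win}px window; "
            f"pad the image or choose a smaller window")
    rows = _axis_origins(h, win, config.stride)
    cols = _axis_origins(w, win, config.stride)
    origins = tuple((r, c) for r in rows for c in cols)
    return TilingPlan(image_size=(h, w), origins=origins, window=win)


def extract_rois(image: np.ndarray, plan: TilingPlan,
                 config: TilingConfig) -> list[tuple[tuple[int, int], np.ndarray]]:
    """Crop every window of the plan, discarding all-black patches.

    A patch is discarded when *every* pixel in *every* channel is at or
    below ``config.black_tol`` (a single brighter pixel keeps the patch).
    The number of discarded windows is logged.  Intended for training-time
    patch harvesting; inference must predict every window so the
    reconstruction canvas has full coverage.
    """
    if image.shape[:2] != plan.image_size:
        raise ValueError(
            f"plan built for {plan.image_size} but image is {image.shape[:2]}")
    w = plan.window
    kept: list[tuple[tuple[int, int], np.ndarray]] = []
    discarded = 0
    for (r, c) in plan.origins:
        patch = image[r:r + w, c:c + w]
        if np.all(patch <= config.black_tol):
            discarded += 1
            continue
        kept.append(((r, c), patch))
    logger.info("extract_rois: kept %d, discarded %d all-black of %d windows",
                len(kept), discarded, len(plan.origins))
    return kept


@dataclass
class ProbabilityCanvas:
    """Full-image accumulator of predicted probabilities and overlap counts."""

    prob_sum: np.ndarray
    count: np.ndarray

    @classmethod
    def empty(cls, image_size: tuple[int, int]) -> "ProbabilityCanvas":
        return cls(prob_sum=np.zeros(image_size, dtype=np.float64),
                   count=np.zeros(image_size, dtype=np.int64))


def accumulate(canvas: ProbabilityCanvas, origin: tuple[int, int],
               patch_probs: np.ndarray) -> ProbabilityCanvas:
    """Place one predicted patch on the canvas at its crop origin.

    Adds the probabilities into ``prob_sum`` and increments ``count`` on the
    window; accumulation order never affects the final state.
    """
    r, c = origin
    h, w = patch_probs.shape
    H, W = canvas.prob_sum.shape
    if r < 0 or c < 0 or r + h > H or c + w > W:
        raise ValueError(f"window {h}x{w} at origin {origin} exceeds "
                         f"canvas {canvas.prob_sum.shape}")
    if patch_probs.min() < 0.0 or patch_probs.max() > 1.0:
        raise ValueError("patch probabilities must lie in [0, 1]")
    canvas.prob_sum[r:r + h, c:c + w] += patch_probs
    canvas.count[r:r + h, c:c + w] += 1
    return canvas


def finalize_map(canvas: ProbabilityCanvas) -> np.ndarray:
    """Average overlapping predictions: prob_sum / count, per pixel."""
    if (canvas.count == 0).any():
        n_uncovered = int((canvas.count == 0).sum())
        rr, cc = np.nonzero(canvas.count == 0)
        raise ValueError(
            f"{n_uncovered} pixels have no covering window "
            f"(first at ({rr[0]}, {cc[0]})); the plan must cover the image")
    return canvas.prob_sum / canvas.count


def threshold_map(prob_map: np.ndarray, tau: float = 0.5) -> np.ndarray:
    """Binarize a probability map: microaneurysm where prob > tau, strictly.

    Pixels at exactly ``tau`` are background, matching the reconstruction
    rule that only predictions *higher than* 0.5 are marked as lesion.
    """
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"threshold tau must be in [0, 1], got {tau}")
    prob_map = np.asarray(prob_map)
    if prob_map.min() < 0.0 or prob_map.max() > 1.0:
        raise ValueError("probability map values must lie in [0, 1]")
    return prob_map > tau
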