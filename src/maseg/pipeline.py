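"""Training protocol, the three-model ensemble, and whole-image prediction.

The workflow mirrors the three-step method: (1) break the image into
overlapping patches, (2) run each patch through the segmentation model(s),
(3) reconstruct the whole-image probability map by averaging overlapping
predictions and threshold it at 0.5 (strict).  The ensemble combines the
U-Net, ResNet34-UNet and U-Net++ members by a pixelwise arithmetic mean of
their probability maps before thresholding; majority voting is available
behind a flag for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from . import metrics, tiling
from .metrics import MetricCounts, MetricReport
from .models import SegModel, as_input_batch
from .nn import Adam, Tensor, softmax_channel, softmax_cross_entropy
from .synthetic import SynthSample
from .tiling import ProbabilityCanvas, TilingConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabeledPatch:
    """An RGB patch with its pixel-aligned ground-truth mask."""

    image: np.ndarray          # (w, w, 3) uint8
    mask: np.ndarray           # (w, w) bool
    source: int = -1           # index of the source image, if any
    origin: tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class SplitSpec:
    """Random 70/10/20 train/validation/test partition of the patch set."""

    train_frac: float = 0.70
    val_frac: float = 0.10
    test_frac: float = 0.20
    seed: int = 0

    def __post_init__(self):
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")


@dataclass(frozen=True)
class TrainConfig:
    """Adam + binary cross-entropy training hyper-parameters.

    The loss is a softmax over the two output channels trained with
    cross-entropy, equivalent to binary cross-entropy on the foreground
    probability.  ``balance_positives`` draws each epoch's patch sample so
    lesion-bearing and lesion-free patches appear in comparable numbers — a
    standard remedy for the extreme pixel imbalance of tiny lesions.
    """

    lr: float = 1e-3
    epochs: int = 10
    batch_size: int = 8
    seed: int = 0
    balance_positives: bool = True

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    mean_foreground_prob: list[float] = field(default_factory=list)
    best_epoch: int = -1


def harvest_patches(samples: Sequence[SynthSample], config: TilingConfig
                    ) -> list[LabeledPatch]:
    """Cut labeled patches from full images with the overlapping grid.

    All-black windows are discarded, as at training time; ground-truth
    patches are cut from the full-image mask at the same origins, so image
    and mask are always aligned.
    """
    patches: list[LabeledPatch] = []
    for i, sample in enumerate(samples):
        plan = tiling.compute_grid(sample.image.shape[:2], config)
        for origin, crop in tiling.extract_rois(sample.image, plan, config):
            r, c = origin
            w = plan.window
            patches.append(LabeledPatch(image=crop,
                                        mask=sample.mask[r:r + w, c:c + w],
                                        source=i, origin=origin))
    return patches


def split_patches(patches: Sequence, spec: SplitSpec):
    """Seeded uniform shuffle then contiguous 70/10/20 cut.

    Sizes are floor(n * frac) for train and validation with the remainder
    going to test; the three parts are disjoint and exhaustive.
    """
    n = len(patches)
    if n < 10:
        raise ValueError(f"need at least 10 patches to split, got {n}")
    order = np.random.default_rng(spec.seed).permutation(n)
    n_train = int(np.floor(n * spec.train_frac))
    n_val = int(np.floor(n * spec.val_frac))
    train = [patches[i] for i in order[:n_train]]
    val = [patches[i] for i in order[n_train:n_train + n_val]]
    test = [patches[i] for i in order[n_train + n_val:]]
    return train, val, test


def pooled_counts(gt_masks: Sequence[np.ndarray],
                  pred_masks: Sequence[np.ndarray]) -> MetricCounts:
    """Sum TP/FP/FN over a set of mask pairs (micro-averaged counts)."""
    tp = fp = fn = 0
    for gt, pred in zip(gt_masks, pred_masks):
        c = metrics.confusion_counts(gt, pred)
        tp += c.tp
        fp += c.fp
        fn += c.fn
    return MetricCounts(tp=tp, fp=fp, fn=fn)


def _patch_arrays(patches: Sequence[LabeledPatch]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.image for p in patches])
    y = np.stack([p.mask for p in patches]).astype(np.int64)
    return x, y


def heldout_dice(model_or_ensemble, patches: Sequence[LabeledPatch],
                 batch_size: int = 16, tau: float = 0.5) -> float:
    """Micro-averaged Dice of thresholded predictions over a patch set."""
    gts, preds = [], []
    for lo in range(0, len(patches), batch_size):
        chunk = patches[lo:lo + batch_size]
        probs = model_or_ensemble.predict_batch(np.stack([p.image for p in chunk]))
        for p, pr in zip(chunk, probs):
            gts.append(p.mask)
            preds.append(tiling.threshold_map(pr, tau))
    return metrics.dice(pooled_counts(gts, preds))


def train_model(model: SegModel, train: Sequence[LabeledPatch],
                val: Sequence[LabeledPatch], config: TrainConfig) -> SegModel:
    """Train one member with Adam + binary cross-entropy, fully seeded.

    After every epoch the validation Dice (micro-averaged at threshold 0.5)
    is measured and the weights of the best epoch are restored at the end.
    The training history is attached to ``model.training_history``.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.net.parameters(), lr=config.lr)
    x_all, y_all = _patch_arrays(train)
    pos_idx = np.array([i for i, p in enumerate(train) if p.mask.any()])
    neg_idx = np.array([i for i in range(len(train)) if i not in set(pos_idx)])
    history = TrainingHistory()
    best_state: Optional[dict] = None
    best_dice = -1.0
    for epoch in range(config.epochs):
        if config.balance_positives and len(pos_idx) and len(neg_idx):
            k = min(len(neg_idx), max(len(pos_idx), 1))
            chosen_neg = rng.choice(neg_idx, size=k, replace=False)
            order = np.concatenate([pos_idx, chosen_neg])
        else:
            order = np.arange(len(train))
        rng.shuffle(order)
        model.net.train()
        losses, fg_probs = [], []
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            xb = as_input_batch(x_all[idx])
            logits = model.logits(Tensor(xb))
            loss = softmax_cross_entropy(logits, y_all[idx])
            model.net.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            fg_probs.append(float(softmax_channel(logits.data)[:, 1].mean()))
        history.train_loss.append(float(np.mean(losses)))
        history.mean_foreground_prob.append(float(np.mean(fg_probs)))
        vd = heldout_dice(model, val) if len(val) else -history.train_loss[-1]
        history.val_dice.append(vd if len(val) else float("nan"))
        if vd > best_dice:
            best_dice = vd
            best_state = model.net.state_dict()
            history.best_epoch = epoch
        logger.info("epoch %d: loss %.4f val_dice %s", epoch,
                    history.train_loss[-1],
                    f"{vd:.4f}" if len(val) else "n/a")
    if best_state is not None:
        model.net.load_state_dict(best_state)
    model.training_history = history
    return model


@dataclass
class Ensemble:
    """The three-member ensemble with a pixelwise probability combiner.

    ``combine`` is "mean" (arithmetic mean of member probability maps,
    before thresholding) or "vote" (fraction of members voting lesion at
    0.5, so downstream thresholding at 0.5 yields the majority)."""

    members: Sequence[SegModel]
    combine: str = "mean"

    def __post_init__(self):
        if self.combine not in ("mean", "vote"):
            raise ValueError(f"unknown combiner {self.combine!r}")
        if len(self.members) == 0:
            raise ValueError("ensemble needs at least one member")

    def predict_batch(self, patches: np.ndarray) -> np.ndarray:
        outs = []
        for m in self.members:
            p = m.predict_batch(patches)
            if outs and p.shape != outs[0].shape:
                raise ValueError(
                    f"member output shape mismatch: {p.shape} vs {outs[0].shape}")
            outs.append(p)
        stack = np.stack(outs)
        if self.combine == "vote":
            return (stack > 0.5).mean(axis=0)
        return stack.mean(axis=0)

    def predict(self, patch: np.ndarray) -> np.ndarray:
        return self.predict_batch(patch[None])[0]


def ensemble_predict_patch(ensemble: Ensemble, patch: np.ndarray) -> np.ndarray:
    """Pixelwise combination of the member probability maps for one patch."""
    return ensemble.predict(patch)


def predict_image(image: np.ndarray,
                  predictor: Union[SegModel, Ensemble],
                  config: TilingConfig,
                  tau: float = 0.5,
                  batch_size: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Whole-image prediction: tile, predict every window, reconstruct.

    Every window of the covering grid is predicted (no black-patch discard
    at inference, so the canvas has full coverage), overlapping predictions
    are averaged, and the map is thresholded strictly above ``tau``.

    Returns the continuous probability map and the binary mask.
    """
    plan = tiling.compute_grid(image.shape[:2], config)
    canvas = ProbabilityCanvas.empty(plan.image_size)
    w = plan.window
    origins = list(plan.origins)
    for lo in range(0, len(origins), batch_size):
        chunk = origins[lo:lo + batch_size]
        batch = np.stack([image[r:r + w, c:c + w] for r, c in chunk])
        probs = predictor.predict_batch(batch)
        for origin, pr in zip(chunk, probs):
            tiling.accumulate(canvas, origin, np.clip(pr, 0.0, 1.0))
    prob_map = tiling.finalize_map(canvas)
    return prob_map, tiling.threshold_map(prob_map, tau)


@dataclass
class EvaluationSummary:
    reports: list[MetricReport]
    mean_iou: float
    mean_dice: float


def evaluate(pred_masks: Sequence[np.ndarray],
             gt_masks: Sequence[np.ndarray]) -> EvaluationSummary:
    """Per-image IoU/Dice reports with unweighted means across images."""
    if len(pred_masks) != len(gt_masks):
        raise ValueError(f"got {len(pred_masks)} predictions for "
                         f"{len(gt_masks)} ground truths")
    reports = [metrics.report(gt, pred)
               for gt, pred in zip(gt_masks, pred_masks)]
    return EvaluationSummary(
        reports=reports,
        mean_iou=float(np.mean([r.iou for r in reports])),
        mean_dice=float(np.mean([r.dice for r in reports])),
    )
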