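"""Desk-scale synthetic benchmark of the full pipeline.

Trains all three ensemble members on a seeded synthetic dataset small
enough for a single CPU — 30 fundus-like images of 320 x 320 px tiled with
a 64 px window at 30% overlap, scaled-down architectures (base width 8) —
and reports each member's micro-averaged Dice on held-out patches plus the
ensemble's.  This validates the pipeline mechanics (patching, training,
ensembling, thresholded evaluation); it is far below clinical scale, and
scores here say nothing about performance on real fundus photographs.

Blob diameters are drawn from 5-20 px so the lesions stay proportionate to
the smaller canvas while remaining within the 50 px clinical bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import ModelConfig, build_model
from .pipeline import (Ensemble, SplitSpec, TrainConfig, harvest_patches,
                       heldout_dice, split_patches, train_model)
from .synthetic import generate_dataset
from .tiling import TilingConfig

#: Number of synthetic images in the benchmark dataset.
N_IMAGES = 30
#: Height and width of each synthetic image, px.
IMAGE_SIZE = (320, 320)
#: Patch window, px (the full-scale pipeline uses 576).
WINDOW = 64

DATASET_KWARGS = dict(image_size=IMAGE_SIZE, n_mas=10,
                      ma_diameter_range=(5, 20), vessel_count=5)

MEMBER_CONFIGS = {
    "unet": ModelConfig("unet", input_size=WINDOW, depth=3, base_width=8),
    "resnet34_unet": ModelConfig("resnet34_unet", input_size=WINDOW,
                                 base_width=8),
    "unetpp": ModelConfig("unetpp", input_size=WINDOW, depth=3, base_width=8),
}

#: One shared hyper-parameter set for all three members.
TRAIN_KWARGS = dict(lr=5e-3, epochs=6, batch_size=16)


@dataclass
class BenchmarkResult:
    member_dice: dict[str, float]
    ensemble_dice: float
    n_patches: int = 0
    split_sizes: tuple[int, int, int] = (0, 0, 0)
    histories: dict = field(default_factory=dict)


def run_desk_benchmark(seed: int = 11, epochs: int | None = None) -> BenchmarkResult:
    """Generate the dataset, train the three members, evaluate held-out Dice.

    Fully seeded: dataset generation, the patch split, weight
    initialization and batch sampling all derive from ``seed``.
    """
    samples = generate_dataset(N_IMAGES, seed=seed, **DATASET_KWARGS)
    patches = harvest_patches(samples, TilingConfig(window=WINDOW, overlap=0.30))
    train, val, test = split_patches(patches, SplitSpec(seed=seed))
    train_kwargs = dict(TRAIN_KWARGS)
    if epochs is not None:
        train_kwargs["epochs"] = epochs
    tc = TrainConfig(seed=seed, **train_kwargs)
    members, member_dice, histories = [], {}, {}
    for name, cfg in MEMBER_CONFIGS.items():
        model = build_model(cfg, seed=seed)
        train_model(model, train, val, tc)
        members.append(model)
        member_dice[name] = heldout_dice(model, test)
        histories[name] = model.training_history
    ensemble = Ensemble(members=members)
    return BenchmarkResult(member_dice=member_dice,
                           ensemble_dice=heldout_dice(ensemble, test),
                           n_patches=len(patches),
                           split_sizes=(len(train), len(val), len(test)),
                           histories=histories)
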