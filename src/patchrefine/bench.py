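"""Desk-scale synthetic benchmark shared by the acceptance tests.

One benchmark run: generate a heterogeneous synthetic dataset, train the
coarse model, train refinement-model variants (full-featured, fine-tune
disabled, context disabled), and evaluate two-stage Dice at refinement
thresholds 0 and 1.  Threshold 1 refines nothing, so it measures the
coarse stage alone; threshold 0 refines every patch.

The learning rate here is raised above the full-scale default (1e-4) so the
tiny randomly initialized backbone converges within the standard 20 epochs
at this small data scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import make_grid
from .models.tiny import TinySegModel
from .pipeline import evaluate
from .synthetic import SyntheticConfig, generate_dataset
from .training import TrainConfig, init_stage2_from_stage1, train_stage1, train_stage2
from .uncertainty import SelectionConfig, patch_scores

__all__ = ["BenchResult", "run_benchmark_seed", "uncertainty_locates_hard_cells"]

IMAGE_SIZE = (96, 96)
NUM_PATCHES = 16
DESK_LR = 2e-3


@dataclass
class BenchResult:
    seed: int
    dice_tau0: float  # full-featured two-stage, every patch refined
    dice_tau1: float  # threshold 1: coarse stage only
    dice_no_finetune: float  # stage 2 from scratch, tau 0
    dice_no_context: float  # context fusion disabled, tau 0


def _train_config(seed: int, epochs: int) -> TrainConfig:
    return TrainConfig(
        learning_rate=DESK_LR, epochs=epochs, batch_size=4, image_size=IMAGE_SIZE, seed=seed
    )


def run_benchmark_seed(
    seed: int,
    n_train: int = 24,
    n_test: int = 10,
    epochs: int = 20,
    strategy: str = "weighted",
) -> BenchResult:
    """Train and evaluate all pipeline variants for one seed."""
    synth = SyntheticConfig(image_size=IMAGE_SIZE, seed=seed)
    train_pairs = [(x, y) for x, y, _ in generate_dataset(synth, n_train)]
    test_pairs = [(x, y) for x, y, _ in generate_dataset(synth, n_test, start_index=n_train)]
    grid = make_grid(IMAGE_SIZE[0], IMAGE_SIZE[1], NUM_PATCHES)
    patch_size = (grid.patch_h, grid.patch_w)
    cfg = _train_config(seed, epochs)

    m1 = TinySegModel(patch_size, seed=seed)
    train_stage1(m1, train_pairs, cfg)

    m2_full = init_stage2_from_stage1(m1)
    train_stage2(m1, m2_full, train_pairs, grid, strategy, cfg, context=True)
    m2_scratch = TinySegModel(patch_size, seed=seed + 10_000)
    train_stage2(m1, m2_scratch, train_pairs, grid, strategy, cfg, context=True)
    m2_noctx = init_stage2_from_stage1(m1)
    train_stage2(m1, m2_noctx, train_pairs, grid, strategy, cfg, context=False)

    def mean_dice(m2, threshold: float, context: bool) -> float:
        sel = SelectionConfig(strategy=strategy, threshold=threshold, seed=seed)
        return evaluate(m1, m2, test_pairs, grid, sel, context=context)["mean_dice"]

    return BenchResult(
        seed=seed,
        dice_tau0=mean_dice(m2_full, 0.0, True),
        dice_tau1=mean_dice(m2_full, 1.0, True),
        dice_no_finetune=mean_dice(m2_scratch, 0.0, True),
        dice_no_context=mean_dice(m2_noctx, 0.0, False),
    )


def uncertainty_locates_hard_cells(
    seed: int = 0, n_train: int = 24, n_images: int = 50, epochs: int = 20
):
    """Train the coarse model, then return paired (hard-cell, easy-cell) mean
    patch-uncertainty samples over fresh images — the premise that coarse
    uncertainty marks the regions worth refining."""
    from .grid import downscale, upscale
    from .models.base import predict_probs

    synth = SyntheticConfig(image_size=IMAGE_SIZE, seed=seed)
    train_pairs = [(x, y) for x, y, _ in generate_dataset(synth, n_train)]
    grid = make_grid(IMAGE_SIZE[0], IMAGE_SIZE[1], NUM_PATCHES)
    m1 = TinySegModel((grid.patch_h, grid.patch_w), seed=seed)
    train_stage1(m1, train_pairs, _train_config(seed, epochs))

    hard_scores, easy_scores = [], []
    for k in range(n_images):
        x, _, hard_cells = generate_dataset(synth, 1, start_index=n_train + k)[0]
        small = downscale(x, grid.patch_h, grid.patch_w)
        probs, _ = predict_probs(m1, small)
        coarse = upscale(probs, grid.image_h, grid.image_w)
        scores = patch_scores(coarse, grid).scores
        hard_scores.extend(scores[hard_cells].tolist())
        easy_scores.extend(scores[~hard_cells].tolist())
    return np.array(hard_scores), np.array(easy_scores)
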