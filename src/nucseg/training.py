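"""Training of region, boundary, fusion, and multitask models.

Optimization follows the published recipe: Adam, learning rate 5e-4,
L2 weight decay 2e-4, batch size 4, dropout; the loss is per-pixel
cross entropy with optional class weights.  Region and boundary models
are trained independently; the fusion model is then trained on their
frozen outputs, stacked as a 2-channel probability input, against the
region target.  Epochs are internally reseeded so that training is
reproducible and a zero learning rate yields a flat loss history.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import maximum_filter, minimum_filter

from .networks import (NetworkSpec, SegmentationModel, build_enet,
                       build_multitask, build_symmetric)
from .nn.core import F32, cross_entropy_with_logits_grad
from .nn.optim import Adam


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 5e-4
    weight_decay_l2: float = 2e-4
    batch_size: int = 4
    max_epochs: int = 100
    dropout_rate: float = 0.1
    seed: int = 0
    loss: str = "cross_entropy"
    class_weights: tuple | None = None
    boundary_thickness: int = 2

    def __post_init__(self):
        if self.loss != "cross_entropy":
            raise ValueError("only cross_entropy loss is implemented")
        if self.batch_size < 1 or self.max_epochs < 0:
            raise ValueError("invalid batch size or epoch count")


@dataclass
class FusionModel:
    region: SegmentationModel
    boundary: SegmentationModel
    fusion: SegmentationModel

    def __post_init__(self):
        if self.fusion.spec.family != self.region.spec.family:
            raise ValueError("fusion net family must match the region net")
        if self.fusion.spec.in_channels != 2:
            raise ValueError("fusion net must take 2 input channels")

    def predict(self, batch: np.ndarray) -> np.ndarray:
        """Fused foreground/background probability maps for a batch."""
        stacked = self.stack_probabilities(batch)
        return self.fusion.forward(stacked, train=False)

    def stack_probabilities(self, batch: np.ndarray) -> np.ndarray:
        pr = self.region.forward(batch, train=False)
        pb = self.boundary.forward(batch, train=False)
        return np.concatenate([pr[:, 1:2], pb[:, 1:2]], axis=1)


def boundary_from_mask(mask: np.ndarray, thickness: int = 2) -> np.ndarray:
    """Instance-interior pixels within Chebyshev ``thickness`` of a pixel
    with a different label (background included), so contact lines between
    touching instances are always marked."""
    if thickness < 1:
        raise ValueError("thickness must be >= 1")
    mask = np.asarray(mask)
    size = 2 * thickness + 1
    hi = maximum_filter(mask, size=size, mode="nearest")
    lo = minimum_filter(mask, size=size, mode="nearest")
    return (mask > 0) & ((hi != mask) | (lo != mask))


def _iter_batches(n: int, batch_size: int, rng) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i:i + batch_size] for i in range(0, n, batch_size)]


def train_model(model: SegmentationModel, inputs: np.ndarray,
                targets: np.ndarray, config: TrainConfig
                ) -> tuple[SegmentationModel, list[float]]:
    """Adam training loop; returns the model and per-epoch mean loss.

    ``inputs`` is (N, C, H, W) float, ``targets`` (N, H, W) integer class
    maps.  Both the shuffle and the dropout stream are reseeded from
    ``config.seed`` at the top of every epoch, which makes runs
    reproducible and learning-rate-0 runs exactly flat.
    """
    inputs = np.asarray(inputs, dtype=F32)
    targets = np.asarray(targets)
    n = inputs.shape[0]
    if targets.shape[0] != n:
        raise ValueError("inputs and targets must be aligned")
    if config.batch_size > n:
        raise ValueError("batch_size exceeds dataset size")
    opt = Adam(model.params(), lr=config.learning_rate,
               weight_decay=config.weight_decay_l2)
    weights = None if config.class_weights is None \
        else np.asarray(config.class_weights, dtype=F32)
    history: list[float] = []
    for epoch in range(config.max_epochs):
        rng = np.random.default_rng(config.seed)
        model.net.reseed_dropout(config.seed + 7919)
        total, count = 0.0, 0
        for batch_idx in _iter_batches(n, config.batch_size, rng):
            x = inputs[batch_idx]
            t = targets[batch_idx]
            probs = model.forward(x, train=True)
            loss, dlogits = cross_entropy_with_logits_grad(probs, t, weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}; "
                    "lower the learning rate or check the targets")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            total += loss * len(batch_idx)
            count += len(batch_idx)
        history.append(total / count)
    return model, history


def region_targets(masks: np.ndarray) -> np.ndarray:
    return (np.asarray(masks) > 0).astype(np.int64)


def boundary_targets(masks: np.ndarray, thickness: int = 2) -> np.ndarray:
    return np.stack([boundary_from_mask(m, thickness).astype(np.int64)
                     for m in masks])


def train_fusion(inputs: np.ndarray, masks: np.ndarray,
                 region_spec: NetworkSpec, boundary_spec: NetworkSpec,
                 config: TrainConfig) -> tuple[FusionModel, dict]:
    """Two-stage fusion training.

    Stage 1 trains the region and boundary nets independently (seeds
    ``config.seed`` and ``config.seed + 1``).  Stage 2 freezes both, runs
    them over the training set, stacks the two foreground-probability
    maps as a 2-channel input, and trains a fusion net of the same family
    (seed ``config.seed + 2``) against the region target with the same
    optimization parameters.
    """
    region = _build(region_spec, config.seed)
    boundary = _build(boundary_spec, config.seed + 1)
    histories = {}
    try:
        region, histories["region"] = train_model(
            region, inputs, region_targets(masks), config)
    except RuntimeError as err:
        raise RuntimeError(f"[stage region] {err}") from err
    try:
        boundary, histories["boundary"] = train_model(
            boundary, inputs,
            boundary_targets(masks, config.boundary_thickness),
            replace(config, seed=config.seed + 1))
    except RuntimeError as err:
        raise RuntimeError(f"[stage boundary] {err}") from err

    fusion_spec = replace(region_spec, in_channels=2)
    fusion = _build(fusion_spec, config.seed + 2)
    model = FusionModel(region=region, boundary=boundary, fusion=fusion)
    stacked = model.stack_probabilities(np.asarray(inputs, dtype=F32))
    try:
        fusion, histories["fusion"] = train_model(
            fusion, stacked, region_targets(masks),
            replace(config, seed=config.seed + 2))
    except RuntimeError as err:
        raise RuntimeError(f"[stage fusion] {err}") from err
    return model, histories


def train_multitask(inputs: np.ndarray, masks: np.ndarray,
                    spec: NetworkSpec, config: TrainConfig
                    ) -> tuple[SegmentationModel, list[float]]:
    """One shared trunk, two heads (region, boundary), summed losses."""
    model = build_multitask(spec, seed=config.seed)
    inputs = np.asarray(inputs, dtype=F32)
    t_region = region_targets(masks)
    t_boundary = boundary_targets(masks, config.boundary_thickness)
    n = inputs.shape[0]
    if config.batch_size > n:
        raise ValueError("batch_size exceeds dataset size")
    opt = Adam(model.params(), lr=config.learning_rate,
               weight_decay=config.weight_decay_l2)
    weights = None if config.class_weights is None \
        else np.asarray(config.class_weights, dtype=F32)
    history: list[float] = []
    for epoch in range(config.max_epochs):
        rng = np.random.default_rng(config.seed)
        model.net.reseed_dropout(config.seed + 7919)
        total, count = 0.0, 0
        for batch_idx in _iter_batches(n, config.batch_size, rng):
            pr, pb = model.forward(inputs[batch_idx], train=True)
            loss_r, dr = cross_entropy_with_logits_grad(
                pr, t_region[batch_idx], weights)
            loss_b, db = cross_entropy_with_logits_grad(
                pb, t_boundary[batch_idx], weights)
            loss = loss_r + loss_b
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss {loss} at epoch {epoch}")
            opt.zero_grad()
            model.net.backward(dr, db)
            opt.step()
            total += loss * len(batch_idx)
            count += len(batch_idx)
        history.append(total / count)
    return model, history


def _build(spec: NetworkSpec, seed: int) -> SegmentationModel:
    if spec.family == "symmetric":
        return build_symmetric(spec=spec, seed=seed)
    return build_enet(spec=spec, seed=seed)
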