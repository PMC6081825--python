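"""Desk-scale benchmark: fused pipeline versus region-only pipeline.

Generates a seeded synthetic overlap benchmark, trains the three-network
fusion stack, and scores both pipelines with object-level F1 after
watershed post-processing.  Scaled far below the published experiments
(which used ~19k annotated nuclei and GPU-hours); only the *direction*
of the comparison is meaningful at this scale.
"""

from __future__ import annotations

import numpy as np

from .evaluation import MatchResult, compute_metrics, match_objects
from .networks import NetworkSpec
from .postprocess import PostprocessParams, segment
from .stains import nuclear_channel
from .synth import Scene, SceneSpec, generate_scene
from .training import FusionModel, TrainConfig, train_fusion

BENCH_SCENE = dict(height=64, width=64, n_nuclei=6, radius_range=(5.0, 9.0),
                   overlap_fraction=0.5, noise_sd=2.0)
BENCH_PLAN = (8, 16, 32)


def make_benchmark_scenes(seed: int, n_train: int, n_test: int,
                          scene_kw: dict | None = None
                          ) -> tuple[list[Scene], list[Scene]]:
    kw = dict(BENCH_SCENE)
    if scene_kw:
        kw.update(scene_kw)
    scenes = [generate_scene(SceneSpec(**kw, seed=seed * 10_000 + i))
              for i in range(n_train + n_test)]
    return scenes[:n_train], scenes[n_train:]


def scenes_to_arrays(scenes: list[Scene]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([nuclear_channel(s.image)[None] for s in scenes])
    M = np.stack([s.mask for s in scenes])
    return X.astype(np.float32), M


def pooled_f1(gt_masks, pred_masks) -> float:
    tp = fp = fn = 0
    for gt, pred in zip(gt_masks, pred_masks):
        m = match_objects(gt, pred)
        tp += m.true_positive
        fp += m.false_positive
        fn += m.false_negative
    return compute_metrics(MatchResult(tp, fp, fn, ()))[2]


def run_overlap_benchmark(seed: int, n_train: int = 32, n_test: int = 12,
                          epochs: int = 30,
                          params: PostprocessParams | None = None) -> dict:
    """Train fused + region pipelines for one seed; return pooled F1s."""
    params = params or PostprocessParams(min_object_area=10, marker_h=1.0)
    train_scenes, test_scenes = make_benchmark_scenes(seed, n_train, n_test)
    Xtr, Mtr = scenes_to_arrays(train_scenes)
    Xte, Mte = scenes_to_arrays(test_scenes)
    spec = NetworkSpec(n_modules=3, feature_plan=BENCH_PLAN)
    cfg = TrainConfig(max_epochs=epochs, seed=seed)
    model, _ = train_fusion(Xtr, Mtr, spec, spec, cfg)

    region_pred, fused_pred = [], []
    for i in range(Xte.shape[0]):
        x = Xte[i:i + 1]
        p_region = model.region.forward(x, train=False)[0, 1]
        p_fused = model.predict(x)[0, 1]
        region_pred.append(segment(p_region, params))
        fused_pred.append(segment(p_fused, params))
    return {
        "seed": seed,
        "region_f1": pooled_f1(Mte, region_pred),
        "fused_f1": pooled_f1(Mte, fused_pred),
        "model": model,
    }
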