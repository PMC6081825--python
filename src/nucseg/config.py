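"""Pipeline configuration: one YAML file validated into nested configs."""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .networks import NetworkSpec
from .postprocess import PostprocessParams
from .synth import SceneSpec
from .training import TrainConfig


@dataclass(frozen=True)
class PipelineConfig:
    scene: SceneSpec = field(default_factory=SceneSpec)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    postprocess: PostprocessParams = field(default_factory=PostprocessParams)
    stain_matrix_path: str | None = None
    output_dir: str = "out"
    input_mode: str = "cd-grayscale"  # or "rgb"
    train_mode: str = "fusion"        # or "multitask"

    def __post_init__(self):
        if self.input_mode not in ("cd-grayscale", "rgb"):
            raise ValueError("input_mode must be 'cd-grayscale' or 'rgb'")
        if self.train_mode not in ("fusion", "multitask"):
            raise ValueError("train_mode must be 'fusion' or 'multitask'")
        expected = 1 if self.input_mode == "cd-grayscale" else 3
        if self.network.in_channels != expected:
            raise ValueError(
                f"network.in_channels={self.network.in_channels} does not "
                f"match input_mode '{self.input_mode}' (expected {expected})")

    def to_dict(self) -> dict:
        from dataclasses import asdict
        d = {
            "scene": self.scene.to_dict(),
            "network": self.network.to_dict(),
            "train": asdict(self.train),
            "postprocess": asdict(self.postprocess),
            "stain_matrix_path": self.stain_matrix_path,
            "output_dir": self.output_dir,
            "input_mode": self.input_mode,
            "train_mode": self.train_mode,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kw = {}
        if "scene" in d:
            kw["scene"] = SceneSpec.from_dict(d["scene"])
        if "network" in d:
            kw["network"] = NetworkSpec.from_dict(d["network"])
        if "train" in d:
            tr = dict(d["train"])
            if tr.get("class_weights") is not None:
                tr["class_weights"] = tuple(tr["class_weights"])
            kw["train"] = TrainConfig(**tr)
        if "postprocess" in d:
            kw["postprocess"] = PostprocessParams(**d["postprocess"])
        for k in ("stain_matrix_path", "output_dir", "input_mode", "train_mode"):
            if k in d:
                kw[k] = d[k]
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
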