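"""YAML run configuration: one document describing a full analysis run.

The shipped defaults are the study parameters this pipeline was built
around (1.5 deg dispersion, 80/220 ms durations, 0.6 confidence floor,
70 px navigation / 30 px interaction thresholds); every value can be
overridden per run, since the thresholds are study choices rather than
constants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .camera import CameraModel
from .fixation import FixationParams
from .registration import RegistrationConfig

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to run one workflow end to end."""

    mode: str = "navigation"            # 'navigation' | 'interaction'
    gaze_path: str | None = None
    detections_dir: str | None = None
    output_dir: str = "droi_run"
    gaze_dialect: str = "topleft"
    camera: CameraModel = field(default_factory=CameraModel)
    fixation: FixationParams = field(default_factory=FixationParams)
    registration: RegistrationConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("navigation", "interaction"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.registration is None:
            reg = (RegistrationConfig.navigation() if self.mode == "navigation"
                   else RegistrationConfig.interaction())
            object.__setattr__(self, "registration", reg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        kwargs: dict = {k: doc[k] for k in
                        ("mode", "gaze_path", "detections_dir", "output_dir",
                         "gaze_dialect", "seed") if k in doc}
        if "camera" in doc:
            kwargs["camera"] = CameraModel(**doc["camera"])
        if "fixation" in doc:
            kwargs["fixation"] = FixationParams(**doc["fixation"])
        if "registration" in doc:
            reg = dict(doc["registration"])
            mode = kwargs.get("mode", "navigation")
            base = (RegistrationConfig.navigation if mode == "navigation"
                    else RegistrationConfig.interaction)
            kwargs["registration"] = base(**reg)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "mode": self.mode,
            "gaze_path": self.gaze_path,
            "detections_dir": self.detections_dir,
            "output_dir": self.output_dir,
            "gaze_dialect": self.gaze_dialect,
            "seed": self.seed,
            "camera": dataclasses.asdict(self.camera),
            "fixation": dataclasses.asdict(self.fixation),
            "registration": {
                "confidence_min": self.registration.confidence_min,
                "distance_threshold_px":
                    self.registration.distance_threshold_px,
            },
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
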