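"""Pipeline configuration: one object, YAML in and out.

Sections mirror the pipeline stages (cleaning / energy / features /
classifier / scanner / calibration). Defaults reproduce the documented
field setup: 0.5 s SPL frames over 1–40,000 Hz, 3 dB gating margin,
5.5 s x 800–10,000 Hz feature windows on a 32x32 grid, a [10, 8, 6]
hidden-layer network thresholded at 0.5, and snap cleaning on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .cleaning import CleaningParams
from .core_io import CalibrationSpec
from .energy import SplParams
from .features import FeatureParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    cleaning_enabled: bool = True
    cleaning: CleaningParams = field(default_factory=CleaningParams)
    spl: SplParams = field(default_factory=SplParams)
    gate_margin: float = 3.0
    gate_min_duration: float = 1.0
    gate_merge_gap: float = 1.0
    features: FeatureParams = field(default_factory=FeatureParams)
    score_threshold: float = 0.5
    calibration: CalibrationSpec = field(default_factory=CalibrationSpec)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "cleaning": {"enabled": self.cleaning_enabled, **asdict(self.cleaning)},
            "energy": {
                **asdict(self.spl),
                "margin": self.gate_margin,
                "min_duration": self.gate_min_duration,
                "merge_gap": self.gate_merge_gap,
            },
            "features": {**asdict(self.features),
                         "grid": list(self.features.grid)},
            "classifier": {"threshold": self.score_threshold},
            "calibration": asdict(self.calibration),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        cl = dict(doc.get("cleaning", {}))
        enabled = cl.pop("enabled", True)
        en = dict(doc.get("energy", {}))
        margin = en.pop("margin", cfg.gate_margin)
        min_dur = en.pop("min_duration", cfg.gate_min_duration)
        merge_gap = en.pop("merge_gap", cfg.gate_merge_gap)
        fe = dict(doc.get("features", {}))
        if "grid" in fe:
            fe["grid"] = tuple(fe["grid"])
        clf = doc.get("classifier", {})
        calib = doc.get("calibration", {})
        return cls(
            cleaning_enabled=bool(enabled),
            cleaning=CleaningParams(**cl) if cl else CleaningParams(),
            spl=SplParams(**en) if en else SplParams(),
            gate_margin=float(margin),
            gate_min_duration=float(min_dur),
            gate_merge_gap=float(merge_gap),
            features=FeatureParams(**fe) if fe else FeatureParams(),
            score_threshold=float(clf.get("threshold", cfg.score_threshold)),
            calibration=CalibrationSpec(**calib) if calib else CalibrationSpec(),
        )
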