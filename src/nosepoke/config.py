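"""Run configuration: phase, modality, stimulus specs, observer, seed.

Defaults reproduce the standard task parameterization bit-exactly (schedule
tables, stimulus specs, Detection constants). Configurations round-trip
through YAML so sessions are fully reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .observer import ObserverModel
from .scheduler import Phase
from .stimuli import Modality, PulseTrainSpec, ToneSpec

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to run (or re-run) one session.

    ``naive_intensity`` is the training anchor: the intensity known to evoke
    a percept (observed physical response shortly after implantation for
    ICMS, nominally 3-4 nC/ph; the 100%-amplitude training tone for
    auditory). ``jitter`` toggles the uniform step-size variation of the
    staircase; off gives deterministic central steps for testing.
    """

    phase: Phase = Phase.DETECTION
    modality: Modality = Modality.ICMS
    naive_intensity: float = 3.0
    seed: int = 0
    jitter: bool = True
    session_minutes: int = 60
    inter_trial_s: float = 3.0
    lockout_s: float = 0.150
    observer: ObserverModel = field(default_factory=ObserverModel)
    pulse_train: PulseTrainSpec = field(default_factory=PulseTrainSpec)
    tone: ToneSpec = field(default_factory=ToneSpec)

    def __post_init__(self) -> None:
        if self.naive_intensity <= 0:
            raise ValueError("naive_intensity must be > 0")
        if self.modality is Modality.AUDITORY and self.naive_intensity > 100:
            raise ValueError("auditory naive intensity may not exceed 100%")

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["phase"] = self.phase.value
        d["modality"] = self.modality.value
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "observer" in d and isinstance(d["observer"], dict):
            d["observer"] = ObserverModel(**d["observer"])
        if "pulse_train" in d and isinstance(d["pulse_train"], dict):
            d["pulse_train"] = PulseTrainSpec(**d["pulse_train"])
        if "tone" in d and isinstance(d["tone"], dict):
            d["tone"] = ToneSpec(**d["tone"])
        if "phase" in d:
            d["phase"] = Phase(d["phase"])
        if "modality" in d:
            d["modality"] = Modality(d["modality"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
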