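"""Run configuration: one serializable object drives the whole pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .beats import DetectionConfig
from .entropy import IeinConfig, OrdinalConfig
from .hrv import HrvBands
from .repol import StvConfig
from .riskstats import QuadrantThresholds
from .synth import GroupProfile, PhaseProtocol, default_profiles


@dataclass
class RunConfig:
    """Configuration of a simulate -> analyze -> stratify run.

    Defaults reproduce the study conditions: 12/11/14 animals across the
    YC/AC/CH profiles, the four-phase protocol, 1 kHz rendering of the
    first 60 s of baseline, and the published entropy quadrant thresholds.
    """

    seed: int = 1
    n_per_group: tuple[int, ...] = (12, 11, 14)
    profiles: tuple[GroupProfile, ...] = field(default_factory=default_profiles)
    protocol: PhaseProtocol = field(default_factory=PhaseProtocol)
    fs_hz: float = 1000.0
    waveform_seconds: float = 60.0
    noise_sd_mv: float = 0.01
    responder_amp_jitter: float = 0.1
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    stv: StvConfig = field(default_factory=StvConfig)
    bands: HrvBands = field(default_factory=HrvBands)
    hrv_minutes: float = 5.0
    freq_grid: tuple[float, float, float] = (0.02, 0.50, 0.005)
    ordinal: OrdinalConfig = field(default_factory=OrdinalConfig)
    iein: IeinConfig = field(default_factory=IeinConfig)
    entropy_decimate_hz: float = 250.0
    entropy_min_seconds: float = 20.0
    thresholds: QuadrantThresholds = field(default_factory=QuadrantThresholds)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["profiles"] = [asdict(p) for p in self.profiles]
        d["protocol"] = {"phases": [list(p) for p in self.protocol.phases]}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["n_per_group"] = tuple(d["n_per_group"])
        d["profiles"] = tuple(_profile_from_dict(p) for p in d["profiles"])
        d["protocol"] = PhaseProtocol(
            phases=tuple((str(a), float(b))
                         for a, b in d["protocol"]["phases"]))
        d["freq_grid"] = tuple(d["freq_grid"])
        d["detection"] = DetectionConfig(**d["detection"])
        d["stv"] = StvConfig(**d["stv"])
        d["bands"] = HrvBands(**d["bands"])
        d["ordinal"] = OrdinalConfig(**d["ordinal"])
        d["iein"] = IeinConfig(**d["iein"])
        d["thresholds"] = QuadrantThresholds(**d["thresholds"])
        return cls(**d)

    def to_json(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True)
                        + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    def config_hash(self) -> str:
        """Short content hash embedded in output file headers."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _profile_from_dict(d: dict) -> GroupProfile:
    d = dict(d)
    d["rr_mod"] = tuple((float(f), float(a)) for f, a in d.get("rr_mod", ()))
    return GroupProfile(**d)
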