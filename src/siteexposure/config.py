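"""Pipeline configuration: YAML-backed, lossless round trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ConstructConfig",
    "TitrationConfig",
    "PipelineConfig",
]


@dataclass
class ConstructConfig:
    """One single-molecule construct: either a simulation block or a path."""

    label: str
    # simulation block (used when traces_path is None)
    rates: dict | None = None  # {k12, k21, k23, k32}
    concentrations_nM: list = field(default_factory=list)
    n_traces: int = 400
    duration_s: float = 120.0
    # or pre-existing data
    traces_path: str | None = None


@dataclass
class TitrationConfig:
    """One ensemble titration: a generation block or a CSV path."""

    label: str
    generate: dict | None = None  # {s_values, amplitudes, e0, noise_sd, replicates}
    path: str | None = None
    inner_edge_bp: int | None = None


@dataclass
class PipelineConfig:
    """Every knob of the end-to-end analysis, with a single master seed."""

    seed: int = 0
    constructs: list = field(default_factory=list)  # list[ConstructConfig]
    titrations: list = field(default_factory=list)  # list[TitrationConfig]
    emission: dict = field(
        default_factory=lambda: {
            "e_high": 0.75, "e_low": 0.15, "noise_sd": 0.08, "frame_time": 0.1
        }
    )
    idealization: dict = field(
        default_factory=lambda: {"method": "hmm", "tol": 1e-6, "max_iter": 500}
    )
    dwell: dict = field(
        default_factory=lambda: {
            "alpha": 0.05, "bootstrap_reps": 200, "censoring": "survival"
        }
    )
    fitting: dict = field(
        default_factory=lambda: {"bootstrap_reps": 500, "weights": "inverse_variance"}
    )
    landscape: dict = field(
        default_factory=lambda: {
            "table_path": None,  # None -> synthetic stand-in landscape
            "calibration_bp": 29,
            "offset_bp": 3,
            "reference": "P26",
            "source": "ensemble",
        }
    )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["constructs"] = [asdict(c) if not isinstance(c, dict) else c
                           for c in self.constructs]
        d["titrations"] = [asdict(t) if not isinstance(t, dict) else t
                           for t in self.titrations]
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["constructs"] = [
            ConstructConfig(**c) if isinstance(c, dict) else c
            for c in d.get("constructs", [])
        ]
        d["titrations"] = [
            TitrationConfig(**t) if isinstance(t, dict) else t
            for t in d.get("titrations", [])
        ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
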