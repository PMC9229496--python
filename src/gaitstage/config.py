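"""Run configuration: one flat, serializable set of pipeline settings."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError
from .features import PeakConfig
from .synthesis import SignalConfig


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with its default.

    Serialized verbatim next to each command's outputs so a run can be
    reproduced from its artifacts alone.
    """

    fps: float = 30.0
    person_index: int = 0
    # signal conditioning
    fft_keep_fraction: float = 0.1
    resample_points: int = 1000
    t2_landmarks: tuple[str, str] = ("LHeel", "RHeel")
    # peak detection
    peak_min_prominence: float = 0.1
    peak_min_separation_s: float = 0.25
    # synthesis
    n_combinations: int = 80
    # modelling
    family: str = "KNN"
    cv_folds: int = 10
    gap_tol: float = 0.05
    plateau_tol: float = 0.01
    seed: int = 22

    def peak_cfg(self) -> PeakConfig:
        return PeakConfig(
            min_prominence=self.peak_min_prominence,
            min_separation_s=self.peak_min_separation_s,
        )

    def signal_cfg(self) -> SignalConfig:
        return SignalConfig(
            fft_keep_fraction=self.fft_keep_fraction,
            resample_points=self.resample_points,
            t2_landmarks=tuple(self.t2_landmarks),
        )

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["t2_landmarks"] = list(d["t2_landmarks"])
        return d

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2, sort_keys=True) + "\n")


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML/JSON file plus overrides.

    Unknown keys fail loudly, naming the key.
    """
    values: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(values) - _FIELDS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    if "t2_landmarks" in values:
        values["t2_landmarks"] = tuple(values["t2_landmarks"])
    return RunConfig(**values)
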