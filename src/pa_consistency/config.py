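"""Run configuration: a single YAML file driving the whole pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs.

    The effective config is echoed into the output directory so a run can
    be repeated exactly.
    """

    # inputs
    records_path: str | None = None
    epochs_path: str | None = None
    # epoch processing
    epoch_s: float = 1.0
    cutpoints: dict = field(
        default_factory=lambda: {"sedentary_max": 0.5, "light_max": 1.5, "moderate_max": 3.0}
    )
    bout_min: dict = field(
        default_factory=lambda: {"sedentary_s": 60, "mvpa_s": 3, "light_s": 3}
    )
    day_window: dict = field(default_factory=lambda: {"start": "08:00", "end": "20:00"})
    # tracker mapping
    calorie_bands: dict = field(default_factory=lambda: {"light_max": 2.0, "moderate_max": 3.5})
    step_goal: int = 11_000
    # clustering
    k: int | str = 3
    normalization: str = "zscore"
    order_key: str = "steps"
    seed: int = 0
    n_restarts: int = 10
    # consistency
    window_days: int = 7
    least_active_threshold: float = 0.5

    def validate(self, require_records: bool = False) -> None:
        if require_records:
            if self.records_path is None:
                raise ValueError("config field 'records_path' is required but missing")
            if not Path(self.records_path).exists():
                raise FileNotFoundError(f"records_path not found: {self.records_path}")

    def to_dict(self) -> dict:
        return asdict(self)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    return RunConfig(**raw)
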