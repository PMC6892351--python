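"""Run configuration: one serializable object covering every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


class ConfigFileError(ValueError):
    pass


@dataclass
class RunConfig:
    # geometry
    n_channels: int = 64
    scalp_radius_m: float = 0.09
    shell_radii_m: tuple[float, ...] = (0.08, 0.085, 0.09)
    shell_conductivities: tuple[float, ...] = (0.33, 0.0042, 0.33)
    n_sources_per_parcel: int = 1
    orientation_mode: str = "free"
    # simulation
    cohort_size: int = 20
    n_trials: int = 100
    iti_s: float = 7.0
    amplitude: float = 20.0
    effect_band: str = "gamma"
    reward_parcel: str = "AMYGDALA"
    punishment_parcel: str = "BA17"
    noise_sd_uv: float = 5.0
    blink_rate_per_min: float = 0.0
    blink_peak_uv: float = 200.0
    seed: int = 0
    # preprocessing (thresholds mirror PreprocessConfig defaults)
    bad_channel_maxmin_uv: float = 200.0
    ocular_maxmin_uv: float = 140.0
    max_bad_channels: int = 10
    # inverse / charge
    alpha_lambda: float = 1e-2
    calibration: float = 1.0
    bin_ms: float = 5.0
    aggregation: str = "max"
    # benchmark
    classifiers: tuple[str, ...] = ("logistic", "averaged_perceptron",
                                    "linear_svm", "neural_network")
    cv_k: int = 5
    # output
    out_dir: str = "eegcharge_out"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON run configuration; unknown keys are rejected."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigFileError(f"unknown config keys: {sorted(unknown)}")
    for key in ("shell_radii_m", "shell_conductivities", "classifiers"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)
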