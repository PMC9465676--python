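"""Pipeline configuration: every tunable constant, named and overridable.

The config file is flat YAML grouped in sections; unknown keys are
rejected so typos cannot silently fall back to defaults. Defaults are the
pipeline's standard operating values (ECG band 3–45 Hz, respiration band
0.1–0.35 Hz, acceleration cutoff 0.32 Hz, 4 s/1 s HR windowing, 31-point
smoothing, T = 1 s MADs blocks, the 8-cell hyperparameter grid).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .model import DEFAULT_GRID, FEATURE_SETS, HyperParams

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # filters
    ecg_band: tuple[float, float] = (3.0, 45.0)
    ecg_taps: int = 201
    resp_band: tuple[float, float] = (0.1, 0.35)
    resp_order: int = 4
    acc_cutoff: float = 0.32
    acc_order: int = 4
    acc_lowpass: str = "axes"  # "axes" (as specified) or "svm" (envelope)
    # features
    resp_source: str = "thoracic"  # thoracic | abdominal | sum
    hr_source: str = "ecg"  # ecg | hr_ref
    hr_window: float = 4.0
    hr_step: float = 1.0
    smooth_width: int = 31
    mads_T: float = 1.0
    # modelling
    feature_set: str = "HR%+RD+MADs+SDI"
    grid: tuple[HyperParams, ...] = DEFAULT_GRID
    cv_folds: int = 5
    # seeds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(
                f"unknown feature set {self.feature_set!r}; "
                f"valid: {', '.join(FEATURE_SETS)}"
            )
        if self.resp_source not in ("thoracic", "abdominal", "sum"):
            raise ValueError(f"unknown resp_source {self.resp_source!r}")
        if self.hr_source not in ("ecg", "hr_ref"):
            raise ValueError(f"unknown hr_source {self.hr_source!r}")
        if self.acc_lowpass not in ("axes", "svm"):
            raise ValueError(f"unknown acc_lowpass {self.acc_lowpass!r}")

    def resolved(self) -> dict:
        """Fully resolved key-value view (logged at the start of every run)."""
        d = dataclasses.asdict(self)
        d["grid"] = [dataclasses.asdict(h) for h in self.grid]
        return d


_VALID_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; unknown keys raise immediately."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    flat: dict = {}
    for key, value in raw.items():
        if isinstance(value, dict):  # section grouping is cosmetic
            flat.update(value)
        else:
            flat[key] = value
    unknown = set(flat) - _VALID_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if "grid" in flat:
        flat["grid"] = tuple(HyperParams(**cell) for cell in flat["grid"])
    for tup_key in ("ecg_band", "resp_band"):
        if tup_key in flat:
            flat[tup_key] = tuple(flat[tup_key])
    return PipelineConfig(**flat)
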