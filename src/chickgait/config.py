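"""Run-level configuration shared by every pipeline stage.

The defaults mirror the constants the analysis is defined around: the 85 %
knee-height collapse rule, the 0.07 µm³ synaptic-bouton volume floor, the
20–80 % density-range contour convention with six lines, 240 fps video and a
101-point percent-of-swing grid.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclasses.dataclass
class RunConfig:
    """Tunable constants for a full analysis run.

    Attributes
    ----------
    collapse_threshold_fraction
        A stride is a whole-body collapse when the minimum knee height falls
        strictly below this fraction of that step's stance-phase mean.
    overshoot_threshold_fraction
        A stride is an overshoot when its swing-peak knee height rises
        strictly above this fraction of the chick's mean swing peak.
    bouton_volume_threshold_um3
        Putative boutons below this volume are not counted as synapses
        (inclusive boundary: ``volume >= threshold`` is retained).
    contour_low, contour_high, n_contours
        Density-contour convention: levels equally spaced between these
        fractions of the density field's value range.
    swing_grid_points
        Number of points of the uniform 0–100 percent-of-swing grid.
    sd_convention
        ``"population"`` (divisor n) or ``"sample"`` (divisor n−1) for
        descriptive standard deviations.
    """

    collapse_threshold_fraction: float = 0.85
    overshoot_threshold_fraction: float = 1.15
    bouton_volume_threshold_um3: float = 0.07
    contour_low: float = 0.20
    contour_high: float = 0.80
    n_contours: int = 6
    swing_grid_points: int = 101
    sd_convention: str = "population"
    fps: float = 240.0
    collapse_window: str = "cycle"  # "cycle" or "swing"
    stance_baseline_scope: str = "step"  # "step" or "session"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.collapse_threshold_fraction < 1.0):
            raise ValueError("collapse_threshold_fraction must lie in (0, 1)")
        if self.overshoot_threshold_fraction <= 1.0:
            raise ValueError("overshoot_threshold_fraction must exceed 1")
        if not (0.0 <= self.contour_low < self.contour_high <= 1.0):
            raise ValueError("require 0 <= contour_low < contour_high <= 1")
        if self.bouton_volume_threshold_um3 < 0:
            raise ValueError("bouton_volume_threshold_um3 must be >= 0")
        if self.swing_grid_points < 2:
            raise ValueError("swing_grid_points must be >= 2")
        if self.sd_convention not in ("population", "sample"):
            raise ValueError("sd_convention must be 'population' or 'sample'")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML/JSON key-value file.

    ``None`` returns the defaults. Unknown keys raise, so typos in config
    files fail loudly rather than silently falling back to defaults.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
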