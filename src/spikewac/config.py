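"""Pipeline configuration and named decoder presets.

A :class:`PipelineConfig` binds a feature family (WAC or spike counts), a
decoder (Wiener or Kalman), the sliding-window geometry and the evaluation
settings.  The four shipped presets are the standard parameterizations of
the framework:

==================  =======  =======  ======  ====  ====  =====  ======
preset              feature  decoder  window  taps  lag   slide  levels
==================  =======  =======  ======  ====  ====  =====  ======
wavelet-wiener      wac      wiener   1000    4     50    5      5
wavelet-kalman      wac      kalman   1000    1     0     5      3
classical-wiener    counts   wiener   50      4     5     5      --
classical-kalman    counts   kalman   50      1     0     5      --
==================  =======  =======  ======  ====  ====  =====  ======

(all durations in ms, bin size 5 ms).  The wavelet-Wiener preset selects
``c5A, d5A, d4A, d3A`` -- the averaged scaling coefficient plus the three
coarsest averaged detail coefficients; the wavelet-Kalman preset uses a
3-level decomposition with ``c3A`` alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

from .wac import SlidingWindowSpec, default_selection, level_lengths


@dataclass
class PipelineConfig:
    feature: str = "wac"            # 'wac' | 'counts'
    decoder: str = "wiener"         # 'wiener' | 'kalman'
    bin_ms: float = 5.0
    window_ms: float = 1000.0
    taps: int = 4
    lag_ms: float = 50.0
    slide_ms: float = 5.0
    levels: int = 5
    selection: tuple | None = None  # None = c{J}A + 3 coarsest details
    ridge: float = 0.0
    folds: int = 5
    kalman_add_velocity: bool = True
    preset: str | None = None

    def __post_init__(self) -> None:
        if self.feature not in ("wac", "counts"):
            raise ValueError(f"feature must be 'wac' or 'counts', got {self.feature!r}")
        if self.decoder not in ("wiener", "kalman"):
            raise ValueError(f"decoder must be 'wiener' or 'kalman', got {self.decoder!r}")
        self.window_spec()  # validates the sliding-window invariants
        if self.feature == "wac":
            level_lengths(self.window_spec().window_bins, self.levels)
        if self.selection is not None:
            self.selection = tuple(self.selection)
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def window_spec(self) -> SlidingWindowSpec:
        return SlidingWindowSpec(self.bin_ms, self.window_ms, self.taps,
                                 self.lag_ms, self.slide_ms)

    def resolved_selection(self) -> list | None:
        if self.feature != "wac":
            return None
        if self.selection is not None:
            return list(self.selection)
        return default_selection(self.levels)

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["selection"] = self.resolved_selection()
        return d

    def fingerprint(self) -> str:
        """Stable short hash of the resolved configuration."""
        blob = json.dumps(self.as_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def max_levels(window_bins: int) -> int:
    """Deepest decomposition whose every level input has >= 2 samples."""
    j, n = 0, window_bins
    while n >= 2:
        n = -(-n // 2)
        j += 1
    return j


PRESETS: dict = {
    "wavelet-wiener": PipelineConfig(
        feature="wac", decoder="wiener", window_ms=1000.0, taps=4, lag_ms=50.0,
        levels=5, selection=("c5A", "d5A", "d4A", "d3A"), preset="wavelet-wiener"),
    "wavelet-kalman": PipelineConfig(
        feature="wac", decoder="kalman", window_ms=1000.0, taps=1, lag_ms=0.0,
        levels=3, selection=("c3A",), preset="wavelet-kalman"),
    "classical-wiener": PipelineConfig(
        feature="counts", decoder="wiener", window_ms=50.0, taps=4, lag_ms=5.0,
        preset="classical-wiener"),
    "classical-kalman": PipelineConfig(
        feature="counts", decoder="kalman", window_ms=50.0, taps=1, lag_ms=0.0,
        preset="classical-kalman"),
}


def from_preset(name: str, **overrides) -> PipelineConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    cfg = PRESETS[name].replace(**overrides)
    return cfg
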