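"""Wavelet average coefficients (WAC) and sliding-window feature matrices.

The trend features Q of a window are shrunk to one number per coefficient
vector by plain averaging: a J-level decomposition yields the averaged
scaling coefficient ``c{J}A`` and averaged detail coefficients
``d{1}A .. d{J}A``.  A *selection* (e.g. ``["c5A", "d5A", "d4A", "d3A"]``)
picks the subset used as decoder input; coarse levels carry the slow trend
of the waveform, fine levels its fast structure.

Sliding-window structure (all durations multiples of the bin width):

* **window** -- the span transformed into one WAC (or one spike count);
* **taps**   -- how many time-shifted windows feed one output step;
* **lag**    -- offset between consecutive taps (tap 1 is the most recent;
  tap j ends ``(j-1)*lag`` before the output step -- strictly causal);
* **slide**  -- step between consecutive output rows (the bin width here,
  so the decoder updates at full temporal resolution).

Feature rows start at the first step where the oldest tap's window fits
entirely inside the recording; earlier steps are dropped, never zero-padded.

Windows shared between overlapping taps are computed once per (neuron,
window end) and reused, which is bit-identical to recomputing each tap.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

from .dwt import WaveletBasis, WaveletDecomposition, level_lengths
from .io import SpikeRaster

_CHUNK = 16384  # windows per wavedec batch; caps transient memory


@dataclass
class WACVector:
    """Averaged trend features of one window: ``c_avg`` = mean(c_J),
    ``d_avg[l-1]`` = mean(d_l)."""

    c_avg: float
    d_avg: list
    levels: int

    def __post_init__(self) -> None:
        if len(self.d_avg) != self.levels:
            raise ValueError("d_avg must have one entry per level")
        vals = [self.c_avg, *self.d_avg]
        if not np.all(np.isfinite(vals)):
            raise ValueError("WAC entries must be finite")

    def names(self) -> list:
        return [f"c{self.levels}A"] + [f"d{l}A" for l in range(1, self.levels + 1)]

    def as_dict(self) -> dict:
        d = {f"c{self.levels}A": self.c_avg}
        d.update({f"d{l}A": self.d_avg[l - 1] for l in range(1, self.levels + 1)})
        return d


@dataclass
class SlidingWindowSpec:
    """Bin/window/tap/lag/slide parameterization of the feature extractor."""

    bin_ms: float = 5.0
    window_ms: float = 1000.0
    taps: int = 4
    lag_ms: float = 50.0
    slide_ms: float = 5.0

    def __post_init__(self) -> None:
        if self.bin_ms <= 0:
            raise ValueError("bin_ms must be positive")
        for name in ("window_ms", "slide_ms"):
            v = getattr(self, name)
            if v <= 0 or not _is_multiple(v, self.bin_ms):
                raise ValueError(f"{name} must be a positive multiple of bin_ms")
        if self.taps < 1:
            raise ValueError("taps must be >= 1")
        if self.lag_ms < 0 or not _is_multiple(self.lag_ms, self.bin_ms):
            raise ValueError("lag_ms must be a non-negative multiple of bin_ms")
        if self.taps > 1 and self.lag_ms == 0:
            raise ValueError("lag_ms must be positive when taps > 1")

    @property
    def window_bins(self) -> int:
        return round(self.window_ms / self.bin_ms)

    @property
    def lag_bins(self) -> int:
        return round(self.lag_ms / self.bin_ms)

    @property
    def slide_bins(self) -> int:
        return round(self.slide_ms / self.bin_ms)

    @property
    def span_bins(self) -> int:
        """Total history consumed by one output step."""
        return self.window_bins + (self.taps - 1) * self.lag_bins

    @property
    def first_valid_bin(self) -> int:
        return self.span_bins - 1


def _is_multiple(v: float, base: float) -> bool:
    r = v / base
    return abs(r - round(r)) < 1e-9


@dataclass
class FeatureMatrix:
    """Assembled per-time-step decoder inputs.

    Row ``n`` corresponds to global bin ``first_valid_bin + n*slide_bins``.
    ``feature_labels[j]`` is ``(neuron_id, tap, coefficient_name)`` for WAC
    features or ``(neuron_id, tap, "count")`` for spike counts.
    """

    values: np.ndarray
    feature_labels: list
    first_valid_bin: int
    slide_bins: int = 1
    bin_ms: float = 5.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[1] != len(self.feature_labels):
            raise ValueError("one label per feature column required")

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    def step_bins(self) -> np.ndarray:
        """Global bin index of each row."""
        return self.first_valid_bin + self.slide_bins * np.arange(self.n_steps)

    def to_csv(self, path) -> None:
        """Export with a header of ``neuron|tap|coefficient`` labels so
        external learners (e.g. sequence models) can consume the matrix."""
        header = ",".join("|".join(str(p) for p in lab) for lab in self.feature_labels)
        np.savetxt(path, self.values, delimiter=",", header=header, comments="")


def average_trend_features(decomp: WaveletDecomposition) -> WACVector:
    """Collapse each coefficient vector of Q to its arithmetic mean."""
    if len(decomp.approx) == 0 or any(len(d) == 0 for d in decomp.details):
        raise ValueError("cannot average an empty coefficient vector")
    return WACVector(
        c_avg=float(np.mean(decomp.approx)),
        d_avg=[float(np.mean(d)) for d in decomp.details],
        levels=decomp.levels,
    )


_NAME_RE = re.compile(r"^([cd])_?(\d+)A?$")


def _parse_name(name: str, levels: int) -> tuple:
    """Normalize a coefficient name like ``c5A``/``c_5A``/``d3A``.

    Returns ("c", level) or ("d", level).
    """
    m = _NAME_RE.match(name)
    valid = [f"c{levels}A"] + [f"d{l}A" for l in range(1, levels + 1)]
    if not m:
        raise ValueError(f"unknown coefficient name {name!r}; valid names: {valid}")
    kind, lvl = m.group(1), int(m.group(2))
    if kind == "c" and lvl != levels:
        raise ValueError(
            f"{name!r} does not match decomposition depth {levels}; valid names: {valid}"
        )
    if kind == "d" and not 1 <= lvl <= levels:
        raise ValueError(f"{name!r} outside levels 1..{levels}; valid names: {valid}")
    return kind, lvl


def select_wac(wac: WACVector, selection) -> np.ndarray:
    """Pick WAC entries by name, in selection order (duplicates allowed)."""
    out = []
    for name in selection:
        kind, lvl = _parse_name(name, wac.levels)
        out.append(wac.c_avg if kind == "c" else wac.d_avg[lvl - 1])
    return np.asarray(out)


def default_selection(levels: int, n_details: int = 3) -> list:
    """Averaged scaling coefficient plus the ``n_details`` coarsest detail
    averages, e.g. levels=5 -> ["c5A", "d5A", "d4A", "d3A"]."""
    n_details = min(n_details, levels)
    return [f"c{levels}A"] + [f"d{l}A" for l in range(levels, levels - n_details, -1)]


def _windowed_waveforms(prefix: np.ndarray, window_bins: int) -> np.ndarray:
    """All in-window waveforms of one neuron as a (n_windows, W) stride view.

    ``prefix`` is the zero-prepended cumulative walk of the whole recording;
    the window starting at bin a has waveform prefix[a+1 : a+W+1] - prefix[a]
    (the kernel walk restarted at the window start).
    """
    n_bins = len(prefix) - 1
    n_windows = n_bins - window_bins + 1
    view = np.lib.stride_tricks.sliding_window_view(prefix[1:], window_bins)
    return view, prefix[:n_windows]


def _per_window_wac(row: np.ndarray, spec: SlidingWindowSpec, levels: int,
                    basis: WaveletBasis) -> dict:
    """Averaged coefficients of every window of one neuron.

    Returns ``{name: array over window end bins}`` where entry e corresponds
    to the window ending at global bin ``window_bins - 1 + e``.  Windows are
    batch-transformed with the same periodized cascade as
    :func:`spikewac.dwt.dwt_multilevel`, in chunks to bound memory.
    """
    W = spec.window_bins
    steps = 2 * row.astype(np.int64) - 1
    prefix = np.concatenate(([0], np.cumsum(steps)))
    view, offsets = _windowed_waveforms(prefix, W)
    n_windows = view.shape[0]
    names = [f"c{levels}A"] + [f"d{l}A" for l in range(levels, 0, -1)]
    out = {name: np.empty(n_windows) for name in names}
    for start in range(0, n_windows, _CHUNK):
        stop = min(start + _CHUNK, n_windows)
        block = view[start:stop].astype(float)
        block -= offsets[start:stop, None]
        with warnings.catch_warnings():
            # depth is validated against the ceil-halving rule ourselves;
            # periodization wraps the short-window boundary by construction
            warnings.simplefilter("ignore", UserWarning)
            coeffs = pywt.wavedec(block, basis.name, mode="periodization",
                                  level=levels, axis=1)
        # coeffs: [cJ, dJ, ..., d1]
        for name, c in zip(names, coeffs):
            out[name][start:stop] = c.mean(axis=1)
    return out


def wac_feature_matrix(raster: SpikeRaster, spec: SlidingWindowSpec,
                       levels: int = 5, selection=None,
                       basis: WaveletBasis | None = None) -> FeatureMatrix:
    """WAC features for every output step of a recording.

    For each step n on the slide grid and tap j, the ``window_bins``-bin
    window ending at bin ``n - (j-1)*lag_bins`` is run through
    kernel -> periodized db-wavelet cascade -> per-level averaging, and the
    named selection is kept.  Columns are ordered neuron-major, then tap,
    then coefficient.
    """
    basis = basis or WaveletBasis()
    _check_fit(raster, spec)
    level_lengths(spec.window_bins, levels)
    selection = list(selection) if selection is not None else default_selection(levels)
    for name in selection:
        _parse_name(name, levels)

    n_bins = raster.data.shape[1]
    W, lag, slide = spec.window_bins, spec.lag_bins, spec.slide_bins
    steps = np.arange(spec.first_valid_bin, n_bins, slide)
    cols, labels = [], []
    for i, nid in enumerate(raster.neuron_ids):
        per_end = _per_window_wac(raster.data[i], spec, levels, basis)
        for j in range(1, spec.taps + 1):
            ends = steps - (j - 1) * lag
            idx = ends - (W - 1)  # window-end bin -> index into per_end arrays
            for name in selection:
                cols.append(per_end[name][idx])
                labels.append((nid, j, name))
    values = np.column_stack(cols) if cols else np.empty((len(steps), 0))
    return FeatureMatrix(values, labels, spec.first_valid_bin, slide, spec.bin_ms)


def count_feature_matrix(raster: SpikeRaster, spec: SlidingWindowSpec) -> FeatureMatrix:
    """Classical sliding-window spike-count features.

    Feature (i, j) at step n is the number of occupied bins of neuron i in
    tap j's window; row alignment matches :func:`wac_feature_matrix`, so the
    two feature families are directly comparable.
    """
    _check_fit(raster, spec)
    n_bins = raster.data.shape[1]
    W, lag, slide = spec.window_bins, spec.lag_bins, spec.slide_bins
    steps = np.arange(spec.first_valid_bin, n_bins, slide)
    cols, labels = [], []
    for i, nid in enumerate(raster.neuron_ids):
        prefix = np.concatenate(([0], np.cumsum(raster.data[i], dtype=np.int64)))
        for j in range(1, spec.taps + 1):
            ends = steps - (j - 1) * lag
            cols.append((prefix[ends + 1] - prefix[ends + 1 - W]).astype(float))
            labels.append((nid, j, "count"))
    values = np.column_stack(cols) if cols else np.empty((len(steps), 0))
    return FeatureMatrix(values, labels, spec.first_valid_bin, slide, spec.bin_ms)


def _check_fit(raster: SpikeRaster, spec: SlidingWindowSpec) -> None:
    if abs(raster.bin_ms - spec.bin_ms) > 1e-9:
        raise ValueError(
            f"raster bin_ms={raster.bin_ms} does not match spec bin_ms={spec.bin_ms}"
        )
    n_bins = raster.data.shape[1]
    if n_bins < spec.span_bins:
        raise ValueError(
            f"recording has {n_bins} bins but one output step needs "
            f"{spec.span_bins} (window + (taps-1)*lag)"
        )
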