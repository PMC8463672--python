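"""Reading, writing and binning of spike and kinematic data.

Formats are deliberately minimal plain text:

* spike times -- one neuron per line, whitespace-separated event times in
  seconds; an empty line is a silent neuron;
* binary raster -- delimited 0/1 text, one neuron per row, with a sidecar
  header line ``# bin_ms=<v> t0_s=<v>``;
* kinematics -- delimited table (comma/tab/whitespace auto-detected) with a
  header row of covariate names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class SpikeRaster:
    """Binary neurons x time-bins matrix at a fixed bin width.

    Bins are half-open ``[b*bin_ms, (b+1)*bin_ms)`` relative to ``t0_s``;
    entry (i, b) is 1 iff neuron i spiked at least once in bin b.
    """

    data: np.ndarray
    bin_ms: float
    t0_s: float = 0.0
    neuron_ids: list = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster must be 2-D (neurons x bins)")
        if not np.all((self.data == 0) | (self.data == 1)):
            raise ValueError("raster entries must be 0 or 1")
        self.data = self.data.astype(np.uint8)
        if self.bin_ms <= 0:
            raise ValueError("bin_ms must be positive")
        if self.neuron_ids is None:
            self.neuron_ids = [f"n{i}" for i in range(self.data.shape[0])]
        if len(self.neuron_ids) != self.data.shape[0]:
            raise ValueError("one neuron_id per row required")

    @property
    def n_neurons(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_bins * self.bin_ms / 1000.0


@dataclass
class KinematicSeries:
    """Real-valued covariates on a regular time grid (rows = steps)."""

    data: np.ndarray
    names: list
    step_ms: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.step_ms <= 0:
            raise ValueError("step_ms must be positive")
        if self.data.shape[1] != len(self.names):
            raise ValueError("one column per covariate name required")
        if np.isnan(self.data).any():
            r, c = np.argwhere(np.isnan(self.data))[0]
            raise ValueError(f"missing value at row {r}, column {self.names[c]!r}")

    @property
    def n_steps(self) -> int:
        return self.data.shape[0]

    def column(self, name: str) -> np.ndarray:
        try:
            return self.data[:, self.names.index(name)]
        except ValueError:
            raise KeyError(f"unknown covariate {name!r}; have {self.names}") from None


def bin_spikes(spike_times, bin_ms: float, duration_s: float,
               neuron_ids=None, t0_s: float = 0.0) -> SpikeRaster:
    """Bin per-neuron spike times into a binary raster.

    An event at time t (seconds, relative to ``t0_s``) lands in bin
    ``floor(t*1000/bin_ms)``; events exactly on a boundary belong to the
    later bin.  Multiple events in one bin are clipped to 1 with a warning,
    since a binary raster at this width cannot represent them.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    n_bins = int(np.ceil(duration_s * 1000.0 / bin_ms))
    spike_times = list(spike_times)
    data = np.zeros((len(spike_times), n_bins), dtype=np.uint8)
    clipped = 0
    for i, times in enumerate(spike_times):
        times = np.asarray(list(times), dtype=float)
        if times.size == 0:
            continue
        bad = (times < 0) | (times >= duration_s)
        if bad.any():
            t = times[bad][0]
            raise ValueError(
                f"neuron {i}: event time {t} s outside [0, {duration_s}) s"
            )
        idx = np.floor(times * 1000.0 / bin_ms).astype(np.int64)
        uniq, counts = np.unique(idx, return_counts=True)
        clipped += int((counts > 1).sum())
        data[i, uniq] = 1
    if clipped:
        warnings.warn(
            f"{clipped} bins received multiple spikes and were clipped to 1; "
            f"bin_ms={bin_ms} may be too coarse for this data",
            stacklevel=2,
        )
    return SpikeRaster(data, bin_ms, t0_s, neuron_ids)


def read_spike_times(path) -> list:
    """Parse a spike-times file into per-neuron event lists (seconds)."""
    neurons = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            times = []
            for tok in tokens:
                try:
                    times.append(float(tok))
                except ValueError:
                    raise ValueError(
                        f"{path}: line {lineno}: non-numeric token {tok!r}"
                    ) from None
            neurons.append(times)
    return neurons


def write_spike_times(path, spike_times) -> None:
    with open(path, "w") as fh:
        for times in spike_times:
            fh.write(" ".join(repr(float(t)) for t in times) + "\n")


def read_kinematics(path, step_ms: float) -> KinematicSeries:
    """Read a delimited kinematics table with a header of covariate names."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh
                 if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    header = [t.strip() for t in _split(lines[0], delim)]
    if all(_is_number(t) for t in header):
        raise ValueError(f"{path}: missing header row of covariate names")
    rows = []
    for rowno, line in enumerate(lines[1:], 1):
        tokens = _split(line, delim)
        if len(tokens) != len(header):
            raise ValueError(
                f"{path}: row {rowno} has {len(tokens)} values, expected {len(header)}"
            )
        try:
            rows.append([float(t) for t in tokens])
        except ValueError:
            raise ValueError(f"{path}: row {rowno}: non-numeric value") from None
    return KinematicSeries(np.asarray(rows), header, step_ms)


def write_kinematics(path, kin: KinematicSeries) -> None:
    np.savetxt(path, kin.data, delimiter=",", header=",".join(kin.names), comments="")


def write_raster(path, raster: SpikeRaster) -> None:
    """Raster as delimited 0/1 text with a sidecar metadata line."""
    with open(path, "w") as fh:
        fh.write(f"# bin_ms={raster.bin_ms!r} t0_s={raster.t0_s!r}\n")
        for row in raster.data:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_raster(path) -> SpikeRaster:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '# bin_ms=... t0_s=...' header line")
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        data = np.loadtxt(fh, dtype=np.uint8, ndmin=2)
    return SpikeRaster(data, float(meta["bin_ms"]), float(meta["t0_s"]))


def resample_kinematics(kin: KinematicSeries, step_ms: float) -> KinematicSeries:
    """Linear interpolation of covariates onto a new regular grid.

    Provided for recordings whose kinematic sampling differs from the
    decoder's slide grid; simulator output is already on the bin grid.
    """
    if abs(kin.step_ms - step_ms) < 1e-9:
        return kin
    t_old = np.arange(kin.n_steps) * kin.step_ms
    t_new = np.arange(0.0, t_old[-1] + 1e-9, step_ms)
    data = np.column_stack([np.interp(t_new, t_old, kin.data[:, j])
                            for j in range(kin.data.shape[1])])
    return KinematicSeries(data, list(kin.names), step_ms, kin.t0_s)


def _sniff_delimiter(header_line: str):
    if "," in header_line:
        return ","
    if "\t" in header_line:
        return "\t"
    return None  # whitespace


def _split(line: str, delim):
    return [t for t in (line.split(delim) if delim else line.split())]


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
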