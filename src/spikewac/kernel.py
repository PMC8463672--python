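"""Kernel function: binary spike trains to discrete neural signal waveforms.

A binary spike train ``x[n]`` (one bin per 5--10 ms, at most one spike per
bin) is converted into a signed cumulative walk

    k[n] = k[n-1] + 2 * (x[n] - 0.5),   k[0] = 0,

which steps +1 on a spike bin and -1 on a silent bin.  The walk fluctuates
with the *placement* of spikes inside the window, not just their number, so
downstream wavelet features can read temporal structure that a plain count
throws away.  The walk is restarted at the beginning of every analysis
window: a single global walk would make the feature level depend on the
whole history of the recording and destroy stationarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class NeuralWaveform:
    """Signed cumulative walk of one spike-train window.

    ``values`` has exactly T samples (``k[1..T]``); the implicit seed
    ``k[0] = 0`` is not stored so that a 1 s window at 5 ms bins yields a
    200-sample signal.
    """

    values: np.ndarray
    source_window: tuple = field(default=(None, 0, 0))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        v = self.values
        if v.ndim != 1 or v.size == 0:
            raise ValueError("waveform must be a non-empty 1-D sequence")
        if v[0] not in (-1, 1):
            raise ValueError("waveform must start at -1 or +1 (unit step from k[0]=0)")
        if v.size > 1 and not np.all(np.abs(np.diff(v)) == 1):
            raise ValueError("waveform must change by exactly 1 per bin")


def waveform_from_spikes(x, source_window: tuple = (None, 0, 0)) -> NeuralWaveform:
    """Apply the kernel function to a binary spike-train window.

    Parameters
    ----------
    x : sequence of {0, 1}
        Binary spike indicators, one per bin.

    Returns
    -------
    NeuralWaveform
        ``values[n-1] = (#ones in x[1..n]) - (#zeros in x[1..n])``.
    """
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("spike-train window must be non-empty")
    if not np.all((x == 0) | (x == 1)):
        bad = x[(x != 0) & (x != 1)][0]
        raise ValueError(f"spike train must be binary; found entry {bad!r}")
    steps = 2 * x.astype(np.int64) - 1
    return NeuralWaveform(np.cumsum(steps), source_window)


def waveform_values(x) -> np.ndarray:
    """Waveform samples only, without constructing the dataclass.

    Identical arithmetic to :func:`waveform_from_spikes`; used on hot paths.
    """
    return np.cumsum(2 * np.asarray(x, dtype=np.int64) - 1)
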