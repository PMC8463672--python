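"""Multilevel discrete wavelet analysis/synthesis of neural signal waveforms.

The analysis cascade repeatedly splits a signal into a lowpass (trend) and a
highpass (detail) half-band, downsampling by two at each level.  The outputs
of a J-level decomposition -- one approximation vector ``c_J`` plus detail
vectors ``d_1 .. d_J`` (level 1 = finest) -- are the *trend features Q* of a
spike-train waveform.

Boundary handling is **periodization**: the signal is treated as circular,
each level has ``ceil(n/2)`` coefficients, and an odd-length level input is
extended by repeating its final sample before wrapping.  This is the only
standard convention under which a 200-sample waveform (1 s window at 5 ms
bins) decomposed 5 levels with db3 produces detail lengths
[100, 50, 25, 13, 7] and an approximation of length 7.  On fully even
halving chains the transform is orthonormal (energy conserving); the
odd-length extension keeps perfect reconstruction but gives up exact
orthonormality at that level.

The filter bank itself is delegated to PyWavelets; this module owns the
conventions (level ordering, length bookkeeping, validation) and the
container types.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

_MODE = "periodization"


@dataclass
class WaveletBasis:
    """An orthonormal Daubechies filter bank.

    Filters are taken from the standard construction (via PyWavelets) and
    re-validated on instantiation: lowpass sums to sqrt(2), highpass sums to
    0, and every filter has unit l2 norm.  db3 (3 vanishing moments, 6 taps)
    is the default basis for spike-train waveforms.
    """

    name: str = "db3"
    analysis_lowpass: np.ndarray = field(default=None, repr=False)
    analysis_highpass: np.ndarray = field(default=None, repr=False)
    synthesis_lowpass: np.ndarray = field(default=None, repr=False)
    synthesis_highpass: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.name.startswith("db"):
            raise ValueError(
                f"unsupported basis {self.name!r}: only Daubechies (dbN) bases are supported"
            )
        w = pywt.Wavelet(self.name)
        if self.analysis_lowpass is None:
            self.analysis_lowpass = np.asarray(w.dec_lo)
            self.analysis_highpass = np.asarray(w.dec_hi)
            self.synthesis_lowpass = np.asarray(w.rec_lo)
            self.synthesis_highpass = np.asarray(w.rec_hi)
        self.validate()

    def validate(self, tol: float = 1e-12) -> None:
        lo, hi = self.analysis_lowpass, self.analysis_highpass
        if abs(lo.sum() - math.sqrt(2.0)) > tol:
            raise ValueError("analysis lowpass must sum to sqrt(2)")
        if abs(hi.sum()) > tol:
            raise ValueError("analysis highpass must sum to 0")
        for f in (lo, hi, self.synthesis_lowpass, self.synthesis_highpass):
            if abs(np.linalg.norm(f) - 1.0) > tol:
                raise ValueError("filters must have unit l2 norm (orthonormal bank)")

    @property
    def filter_length(self) -> int:
        return len(self.analysis_lowpass)


@dataclass
class WaveletDecomposition:
    """Trend features Q of one signal.

    ``details[0]`` is the finest level (d_1), ``details[-1]`` the coarsest
    (d_J); ``approx`` is the scaling-function coefficient vector c_J.
    """

    approx: np.ndarray
    details: list
    levels: int
    original_length: int

    def __post_init__(self) -> None:
        self.approx = np.asarray(self.approx, dtype=float)
        self.details = [np.asarray(d, dtype=float) for d in self.details]
        if len(self.details) != self.levels:
            raise ValueError("number of detail vectors must equal levels")
        for lvl, expected in enumerate(level_lengths(self.original_length, self.levels), 1):
            got = len(self.details[lvl - 1])
            if got != expected:
                raise ValueError(
                    f"detail level {lvl} has length {got}, expected {expected} "
                    f"for original length {self.original_length}"
                )
        if len(self.approx) != len(self.details[-1]):
            raise ValueError("approximation must have the coarsest-detail length")

    def coefficient_names(self) -> list:
        """Canonical names: ``c{J}A`` then ``d{J}A .. d{1}A`` averages exist
        per level; here just the vector labels ``c{J}`` and ``d{l}``."""
        return [f"c{self.levels}"] + [f"d{l}" for l in range(self.levels, 0, -1)]


def level_lengths(n: int, levels: int) -> list:
    """Ceil-halving length of each detail level (level 1 first).

    Raises if some level's input would be shorter than 2 samples.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    out = []
    for lvl in range(1, levels + 1):
        if n < 2:
            raise ValueError(
                f"cannot decompose {levels} levels: level {lvl} input has length {n} < 2"
            )
        n = math.ceil(n / 2)
        out.append(n)
    return out


def dwt_multilevel(signal, basis: WaveletBasis | None = None, levels: int = 5) -> WaveletDecomposition:
    """J-level periodized analysis cascade.

    Parameters
    ----------
    signal : 1-D real sequence
    basis : WaveletBasis, default db3
    levels : int
        Decomposition depth J; every level input must have >= 2 samples.

    Returns
    -------
    WaveletDecomposition
        With ``details[0]`` the finest band.
    """
    basis = basis or WaveletBasis()
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be 1-D")
    level_lengths(len(signal), levels)  # validates depth
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(signal, basis.name, mode=_MODE, level=levels)
    approx, coarse_to_fine = coeffs[0], coeffs[1:]
    return WaveletDecomposition(
        approx=approx,
        details=list(reversed(coarse_to_fine)),
        levels=levels,
        original_length=len(signal),
    )


def idwt_multilevel(decomp: WaveletDecomposition, basis: WaveletBasis | None = None) -> np.ndarray:
    """Inverse cascade; returns a signal of ``decomp.original_length``."""
    basis = basis or WaveletBasis()
    coeffs = [decomp.approx] + list(reversed(decomp.details))
    rec = pywt.waverec(coeffs, basis.name, mode=_MODE)
    return np.asarray(rec[: decomp.original_length])


def dump_decomposition(decomp: WaveletDecomposition, path) -> None:
    """Debug dump: one labelled coefficient vector per line."""
    with open(path, "w") as fh:
        fh.write(f"c{decomp.levels}\t" + "\t".join(repr(v) for v in decomp.approx) + "\n")
        for lvl in range(decomp.levels, 0, -1):
            d = decomp.details[lvl - 1]
            fh.write(f"d{lvl}\t" + "\t".join(repr(v) for v in d) + "\n")
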