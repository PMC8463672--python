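"""Synthetic BMI recordings: tuned spike rasters plus kinematics.

Two movement paradigms are emulated:

* **center_out** -- point-to-point reaches from a central position to 8
  radial targets with minimum-jerk (bell-shaped) speed profiles; covariates
  ``pos_x, pos_y, vel_x, vel_y``.
* **locomotion** -- treadmill-like sinusoidal ankle trajectories:
  ``ankle_x`` with period 3.2 s and amplitude 0.25 (slow, large) and
  ``ankle_y`` with period 1.9 s and amplitude 0.05 (fast, small).  Each
  rhythm carries stride-to-stride timing variability, modelled as a phase
  random walk accumulating ``phase_jitter`` radians (SD) per cycle, so a
  rhythm stays predictable for a number of *cycles* rather than forever --
  the slow rhythm therefore remains informative over longer absolute
  history than the fast one, as in real gait.

Spiking is Bernoulli per 5 ms bin (the downstream pipeline consumes binary
bins, so at most one spike per bin by construction), with cosine direction
tuning in the rate-coded regime:

    p_i[n] = clip(b_i + m_i * cos(theta[n] - phi_i) * gate[n], 0, 1)

where ``theta`` is the movement direction (center-out) or the phase of the
ankle oscillation the neuron is locked to (locomotion; the population is
split between the slow ankle_x and the fast ankle_y rhythm so both
covariates are represented), and ``gate`` scales modulation by movement
speed in center-out reaches.

The **temporal-code regime** emulates information carried by spike timing
rather than by short-window counts.  Firing is sparse (low baseline) with
the same cosine intensity profile, and the *inter-spike regularity*
switches with a binary kinematic state (rising vs falling ankle_y, or fast
vs slow reach speed): in the regular state spikes are laid down on a
jittered lattice paced by the integrated intensity (near-clockwork
spacing), in the irregular state they are drawn independently per bin at
the same intensity.  Both states therefore share the same expected rate at
every bin; the regularity switch is carried purely by spike-train
variability, while the sparse phase-locked intensity makes the slow
kinematics recoverable only by features that integrate long windows.

All randomness flows from one integer seed through numpy's Generator, so a
spec reproduces bit-identically across runs and platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import KinematicSeries, SpikeRaster

#: per-bin baseline probability and tuning depth of the rate-coded regime
#: (0.05 per 5 ms bin = 10 Hz baseline, 80% depth)
RATE_BASELINE = 0.05
RATE_MODULATION = 0.04

#: sparse, strongly phase-locked firing of the temporal-code regime
#: (0.0125 per 5 ms bin = 2.5 Hz baseline, 80% depth)
TEMPORAL_BASELINE = 0.0125
TEMPORAL_MODULATION = 0.01

#: lattice jitter, as a fraction of the local inter-spike spacing
LATTICE_JITTER_FRAC = 0.1


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic recording.

    ``baseline`` and ``modulation`` are per-bin spike probabilities (scalar
    or per-neuron arrays); ``phases`` defaults to preferred directions
    spread uniformly around the circle.  ``seed`` is mandatory: every draw
    must be reproducible.
    """

    n_neurons: int
    duration_s: float
    seed: int
    bin_ms: float = 5.0
    mode: str = "locomotion"
    baseline: float | np.ndarray | None = None
    modulation: float | np.ndarray | None = None
    phases: np.ndarray | None = None
    temporal_code: bool = False
    ankle_x_period_s: float = 3.2
    ankle_x_amplitude: float = 0.25
    ankle_y_period_s: float = 1.9
    ankle_y_amplitude: float = 0.05
    phase_jitter: float = 1.2  # rad SD accumulated per gait cycle
    n_targets: int = 8
    reach_s: float = 0.6
    hold_s: float = 0.4
    target_radius: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("center_out", "locomotion"):
            raise ValueError(f"unknown mode {self.mode!r}: use 'center_out' or 'locomotion'")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_neurons < 1 or self.duration_s <= 0 or self.bin_ms <= 0:
            raise ValueError("n_neurons, duration_s and bin_ms must be positive")
        n_bins = self.duration_s * 1000.0 / self.bin_ms
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError("duration_s must be an integer number of bins")
        if self.baseline is None:
            self.baseline = TEMPORAL_BASELINE if self.temporal_code else RATE_BASELINE
        if self.modulation is None:
            self.modulation = TEMPORAL_MODULATION if self.temporal_code else RATE_MODULATION
        b = np.broadcast_to(np.asarray(self.baseline, dtype=float), (self.n_neurons,))
        m = np.broadcast_to(np.asarray(self.modulation, dtype=float), (self.n_neurons,))
        if np.any(b < 0) or np.any(b + m > 1):
            raise ValueError("need 0 <= baseline and baseline + modulation <= 1 per bin")
        self._b, self._m = b.copy(), m.copy()
        if self.phases is None:
            self.phases = 2 * np.pi * np.arange(self.n_neurons) / self.n_neurons
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.shape != (self.n_neurons,):
            raise ValueError("phases must have one entry per neuron")

    @property
    def n_bins(self) -> int:
        return round(self.duration_s * 1000.0 / self.bin_ms)


def simulate_kinematics(spec: SimulationSpec) -> KinematicSeries:
    """Kinematic covariates sampled on the bin grid."""
    t = (np.arange(spec.n_bins) + 0.5) * spec.bin_ms / 1000.0
    if spec.mode == "locomotion":
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x71]))
        cols = []
        for period, amp in ((spec.ankle_x_period_s, spec.ankle_x_amplitude),
                            (spec.ankle_y_period_s, spec.ankle_y_amplitude)):
            # phase drift accumulates per stride and is linearly interpolated
            # between stride knots, so trajectories stay smooth within a cycle
            n_knots = int(spec.duration_s / period) + 2
            knots = np.cumsum(rng.normal(0.0, spec.phase_jitter, size=n_knots))
            drift = np.interp(t, np.arange(n_knots) * period, knots)
            cols.append(amp * np.sin(2 * np.pi * t / period + drift))
        return KinematicSeries(np.column_stack(cols), ["ankle_x", "ankle_y"], spec.bin_ms)
    return _center_out_kinematics(spec, t)


def _min_jerk(u: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on u in [0, 1] (bell-shaped speed)."""
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def _center_out_kinematics(spec: SimulationSpec, t: np.ndarray) -> KinematicSeries:
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xC0]))
    dt = spec.bin_ms / 1000.0
    cycle = spec.hold_s + spec.reach_s + spec.hold_s + spec.reach_s  # out and back
    pos = np.zeros((spec.n_bins, 2))
    order = rng.permutation(spec.n_targets)
    for n, tn in enumerate(t):
        k, tau = divmod(tn, cycle)
        angle = 2 * np.pi * order[int(k) % spec.n_targets] / spec.n_targets
        target = spec.target_radius * np.array([math.cos(angle), math.sin(angle)])
        if tau < spec.hold_s:
            p = 0.0
        elif tau < spec.hold_s + spec.reach_s:
            p = _min_jerk((tau - spec.hold_s) / spec.reach_s)
        elif tau < 2 * spec.hold_s + spec.reach_s:
            p = 1.0
        else:
            p = 1.0 - _min_jerk((tau - 2 * spec.hold_s - spec.reach_s) / spec.reach_s)
        pos[n] = p * target
    vel = np.gradient(pos, dt, axis=0)
    data = np.column_stack([pos, vel])
    return KinematicSeries(data, ["pos_x", "pos_y", "vel_x", "vel_y"], spec.bin_ms)


def _oscillation_phase(x: np.ndarray, amplitude: float, period_s: float,
                       step_ms: float) -> np.ndarray:
    """Instantaneous phase of a sinusoidal covariate from its quadratures."""
    omega = 2 * np.pi / period_s
    dx = np.gradient(x, step_ms / 1000.0)
    return np.arctan2(x / amplitude, dx / (amplitude * omega))


def _tuning_angles_and_gate(kin: KinematicSeries, spec: SimulationSpec):
    """Per-neuron tuning variable theta[i, n] and modulation gate in [0, 1].

    Locomotion involves two independent rhythms (ankle_x slow, ankle_y
    fast); the population is split between them -- even-indexed neurons are
    phase-locked to the ankle_x oscillation, odd-indexed neurons to the
    ankle_y oscillation -- so both covariates are represented.  Center-out
    neurons are tuned to movement direction, gated by normalized speed.
    """
    if spec.mode == "locomotion":
        th_x = _oscillation_phase(kin.column("ankle_x"), spec.ankle_x_amplitude,
                                  spec.ankle_x_period_s, kin.step_ms)
        th_y = _oscillation_phase(kin.column("ankle_y"), spec.ankle_y_amplitude,
                                  spec.ankle_y_period_s, kin.step_ms)
        theta = np.empty((spec.n_neurons, kin.n_steps))
        theta[0::2] = th_x
        theta[1::2] = th_y
        return theta, np.ones(kin.n_steps)
    vx, vy = kin.column("vel_x"), kin.column("vel_y")
    speed = np.hypot(vx, vy)
    top = speed.max() or 1.0
    theta = np.broadcast_to(np.arctan2(vy, vx), (spec.n_neurons, kin.n_steps))
    return theta, speed / top


def _binary_state(kin: KinematicSeries, spec: SimulationSpec) -> np.ndarray:
    """The kinematic state that switches spike-train regularity."""
    if spec.mode == "locomotion":
        dy = np.gradient(kin.column("ankle_y"), kin.step_ms / 1000.0)
        return dy > 0
    vx, vy = kin.column("vel_x"), kin.column("vel_y")
    speed = np.hypot(vx, vy)
    return speed > np.median(speed)


def simulate_spikes(kin: KinematicSeries, spec: SimulationSpec) -> SpikeRaster:
    """Draw a binary raster from the tuning model on the kinematic grid."""
    if abs(kin.step_ms - spec.bin_ms) > 1e-9 or kin.n_steps != spec.n_bins:
        raise ValueError(
            f"kinematics grid ({kin.n_steps} steps at {kin.step_ms} ms) does not match "
            f"the simulation grid ({spec.n_bins} bins at {spec.bin_ms} ms)"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x5B]))
    theta, gate = _tuning_angles_and_gate(kin, spec)
    prob = np.clip(
        spec._b[:, None] + spec._m[:, None] * np.cos(theta - spec.phases[:, None]) * gate[None, :],
        0.0, 1.0,
    )
    if not spec.temporal_code:
        data = (rng.random(prob.shape) < prob).astype(np.uint8)
        return SpikeRaster(data, spec.bin_ms, 0.0, [f"n{i}" for i in range(spec.n_neurons)])

    state = _binary_state(kin, spec)
    data = np.zeros(prob.shape, dtype=np.uint8)
    runs = _runs(state)
    for i in range(spec.n_neurons):
        for start, stop, regular in runs:
            lam = prob[i, start:stop]
            if regular:
                _lattice_spikes(data[i], start, lam, rng)
            else:
                seg = rng.random(stop - start) < lam
                data[i, start:stop] = seg
    return SpikeRaster(data, spec.bin_ms, 0.0, [f"n{i}" for i in range(spec.n_neurons)])


def _runs(state: np.ndarray):
    """Contiguous (start, stop, value) runs of a boolean sequence."""
    edges = np.flatnonzero(np.diff(state.astype(np.int8))) + 1
    bounds = np.concatenate(([0], edges, [len(state)]))
    return [(bounds[k], bounds[k + 1], bool(state[bounds[k]]))
            for k in range(len(bounds) - 1)]


def _lattice_spikes(row: np.ndarray, start: int, lam: np.ndarray,
                    rng: np.random.Generator) -> None:
    """Quasi-periodic spikes paced by the integrated intensity.

    Spike positions are the bins where ``cumsum(lam) + u0`` crosses an
    integer (u0 uniform, so the expected count matches the Bernoulli
    regime), then jittered by a Gaussian with SD equal to
    ``LATTICE_JITTER_FRAC`` of the local spacing.
    """
    big = np.floor(np.cumsum(lam) + rng.uniform())
    hits = np.flatnonzero(np.diff(np.concatenate(([0.0], big))) >= 1)
    if hits.size == 0:
        return
    spacing = 1.0 / np.maximum(lam[hits], 1e-12)
    jitter = np.rint(rng.normal(0.0, LATTICE_JITTER_FRAC * spacing)).astype(np.int64)
    pos = np.clip(hits + jitter, 0, len(lam) - 1)
    row[start + pos] = 1


def simulate(spec: SimulationSpec):
    """Convenience wrapper: kinematics plus the matching raster."""
    kin = simulate_kinematics(spec)
    return simulate_spikes(kin, spec), kin
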