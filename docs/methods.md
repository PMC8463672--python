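# Methods

## Feature model

A spike train is binned at 5 ms into binary indicators `x[n]` (multiple
events in one bin are clipped to 1 with a warning — at this width real
cortical units almost never fire twice).  Inside each analysis window the
**kernel function** restarts a signed walk `k[n] = k[n-1] + 2(x[n] - 1/2)`
with `k[0] = 0`, giving exactly T samples for a T-bin window.  The restart
is deliberate: one global cumulative trace sliced into windows would make
the feature level depend on the entire session history and destroy
stationarity across windows.  Useful identities: `k[T] = 2S - T` for S
spikes in the window, and the waveform of the complemented train is the
negation of the original.

The walk is analyzed with a J-level **discrete wavelet transform** in the
db3 basis (3 vanishing moments, 6 taps; filters taken from the standard
Daubechies construction and re-validated against the orthonormal-bank
identities at build time, so a transcription typo cannot pass silently).
Boundary handling is **periodization**: circular extension, `ceil(n/2)`
outputs per level, an odd-length level input extended by repeating its last
sample.  This is the only standard convention that yields detail lengths
[100, 50, 25, 13, 7] and approximation length 7 for T = 200 and J = 5, and
it keeps perfect reconstruction exactly (verified to 1e-10).  Energy is
conserved on fully even halving chains; the odd-length extension (levels 4
and 5 of T = 200) gives up exact orthonormality there, which is why the
energy-conservation test uses T = 256.

Each coefficient vector is collapsed to its arithmetic mean — the
**wavelet average coefficients** `c{J}A, d{J}A … d{1}A`.  The default
decoder selection is the scaling average plus the three coarsest detail
averages (`c5A, d5A, d4A, d3A` at J = 5).  The source material is
internally inconsistent about whether the fine (`d1A–d3A`) or coarse
(`d3A–d5A`) detail set enters the Wiener sum; we default to the coarse
reading, which matches the worked selection example given there, and
expose the selection as a config knob so either choice is one line away.

## Sliding-window geometry

`bin` (5 ms) is the elementary quantum; `window` the span transformed into
one WAC or count; `taps` the number of time-shifted windows feeding one
output; `lag` the offset between consecutive taps; `slide` (= bin) the
output step.  Tap 1 ends at the output bin and tap j ends `(j-1)·lag`
earlier — strictly causal, since an online decoder cannot see the future.
Rows before the first step whose oldest tap fits are dropped, never
zero-padded (cost: window + (taps-1)·lag of data, ~1.15 s for the wavelet
Wiener preset).  Overlapping taps reuse the per-(neuron, window-end) WAC,
computed batch-wise over all window positions; this is bit-identical to
naive per-tap recomputation (asserted in the tests).

## Decoders

*Wiener*: ordinary least squares from the feature row to each covariate,
with intercept, on z-scored features (WAC levels differ in scale by orders
of magnitude) — weights are mapped back to original units, so the stored
model is a plain affine map.  Ridge (on the z-scored scale) is available
and defaults to 0.  A rank-deficient design falls back to the minimum-norm
solution with a warning.

*Kalman*: kinematics as hidden state, features as observations — the
standard decoding direction.  (The printed state-space form in the source
swaps these roles, which cannot be run when kinematics are unobserved at
test time; the filtering recursion itself is the standard
predict/update pair either way.)  A and C by least squares, W and V as
residual covariances (symmetrized; PSD by construction), x0 = first
training state, P0 = W.  The covariance is re-symmetrized each step; a
singular innovation covariance falls back to the pseudo-inverse with a
warning.  For locomotion the state is augmented with first-difference
velocity columns, standard practice when the observed covariates are
positions only.

## Evaluation protocol

5-fold cross-validation on **contiguous time blocks** (sizes differ by at
most one, larger first).  Shuffled row-level folds would leak: adjacent
rows share nearly all of their feature windows.  For the same reason
training rows whose feature windows reach into the held-out block (one
window-span after the block) are dropped.  Score: Pearson correlation per
covariate per fold, summarized as mean ± sample SD (ddof = 1, n = 5
folds); zero-variance inputs yield NaN with a warning, never a silent 0.
Paired comparisons: Wilcoxon signed-rank (exact by enumeration of the 2^n
sign assignments for n ≤ 12, average ranks on ties, two-sided by default;
larger n delegate to scipy) and a paired t-test on Fisher-z transformed
ccs with |r| clipped to 1 - 1e-12.

## The simulator: what it emulates, and what it does not

*Kinematics.*  Center-out: reaches from the origin to 8 radial targets
(minimum-jerk position profile, 0.6 s reach, 0.4 s holds, seeded target
order).  Locomotion: two sinusoidal rhythms, ankle_x with period 3.2 s and
amplitude 0.25, ankle_y with period 1.9 s and amplitude 0.05, each with
stride-to-stride timing variability modelled as a phase random walk
accumulating 1.2 rad (SD) per cycle, interpolated linearly between stride
knots so trajectories stay smooth.  The jitter matters: perfectly periodic
kinematics never decorrelate, any window length is linearly invertible,
and the window-size sweep would be monotone; with per-cycle jitter a
rhythm stays predictable for a fixed number of *cycles*, so the slow
rhythm supports longer windows than the fast one — the ordering the sweep
study measures.

*Spiking.*  Bernoulli per 5 ms bin (the pipeline consumes binary bins, so
per-bin Bernoulli rather than Poisson counts), cosine-tuned:
`p_i[n] = clip(b_i + m_i cos(theta[n] - phi_i) · gate[n])`.  In center-out
mode theta is movement direction and the gate is normalized speed; in
locomotion mode the population is split between the two rhythms (even
neurons phase-locked to ankle_x, odd to ankle_y) so both covariates are
represented — locking everyone to a single rhythm would leave the other
covariate undecodable at incommensurate periods.  Rate-coded defaults:
b = 0.05/bin (10 Hz), m = 0.04 (80 % depth), preferred phases spread
uniformly.

*Temporal-code regime.*  Firing is sparse (b = 0.0125/bin = 2.5 Hz,
80 % depth) and strongly phase-locked, and the inter-spike **regularity**
switches with a binary kinematic state (rising vs falling ankle_y): in the
regular state spikes sit on a jittered lattice paced by the integrated
intensity (jitter SD = 10 % of the local spacing), in the irregular state
they are i.i.d. Bernoulli at the same intensity.  Both states share the
same expected rate in every bin, so the regularity switch is invisible to
any feature that is linear in the raster — including, by design, WAC
feature *means*; it shows up in feature variance (measured: 500 ms-window
counts match to < 1 % while the variance of the drift-detrended waveform
excursion differs many-fold).  A genuinely rate-free temporal code is
therefore *not linearly decodable at all*: every feature in this package
(count or WAC) is affine in the binary raster, so a linear readout sees
only conditional means.  What the wavelet decoder gains in this regime —
and what the comparison study measures — is its long multiscale window:
with 2.5 Hz firing a 50 ms count window contains 0.125 expected spikes and
is noise-dominated, while the 1 s WAC window integrates the phase-locked
timing structure across ~200 bins.  This is the package's reading of
"temporal coding for linear decoders": information carried by the
placement of sparse spikes over long history, not by short-window counts.

Not emulated: biophysical dynamics, refractoriness, correlated noise
across neurons, electrode nonstationarity, real reach variability.
Passing studies on this generator show the pipeline's relative ordering
under its assumptions; they do not certify absolute cc levels on animal
data.

## Simulation studies and problem sizes

The two stochastic studies in `tests/test_acceptance.py` use: (a) 20
neurons, 10 simulated minutes, 10 seeds for the sliding-vs-non-sliding and
WAC-vs-counts contrasts (medians of grand-mean cc over seeds); (b) 12
neurons, 2 simulated minutes, 10 seeds, windows
{100, 200, 350, 500, 750, 1000} ms for the window-size sweep.  These sizes
give stable medians while keeping the full suite in a few minutes of CPU.
For short sweep windows the decomposition depth is clamped to the deepest
level whose input still has ≥ 2 samples (a 100 ms window supports 4
levels), with the selection re-derived as c{J}A plus the three coarsest
details.

## Numerical choices

- Bins are half-open `[b·Δ, (b+1)·Δ)`; a boundary event belongs to the
  later bin (floor semantics, no ambiguity).
- Feature z-scoring guards zero-SD columns (treated as SD 1).
- OLS solves the normal equations; rank deficiency is detected on the Gram
  matrix and falls back to `lstsq` (minimum norm).
- Wilcoxon enumeration uses `W+ >= w - 1e-9` / `<= w + 1e-9` tail
  inclusion so ties at the observed statistic count as extreme, matching
  the reference exact implementation.
- All simulator randomness derives from one integer seed through numpy's
  PCG64 `Generator` with fixed SeedSequence branches per component
  (kinematics / spikes), so outputs are bit-reproducible across platforms.

## Known limitations

- Only Daubechies bases are wired up (db3 default); the transform module's
  boundary convention is fixed to periodization.
- The Kalman filter inverts the innovation covariance every step; with
  hundreds of WAC features this is the slow path (a steady-state gain
  would be the natural optimization).
- The exact Wilcoxon enumeration is limited to n ≤ 12 pairs; beyond that
  scipy's implementation (exact where it can, else approximate) is used.
- Count features are integers but are modelled by the same Gaussian linear
  machinery as WAC — that is the point of the comparison, not a bug, but
  it means the "classical" baselines here are as charitable as linear
  theory allows.
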