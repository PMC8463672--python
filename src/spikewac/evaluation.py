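"""Cross-validated decoding evaluation and paired statistical comparisons.

Performance is the Pearson correlation coefficient (cc) between decoded and
true covariates, reported per fold of a k-fold cross-validation (5 folds by
default, mean +/- sample SD over folds).  Folds are *contiguous time
blocks*: sliding-window features of adjacent rows share raster bins, so
shuffled row-level folds would leak test structure into training.  For the
same reason, training rows whose feature windows reach into the held-out
block are dropped (a "no-peek" margin of one window span).

Method comparisons use the Wilcoxon signed-rank test on paired per-fold
ccs (exact, by enumerating sign assignments, for small n) or a paired
t-test on Fisher z-transformed ccs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .config import PipelineConfig, max_levels
from .decoders import fit_kalman, fit_wiener, kalman_filter, predict_wiener
from .io import KinematicSeries, SpikeRaster, resample_kinematics
from .wac import count_feature_matrix, wac_feature_matrix


@dataclass
class EvalReport:
    """Per-fold correlation coefficients of one pipeline configuration."""

    per_fold_cc: np.ndarray          # folds x covariates
    covariates: list
    config_fingerprint: str = ""
    label: str = ""
    comparisons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.per_fold_cc = np.asarray(self.per_fold_cc, dtype=float)
        finite = self.per_fold_cc[np.isfinite(self.per_fold_cc)]
        if finite.size and (np.abs(finite) > 1 + 1e-12).any():
            raise ValueError("correlation coefficients must lie in [-1, 1]")

    @property
    def mean(self) -> np.ndarray:
        return np.nanmean(self.per_fold_cc, axis=0)

    @property
    def sd(self) -> np.ndarray:
        return np.nanstd(self.per_fold_cc, axis=0, ddof=1)

    def mean_cc(self) -> float:
        """Grand mean cc over folds and covariates."""
        return float(np.nanmean(self.per_fold_cc))

    def to_frame(self) -> pd.DataFrame:
        folds, ncov = self.per_fold_cc.shape
        return pd.DataFrame({
            "fold": np.repeat(np.arange(folds), ncov),
            "covariate": self.covariates * folds,
            "cc": self.per_fold_cc.ravel(),
        })

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# config={self.config_fingerprint} label={self.label}\n")
            fh.write(self.to_frame().to_csv(index=False))
            fh.write("# summary: covariate mean sd\n")
            for name, m, s in zip(self.covariates, self.mean, self.sd):
                fh.write(f"# {name} {m:.6f} {s:.6f}\n")
            for a, b, test, p in self.comparisons:
                fh.write(f"# comparison: {a} vs {b} [{test}] p={p:.6g}\n")


def pearson_cc(a, b) -> float:
    """Pearson product-moment correlation; NaN (with a warning) when either
    input has zero variance, never silently 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("inputs must be equal-length 1-D sequences of length >= 2")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("correlation undefined for zero-variance input; returning NaN",
                      stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def kfold_blocks(n_steps: int, k: int) -> list:
    """k contiguous, disjoint, exhaustive ``range`` blocks; sizes differ by
    at most one, larger blocks first."""
    if not 2 <= k <= n_steps:
        raise ValueError(f"need 2 <= k <= n_steps, got k={k}, n_steps={n_steps}")
    base, rem = divmod(n_steps, k)
    sizes = [base + 1] * rem + [base] * (k - rem)
    blocks, start = [], 0
    for s in sizes:
        blocks.append(range(start, start + s))
        start += s
    return blocks


def build_features(raster: SpikeRaster, config: PipelineConfig):
    spec = config.window_spec()
    if config.feature == "wac":
        return wac_feature_matrix(raster, spec, config.levels, config.resolved_selection())
    return count_feature_matrix(raster, spec)


def aligned_targets(kin: KinematicSeries, F, config: PipelineConfig):
    """Kinematic rows matching the feature rows (resampled to the bin grid
    if needed)."""
    kin = resample_kinematics(kin, config.bin_ms)
    bins = F.step_bins()
    if bins[-1] >= kin.n_steps:
        raise ValueError("kinematics shorter than the feature matrix span")
    return kin.data[bins], list(kin.names)


def _augment_velocity(Y: np.ndarray, names: list, step_ms: float):
    """Append first differences for covariates without a velocity column."""
    if any(n.startswith("vel") for n in names):
        return Y, names
    dt = step_ms / 1000.0
    dY = np.gradient(Y, dt, axis=0)
    return np.hstack([Y, dY]), names + [f"d_{n}" for n in names]


def cross_validate(raster: SpikeRaster, kin: KinematicSeries,
                   config: PipelineConfig, label: str = "") -> EvalReport:
    """Blocked k-fold evaluation of one pipeline configuration.

    For each fold the decoder is fitted on the remaining blocks (minus the
    no-peek margin) and run on the held-out block; the per-covariate cc is
    recorded.  Deterministic: same inputs, same report.
    """
    F = build_features(raster, config)
    Y, names = aligned_targets(kin, F, config)
    spec = config.window_spec()
    n = F.n_steps
    margin = math.ceil((spec.span_bins - 1) / spec.slide_bins)
    blocks = kfold_blocks(n, config.folds)
    min_len = margin + 2
    if min(len(b) for b in blocks) < min_len:
        raise ValueError(
            f"folds of {min(len(b) for b in blocks)} rows are shorter than the "
            f"required minimum {min_len} (window span + 2)"
        )

    if config.decoder == "kalman" and config.kalman_add_velocity:
        Z, state_names = _augment_velocity(Y, names, config.slide_ms)
    else:
        Z, state_names = Y, list(names)

    per_fold = np.full((config.folds, len(names)), np.nan)
    for fi, block in enumerate(blocks):
        test = np.asarray(block)
        train = np.ones(n, dtype=bool)
        train[test] = False
        train[test[-1] + 1: test[-1] + 1 + margin] = False  # no-peek margin
        tr = np.flatnonzero(train)
        if config.decoder == "wiener":
            model = fit_wiener(F.values[tr], Y[tr], ridge=config.ridge)
            pred = F.values[test] @ model.weights[:-1] + model.weights[-1]
        else:
            model = fit_kalman(F.values[tr], Z[tr])
            series = kalman_filter(model, F.values[test])
            pred = series.data[:, : len(names)]
        for ci in range(len(names)):
            per_fold[fi, ci] = pearson_cc(pred[:, ci], Y[test, ci])
    return EvalReport(per_fold, list(names), config.fingerprint(),
                      label or (config.preset or f"{config.feature}-{config.decoder}"))


def wilcoxon_signed_rank(differences, alternative: str = "two-sided") -> float:
    """Wilcoxon signed-rank p-value on paired differences.

    Zero differences are dropped (all-zero input returns p = 1 with a
    warning).  For n <= 12 the null distribution of the positive-rank sum
    W+ is computed exactly by enumerating all 2^n sign assignments (average
    ranks for tied magnitudes); larger samples delegate to scipy.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("alternative must be 'two-sided', 'greater' or 'less'")
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    n = d.size
    if n > 12:
        res = scipy.stats.wilcoxon(d, alternative=alternative)
        return float(res.pvalue)
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    signs = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(float)
    w_all = signs @ ranks  # W+ under every sign assignment
    eps = 1e-9
    p_greater = float(np.mean(w_all >= w_obs - eps))
    p_less = float(np.mean(w_all <= w_obs + eps))
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2.0 * min(p_greater, p_less))


def fisher_z_ttest(cc_a, cc_b) -> float:
    """Paired two-sided t-test on Fisher z-transformed cc pairs.

    z = atanh(r) stabilizes the variance of correlation coefficients;
    |r| = 1 is clipped just inside the open interval with a warning.
    """
    a = np.asarray(cc_a, dtype=float)
    b = np.asarray(cc_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 paired correlation values")
    lim = 1.0 - 1e-12
    if (np.abs(a) >= 1).any() or (np.abs(b) >= 1).any():
        warnings.warn("|r| = 1 clipped before the Fisher z-transform", stacklevel=2)
    za, zb = np.arctanh(np.clip(a, -lim, lim)), np.arctanh(np.clip(b, -lim, lim))
    if np.allclose(za, zb):
        return 1.0
    res = scipy.stats.ttest_rel(za, zb)
    return float(res.pvalue)


def compare_reports(a: EvalReport, b: EvalReport, test: str = "wilcoxon"):
    """Paired comparison of two reports over (fold, covariate) cc pairs."""
    ra, rb = a.per_fold_cc.ravel(), b.per_fold_cc.ravel()
    ok = np.isfinite(ra) & np.isfinite(rb)
    if test == "wilcoxon":
        p = wilcoxon_signed_rank(ra[ok] - rb[ok])
    elif test == "fisher_z":
        p = fisher_z_ttest(ra[ok], rb[ok])
    else:
        raise ValueError("test must be 'wilcoxon' or 'fisher_z'")
    entry = (a.label, b.label, test, p)
    a.comparisons.append(entry)
    return entry


def window_size_sweep(raster: SpikeRaster, kin: KinematicSeries,
                      base_config: PipelineConfig, window_sizes_ms) -> pd.DataFrame:
    """Re-run :func:`cross_validate` per window size; tidy long table.

    For WAC configs with the default (auto) selection, the decomposition
    depth is clamped to the deepest feasible level for short windows.
    Results per size are exactly those of an individually-run
    ``cross_validate`` with the same config.
    """
    rows = []
    for w in window_sizes_ms:
        cfg = _sweep_config(base_config, w)
        rep = cross_validate(raster, kin, cfg, label=f"{cfg.feature}-{cfg.decoder}@{w}ms")
        for name, m, s in zip(rep.covariates, rep.mean, rep.sd):
            rows.append({"window_ms": w, "covariate": name,
                         "mean_cc": m, "sd_cc": s})
    return pd.DataFrame(rows)


def _sweep_config(base: PipelineConfig, window_ms: float) -> PipelineConfig:
    kw = {"window_ms": float(window_ms), "preset": None}
    if base.feature == "wac" and base.selection is None:
        window_bins = round(window_ms / base.bin_ms)
        kw["levels"] = min(base.levels, max_levels(window_bins))
    return base.replace(**kw)
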