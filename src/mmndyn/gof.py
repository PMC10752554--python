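"""Subject-level MMN validation and absolute goodness-of-fit.

Two quality gates around the model-comparison pipeline:

* :func:`fit_gaussian_mmn` checks that a subject shows a detectable MMN
  at all, by fitting a constrained Gaussian (negative amplitude, peak in
  100-200 ms) to the deviant-minus-standard difference waveform; a
  zero-amplitude solution means no negative deflection was found and the
  subject is excluded.

* ``R^2_max`` bounds the variance any model could explain: the ratio of
  model-generated variance (scaled to the data by the fitted phi1) to
  observed variance.  Comparing the achieved ``R^2_obs`` to this ceiling
  via the group distribution of log(R^2_obs / R^2_max) tells whether the
  selected model is an adequate generative account (ratio ~ 1) or only a
  partial approximation (ratio < 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["GaussianMMNFit", "AbsoluteFit", "fit_gaussian_mmn", "r2_max", "ratio_test"]

#: amplitudes smaller than this (muV) count as "converged on zero": no MMN.
ZERO_AMPLITUDE_TOL = 1e-3


@dataclass
class GaussianMMNFit:
    """Constrained Gaussian fit of a difference ERP."""

    offset: float          # muV
    amplitude: float       # muV, <= 0 by constraint
    peak_latency: float    # ms, within [100, 200] by constraint
    width: float           # ms
    converged: bool
    excluded: bool         # True when no negative deflection was found
    sse: float = np.nan


@dataclass
class AbsoluteFit:
    """Observed vs. maximal attainable variance explained."""

    r2_obs: float
    r2_max: float

    @property
    def log_ratio(self) -> float:
        return float(np.log(self.r2_obs / self.r2_max))


def _gauss(t, offset, amplitude, peak, width):
    return offset + amplitude * np.exp(-((t - peak) ** 2) / (2.0 * width**2))


def fit_gaussian_mmn(
    diff_erp: np.ndarray,
    times: np.ndarray,
    n_starts: int = 5,
    width_bounds: tuple = (5.0, 100.0),
    peak_bounds: tuple = (100.0, 200.0),
) -> GaussianMMNFit:
    """Fit a negative Gaussian deflection to a difference waveform.

    Bounded nonlinear least squares with multiple starting peak
    latencies spread over the allowed window (the loss surface is
    multimodal for noisy waveforms).  The amplitude is constrained to be
    nonpositive; if the best fit pins it at (numerically) zero the
    waveform holds no detectable MMN and ``excluded`` is set.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(diff_erp, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite waveform")
    if t.min() > peak_bounds[0] or t.max() < peak_bounds[1]:
        raise ValueError("time grid must cover the allowed peak window")

    lo = np.array([-np.inf, -np.inf, peak_bounds[0], width_bounds[0]])
    hi = np.array([np.inf, 0.0, peak_bounds[1], width_bounds[1]])
    amp0 = min(y.min() - y.mean(), 0.0)
    best = None
    for peak0 in np.linspace(peak_bounds[0], peak_bounds[1], n_starts):
        x0 = np.array([float(y.mean()), amp0, peak0, 30.0])
        try:
            res = optimize.least_squares(
                lambda p: _gauss(t, *p) - y, x0, bounds=(lo, hi)
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return GaussianMMNFit(np.nan, np.nan, np.nan, np.nan, False, True)
    offset, amplitude, peak, width = best.x
    excluded = abs(amplitude) < ZERO_AMPLITUDE_TOL
    return GaussianMMNFit(
        offset=float(offset), amplitude=float(amplitude),
        peak_latency=float(peak), width=float(width),
        converged=bool(best.success), excluded=bool(excluded),
        sse=float(2 * best.cost),
    )


def r2_max(g: np.ndarray, y: np.ndarray, phi1: float = 1.0) -> float:
    """Maximum attainable variance fraction for a model at one latency.

    Ratio of the sum of squares of the (phi1-scaled, centered) model
    predictions to the total sum of squares of the centered data.  With
    ``phi1`` the fitted response scale, this is the variance the model
    itself generates on the data scale, as a fraction of observed
    variance.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    ss_model = float(((phi1 * (g - g.mean())) ** 2).sum())
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total == 0:
        raise ValueError("zero data variance")
    if ss_model == 0:
        raise ValueError("constant prediction series: R^2_max undefined")
    return ss_model / ss_total


def ratio_test(log_ratios: np.ndarray):
    """One-sample t-test of the mean log(R^2_obs / R^2_max) against 0.

    The ratios are positively skewed, hence tested on the log scale.
    Returns (estimate, (ci_low, ci_high), t, p) with the estimate and CI
    back-transformed to the ratio scale (an adequate model gives ~ 1).
    """
    x = np.asarray(log_ratios, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 log ratios")
    if x.std(ddof=1) == 0:  # degenerate: identical ratios
        t, p = (0.0, 1.0) if x.mean() == 0 else (np.inf * np.sign(x.mean()), 0.0)
    else:
        t, p = stats.ttest_1samp(x, 0.0)
    se = x.std(ddof=1) / np.sqrt(x.size)
    half = stats.t.ppf(0.975, x.size - 1) * se
    est = float(np.exp(x.mean()))
    ci = (float(np.exp(x.mean() - half)), float(np.exp(x.mean() + half)))
    return est, ci, float(t), float(p)
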