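"""Variational Bayes fitting of one model to one trial series.

Because no evolution parameters are fitted and the initial hidden states
carry zero covariance, each candidate model's prediction series g~ is a
deterministic regressor, and the observation equation

    y_i = phi0 + phi1 * g~_i + eps_i,   eps_i ~ N(0, 1/sigma)

reduces to Bayesian linear regression with a Gaussian prior on
phi = (phi0, phi1) and a Gamma prior on the noise precision sigma.  We
invert it with a mean-field factorization q(phi) q(sigma) iterated by
coordinate ascent; the variational free energy F (the ELBO) is the
approximation of log model evidence used for all model comparison.  Only
evidence *differences* across models matter downstream; F here carries
every additive constant of the standard ELBO so it is also directly
comparable to brute-force marginal-likelihood integration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln

__all__ = [
    "Priors",
    "FitResult",
    "default_priors",
    "mark_outliers",
    "fit_model",
    "fit_all",
]


@dataclass(frozen=True)
class Priors:
    """Priors of the observation model.

    phi_mean is set empirically per subject and latency window:
    phi0 = mean(standards), phi1 = mean(deviants) - mean(standards),
    with a diagonal prior covariance of variance 10 (muV^2).  The noise
    precision has a Gamma(shape 0.1, rate 1) prior, consistent with a
    measurement standard deviation of order 10 muV.
    """

    phi_mean: tuple[float, float]
    phi_variance: float = 10.0
    noise_shape: float = 0.1
    noise_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.phi_variance <= 0 or self.noise_shape <= 0 or self.noise_rate <= 0:
            raise ValueError("prior variance and Gamma parameters must be positive")


@dataclass
class FitResult:
    """Posterior summary of one (subject, model, latency) inversion."""

    phi_mean: np.ndarray          # posterior mean of (phi0, phi1), muV
    phi_cov: np.ndarray           # posterior covariance, 2x2
    noise_shape: float            # Gamma posterior on the noise precision
    noise_rate: float
    free_energy: float            # ELBO approximation of log evidence, nats
    r2_obs: float                 # fraction of variance explained
    n_fitted: int                 # trials that entered the likelihood
    n_iter: int = 0


def default_priors(y: np.ndarray, u: np.ndarray) -> Priors:
    """Empirical prior means from the class means of the fitted trials."""
    y = np.asarray(y, dtype=float)
    u = np.asarray(u)
    std, dev = y[u == 0], y[u == 1]
    if std.size == 0 or dev.size == 0:
        raise ValueError("need at least one standard and one deviant trial")
    m_s, m_d = float(std.mean()), float(dev.mean())
    return Priors(phi_mean=(m_s, m_d - m_s))


def mark_outliers(y: np.ndarray, n_sd: float = 4.0) -> np.ndarray:
    """Flag trials whose amplitude deviates more than ``n_sd`` SD from the mean.

    Flagged trials still drive model evolution but are excluded from the
    likelihood.  A zero-variance series has no outliers.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 trials")
    sd = y.std()
    if sd == 0:
        return np.zeros(y.size, dtype=bool)
    return np.abs(y - y.mean()) > n_sd * sd


def _vb_linear(Sxx, Sxy, yy, n, m0, v0, a0, b0, tol, max_iter):
    """Coordinate-ascent VB for linear regression from sufficient statistics.

    Returns posterior (m, V) for the weights, (a, b) for the noise
    precision, the final free energy and the per-iteration F history.
    The free energy is non-decreasing across iterations by construction.
    """
    d = m0.size
    V0inv = np.eye(d) / v0
    logdetV0 = d * np.log(v0)
    a = a0 + 0.5 * n
    b = b0
    e_prec = a0 / b0
    F_hist = []
    F_prev = -np.inf
    m = m0.copy()
    V = np.eye(d) * v0
    for it in range(max_iter):
        # q(phi) update
        Vinv = V0inv + e_prec * Sxx
        V = np.linalg.inv(Vinv)
        m = V @ (V0inv @ m0 + e_prec * Sxy)
        # E[(y - X phi)^2] under q(phi)
        e_rss = yy - 2.0 * m @ Sxy + np.trace(Sxx @ (V + np.outer(m, m)))
        e_rss = max(e_rss, 0.0)
        # q(sigma) update
        b = b0 + 0.5 * e_rss
        e_prec = a / b
        e_log_prec = digamma(a) - np.log(b)

        e_loglik = -0.5 * n * np.log(2.0 * np.pi) + 0.5 * n * e_log_prec - 0.5 * e_prec * e_rss
        dm = m - m0
        kl_phi = 0.5 * (
            np.trace(V0inv @ V)
            + dm @ V0inv @ dm
            - d
            + logdetV0
            - np.linalg.slogdet(V)[1]
        )
        kl_prec = (
            (a - a0) * digamma(a)
            - gammaln(a)
            + gammaln(a0)
            + a0 * (np.log(b) - np.log(b0))
            + a * (b0 - b) / b
        )
        F = float(e_loglik - kl_phi - kl_prec)
        F_hist.append(F)
        if F < F_prev - 1e-9:
            raise RuntimeError("free energy decreased during VB iteration")
        if F - F_prev < tol:
            break
        F_prev = F
    return m, V, a, b, F_hist[-1], F_hist


def fit_model(
    y: np.ndarray,
    g: np.ndarray,
    fit_mask: np.ndarray | None = None,
    priors: Priors | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> FitResult:
    """Fit the observation model y = phi0 + phi1*g~ + eps on the masked trials.

    Parameters
    ----------
    y : array
        Trial amplitudes (muV) for one latency window.
    g : array
        Normalized model predictions, same length as ``y`` (the null
        model passes an all-zero series; its phi1 then stays at the
        prior and contributes nothing to the evidence).
    fit_mask : bool array, optional
        Trials entering the likelihood (inclusion, artifact and outlier
        masks combined).  Default: all trials.
    priors : Priors, optional
        Default: empirical class-mean priors computed from the masked
        trials (requires a code vector implied by g — pass explicit
        priors when g is not 0/1-like).
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if y.shape != g.shape:
        raise ValueError("y and g must have the same length")
    if fit_mask is None:
        fit_mask = np.ones(y.size, dtype=bool)
    else:
        fit_mask = np.asarray(fit_mask, dtype=bool)
    yf, gf = y[fit_mask], g[fit_mask]
    if yf.size < 2:
        raise ValueError("need at least 2 fitted trials")
    if not (np.isfinite(yf).all() and np.isfinite(gf).all()):
        raise ValueError("non-finite amplitudes or predictions")
    if priors is None:
        raise ValueError("priors must be provided (see default_priors)")

    X = np.column_stack([np.ones(yf.size), gf])
    Sxx = X.T @ X
    Sxy = X.T @ yf
    yy = float(yf @ yf)
    m0 = np.asarray(priors.phi_mean, dtype=float)
    m, V, a, b, F, _ = _vb_linear(
        Sxx, Sxy, yy, yf.size, m0, priors.phi_variance,
        priors.noise_shape, priors.noise_rate, tol, max_iter,
    )
    resid = yf - X @ m
    sstot = float(((yf - yf.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / sstot if sstot > 0 else np.nan
    return FitResult(
        phi_mean=m, phi_cov=V, noise_shape=float(a), noise_rate=float(b),
        free_energy=F, r2_obs=r2, n_fitted=int(yf.size),
    )


def fit_all(table, specs, windows=None, tol: float = 1e-6, max_iter: int = 200):
    """Fit every model to every subject and latency window of a trial table.

    Priors and the 4-SD outlier mask are recomputed per subject and
    window; each model is calibrated on the subject's own sequence.
    Returns a tidy DataFrame (subject, model, family, tau, window, F,
    r2_obs, phi0, phi1, n_fitted) — the evidence table consumed by the
    group-inference stage.
    """
    import pandas as pd

    from .models import calibrate_lambda, predict_series

    if windows is None:
        windows = table.window_labels
    rows = []
    for subject in table.subjects():
        seq = table.sequence(subject)
        calibrated = [calibrate_lambda(s, seq) for s in specs]
        series = {s.name: predict_series(s, seq) for s in calibrated}
        for w in windows:
            y = table.amplitudes(subject, w)
            mask = seq.fit_mask & ~mark_outliers(y)
            priors = default_priors(y[mask], seq.codes[mask])
            for spec in calibrated:
                fr = fit_model(y, series[spec.name], mask, priors, tol, max_iter)
                rows.append(
                    dict(
                        subject=subject, model=spec.name, family=spec.family,
                        tau=spec.tau, window=w, F=fr.free_energy,
                        r2_obs=fr.r2_obs, phi0=fr.phi_mean[0],
                        phi1=fr.phi_mean[1], n_fitted=fr.n_fitted,
                    )
                )
    return pd.DataFrame(rows)
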