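"""Fixed-effect group Bayesian model comparison and averaging.

Under the fixed-effect (homogeneous population) assumption, the group
log evidence of a model is the sum of per-subject log evidences; the
posterior model probability (PMP) under a uniform model prior is the
softmax of group log evidences.  Families of models sharing a mechanism
but differing in their time constant tau are compared by summing member
PMPs, the Bayes factor of one model (or family) against all others is
posterior odds times (K-1), and the family's tau is estimated by
Bayesian model averaging: a PMP-weighted mean over the tau grid.

The SNR utilities implement the single-trial definition
SNR = 1 + mu^2/sigma^2 with mu the deviant-minus-standard mean amplitude
and sigma^2 the pooled intertrial variance; thresholded subsetting and
the log-BF ~ SNR regression operate on the *excess* SNR scale
(mu^2/sigma^2), the scale on which thresholds like 0.008 live.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "SNRRecord",
    "group_log_evidence",
    "posterior_model_probability",
    "family_pmp",
    "bayes_factor_vs_all",
    "kass_raftery_label",
    "bma_tau",
    "compute_snr",
    "family_bmc",
    "subset_by_snr",
    "bf_snr_association",
]


@dataclass(frozen=True)
class SNRRecord:
    """Per-subject single-trial signal-to-noise summary."""

    mu: float       # deviant - standard mean amplitude, muV
    sigma2: float   # pooled intertrial variance, muV^2

    @property
    def snr(self) -> float:
        return 1.0 + self.mu**2 / self.sigma2

    @property
    def excess_snr(self) -> float:
        return self.mu**2 / self.sigma2


def group_log_evidence(evidence: pd.DataFrame, subjects=None) -> pd.DataFrame:
    """Sum per-subject log evidences per model and window (ffx pooling).

    ``evidence`` is the tidy table from :func:`mmndyn.inversion.fit_all`
    (columns subject, model, family, tau, window, F).
    """
    if subjects is not None:
        subjects = list(subjects)
        if not subjects:
            raise ValueError("subject subset must be nonempty")
        evidence = evidence[evidence["subject"].isin(subjects)]
        if evidence.empty:
            raise ValueError("no evidence rows for the requested subjects")
    out = (
        evidence.groupby(["model", "family", "tau", "window"], dropna=False)["F"]
        .sum()
        .reset_index()
        .rename(columns={"F": "log_evidence"})
    )
    return out


def posterior_model_probability(log_evidence: np.ndarray) -> np.ndarray:
    """Softmax of log evidences under a uniform model prior (stable)."""
    le = np.asarray(log_evidence, dtype=float)
    if le.size < 2:
        raise ValueError("need at least 2 models")
    if np.all(np.isneginf(le)):
        raise ValueError("all log evidences are -inf")
    return np.exp(le - logsumexp(le))


def family_pmp(pmp: np.ndarray, families: np.ndarray) -> pd.Series:
    """Aggregate model PMPs into family probabilities (sum of members)."""
    pmp = np.asarray(pmp, dtype=float)
    families = np.asarray(families)
    if pmp.shape != families.shape:
        raise ValueError("pmp and family labels must align")
    return pd.Series(pmp).groupby(families).sum()


def bayes_factor_vs_all(pmp_j: float, K: int) -> float:
    """Bayes factor of one model against all others: posterior odds x (K-1)."""
    if K < 2:
        raise ValueError("need K >= 2 models")
    if pmp_j <= 0.0 or pmp_j >= 1.0:
        warnings.warn("degenerate PMP; Bayes factor is infinite", RuntimeWarning)
        return np.inf if pmp_j >= 1.0 else 0.0
    return pmp_j / (1.0 - pmp_j) * (K - 1)


def kass_raftery_label(bf: float) -> str:
    """Conventional evidence bands: [3,10) substantial, [10,100) strong, >=100 decisive."""
    if bf < 0:
        raise ValueError("Bayes factor must be >= 0")
    if bf < 3:
        return "inconclusive"
    if bf < 10:
        return "substantial"
    if bf < 100:
        return "strong"
    return "decisive"


def bma_tau(weights: np.ndarray, taus: np.ndarray, soa: float | None = None) -> float:
    """Model-averaged time constant: normalized PMP-weighted mean of the tau grid.

    ``soa`` (stimulus-onset asynchrony, seconds per stimulus) converts
    the estimate from stimulus units to seconds.
    """
    w = np.asarray(weights, dtype=float)
    t = np.asarray(taus, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    est = float((w * t).sum() / total)
    return est * soa if soa is not None else est


def compute_snr(y: np.ndarray, u: np.ndarray) -> SNRRecord:
    """Single-trial SNR from one subject's amplitudes and stimulus codes."""
    y = np.asarray(y, dtype=float)
    u = np.asarray(u)
    std, dev = y[u == 0], y[u == 1]
    if std.size < 2 or dev.size < 2:
        raise ValueError("need at least 2 trials in each class")
    mu = float(dev.mean() - std.mean())
    sigma2 = float(
        ((std.size - 1) * std.var(ddof=1) + (dev.size - 1) * dev.var(ddof=1))
        / (std.size + dev.size - 2)
    )
    if sigma2 == 0:
        raise ValueError("zero intertrial variance")
    return SNRRecord(mu=mu, sigma2=sigma2)


def family_bmc(evidence: pd.DataFrame, subjects=None, family_map=None) -> pd.DataFrame:
    """Family-level ffx-BMC per latency window.

    Returns one row per (window, family): family PMP, Bayes factor
    against all other families, its evidence label, the BMA estimate of
    tau within the family (NaN for the static controls) and the number
    of subjects pooled.  ``family_map`` optionally relabels model
    families into comparison families (e.g. {"null": "ctrl", "dd":
    "ctrl"} to pool the static controls).
    """
    gle = group_log_evidence(evidence, subjects)
    if family_map:
        gle = gle.assign(
            family=gle["family"].map(lambda f: family_map.get(f, f))
        )
    n_subj = evidence["subject"].nunique() if subjects is None else len(set(subjects))
    rows = []
    for window, grp in gle.groupby("window"):
        pmp = posterior_model_probability(grp["log_evidence"].to_numpy())
        fam = family_pmp(pmp, grp["family"].to_numpy())
        K = fam.size
        for name, p in fam.items():
            members = grp["family"].to_numpy() == name
            taus = grp["tau"].to_numpy()[members]
            w = pmp[members]
            tau_hat = (
                bma_tau(w, taus)
                if np.isfinite(taus.astype(float)).all() and w.sum() > 0
                else np.nan
            )
            bf = bayes_factor_vs_all(min(max(p, 1e-300), 1 - 1e-16), K) if K > 1 else np.nan
            rows.append(
                dict(
                    window=window, family=name, pmp=p, bf=bf,
                    label=kass_raftery_label(bf) if np.isfinite(bf) else "decisive",
                    bma_tau=tau_hat, n_subjects=n_subj,
                )
            )
    return pd.DataFrame(rows)


def subset_by_snr(
    evidence: pd.DataFrame,
    snr_by_subject_window: pd.DataFrame,
    threshold: float,
) -> pd.DataFrame:
    """Re-run family BMC on latency-specific high-SNR subject subsets.

    ``snr_by_subject_window`` has columns (subject, window, excess_snr);
    per window, subjects with excess SNR strictly above ``threshold``
    are retained.  Windows whose subset is empty are flagged
    (``flagged=True``) and carry no inference.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0 on the excess-SNR scale")
    out = []
    n_total = evidence["subject"].nunique()
    for window in sorted(evidence["window"].unique()):
        sel = snr_by_subject_window[
            (snr_by_subject_window["window"] == window)
            & (snr_by_subject_window["excess_snr"] > threshold)
        ]["subject"].tolist()
        ev_w = evidence[evidence["window"] == window]
        if not sel:
            out.append(
                pd.DataFrame(
                    [dict(window=window, family=None, pmp=np.nan, bf=np.nan,
                          label=None, bma_tau=np.nan, n_subjects=0,
                          retained_fraction=0.0, flagged=True)]
                )
            )
            continue
        res = family_bmc(ev_w, subjects=sel)
        res["retained_fraction"] = len(sel) / n_total
        res["flagged"] = False
        out.append(res)
    return pd.concat(out, ignore_index=True)


def bf_snr_association(log_bf: np.ndarray, snr: np.ndarray):
    """OLS of per-subject log Bayes factor on (excess) SNR.

    Returns (slope, intercept, r_squared, snr_at_zero) where the last is
    the SNR at which the fitted line predicts log BF = 0.
    """
    x = np.asarray(snr, dtype=float)
    y = np.asarray(log_bf, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 subjects")
    if x.std() == 0:
        raise ValueError("degenerate SNR variance")
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    sst = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ((y - pred) ** 2).sum() / sst if sst > 0 else 1.0
    snr0 = -intercept / slope if slope != 0 else np.nan
    return float(slope), float(intercept), float(r2), float(snr0)
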