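"""Deterministic generative models of single-trial mismatch responses.

Each candidate model maps an oddball input sequence u_1..u_n (0 = standard,
1 = deviant) to a deterministic per-trial prediction through a hidden-state
*evolution* function f and an *observation* function g:

    x_{i+1} = f(x_i, u_i)          (no fitted evolution parameters)
    g_i     = g(x_i, u_i)          (raw, model-specific scale)

Five families are implemented:

``null``
    g = 0; no response modulation at all.
``dd``
    Deviant detection, g = u; an MMN without any stimulus-history memory.
``ssa``
    Stimulus-specific adaptation.  Two responsiveness states in (0, 1],
    one per tone-tuned neuronal population, decay exponentially
    (rate K_a = exp(-1/tau_a)) when their tone is played and recover
    exponentially toward 1 (rate K_r = exp(-1/tau_r), tau_r = 2*tau_a)
    otherwise.  The observed response is the responsiveness of the
    population tuned to the current tone.
``bl_surp`` / ``bl_pwpe`` / ``bl_madj``
    Bayesian learning of the deviant probability mu ~ Beta(alpha, beta),
    with pseudo-counts leaking through a forgetting constant
    K_t = exp(-1/tau_t).  The three read-outs are Shannon surprise
    -ln p(u|prior), the precision-weighted prediction error
    (u - E[mu]) / var[mu], and the model adjustment
    KL(prior belief || posterior belief) in closed form.

A per-model affine normalization lambda = (lambda0, lambda1) rescales the
raw observation so its mean is 0 over standards and 1 over deviants of a
calibration sequence; the fitted offset/scale parameters (phi0, phi1) of
the observation equation then share one interpretation across models:
mean standard response and mean deviant-minus-standard difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import betaln, digamma

from .sequences import InputSequence

__all__ = [
    "FAMILIES",
    "SSA_TAU_GRID",
    "BL_TAU_GRID",
    "ModelSpec",
    "ssa_evolve",
    "bl_evolve",
    "beta_kl",
    "observe_raw",
    "raw_series",
    "calibrate_lambda",
    "predict_series",
    "default_model_grid",
]

FAMILIES = ("null", "dd", "ssa", "bl_surp", "bl_pwpe", "bl_madj")
BL_FAMILIES = ("bl_surp", "bl_pwpe", "bl_madj")

#: Adaptation time constants (stimulus units); recovery is always 2x slower.
SSA_TAU_GRID = (3, 10, 20, 30, 50, 100, 200)
#: Temporal-integration (forgetting) constants of the Bayesian learner.
BL_TAU_GRID = (5, 10, 20, 30, 50, 100)


@dataclass(frozen=True)
class ModelSpec:
    """A fully specified candidate model.

    ``tau`` is the fixed time constant in stimulus units (adaptation
    constant for ``ssa``, forgetting constant for the ``bl_*`` families;
    ``None`` for the static ``null``/``dd`` controls).  ``lambda0`` and
    ``lambda1`` are the normalization offset and scale; they are set by
    :func:`calibrate_lambda`, not fitted.
    """

    family: str
    tau: float | None = None
    lambda0: float | None = None
    lambda1: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in ("null", "dd"):
            if self.tau is not None:
                raise ValueError(f"{self.family} model takes no time constant")
        elif self.tau is None or self.tau <= 0:
            raise ValueError(f"{self.family} model needs tau > 0")

    @property
    def name(self) -> str:
        return self.family if self.tau is None else f"{self.family}{self.tau:g}"

    @property
    def is_calibrated(self) -> bool:
        return self.family == "null" or self.lambda0 is not None

    @property
    def is_dynamic(self) -> bool:
        return self.family not in ("null", "dd")


def _decay(tau: float) -> float:
    return math.exp(-1.0 / tau)


def ssa_evolve(state: tuple[float, float], u: int, tau_a: float) -> tuple[float, float]:
    """One adaptation/recovery step of the two responsiveness states.

    The population tuned to the presented tone adapts (multiplicative
    exponential decay with K_a = exp(-1/tau_a)); the other population
    recovers toward full responsiveness 1 with K_r = exp(-1/(2*tau_a)).
    """
    if tau_a <= 0:
        raise ValueError("tau_a must be > 0")
    ka = _decay(tau_a)
    kr = _decay(2.0 * tau_a)
    x0, x1 = state
    if u == 0:
        return x0 * ka, 1.0 - (1.0 - x1) * kr
    return 1.0 - (1.0 - x0) * kr, x1 * ka


def bl_evolve(state: tuple[float, float], u: int, tau_t: float) -> tuple[float, float]:
    """Leaky Beta pseudo-count update: alpha <- u + alpha*K_t, beta <- (1-u) + beta*K_t."""
    if tau_t <= 0:
        raise ValueError("tau_t must be > 0")
    kt = _decay(tau_t)
    alpha, beta = state
    if alpha <= 0 or beta <= 0:
        raise ValueError("Beta pseudo-counts must be positive")
    return u + alpha * kt, (1 - u) + beta * kt


def beta_kl(prior: tuple[float, float], posterior: tuple[float, float]) -> float:
    """KL divergence KL(Beta(prior) || Beta(posterior)), closed form.

    Evaluated with log-Beta and digamma functions so that large
    pseudo-counts (slow forgetting) never overflow Gamma ratios.
    """
    a1, b1 = prior
    a2, b2 = posterior
    if min(a1, b1, a2, b2) <= 0:
        raise ValueError("Beta parameters must be positive")
    return float(
        betaln(a2, b2)
        - betaln(a1, b1)
        + (a1 - a2) * digamma(a1)
        + (b1 - b2) * digamma(b1)
        + (a2 - a1 + b2 - b1) * digamma(a1 + b1)
    )


def observe_raw(spec: ModelSpec, state, u: int, post_state=None) -> float:
    """Raw (un-normalized) observation of one trial.

    ``state`` is the hidden state *before* the current input is absorbed;
    ``bl_madj`` additionally needs ``post_state``, the state after the
    update, to quantify the belief shift the input caused.
    """
    fam = spec.family
    if fam == "null":
        return 0.0
    if fam == "dd":
        return float(u)
    if state is None or not np.all(np.isfinite(state)):
        raise ValueError("non-finite hidden state")
    if fam == "ssa":
        return float(state[1] if u == 1 else state[0])
    alpha, beta = state
    if fam == "bl_surp":
        p = alpha / (alpha + beta) if u == 1 else beta / (alpha + beta)
        return -math.log(p)
    if fam == "bl_pwpe":
        s = alpha + beta
        mean = alpha / s
        var = alpha * beta / (s * s * (s + 1.0))
        return (u - mean) / var
    # bl_madj
    if post_state is None:
        raise ValueError("bl_madj observation needs the post-update state")
    return beta_kl((alpha, beta), tuple(post_state))


def raw_series(spec: ModelSpec, sequence: InputSequence) -> np.ndarray:
    """Run the evolution over the whole sequence and emit raw observations.

    All trials drive the evolution, including rejected and non-included
    ones (the stimulus stream is continuous regardless of which trials are
    later allowed into a likelihood).  Hidden states restart at their
    initial values at every session boundary.
    """
    codes = sequence.codes
    out = np.zeros(codes.size, dtype=float)
    fam = spec.family
    if fam == "null":
        return out
    if fam == "dd":
        return codes.astype(float)

    for _, idx in sequence.sessions():
        state = (1.0, 1.0)  # full responsiveness / flat Beta(1,1) belief
        if fam == "ssa":
            for i in idx:
                u = int(codes[i])
                out[i] = observe_raw(spec, state, u)
                state = ssa_evolve(state, u, spec.tau)
        else:
            for i in idx:
                u = int(codes[i])
                new_state = bl_evolve(state, u, spec.tau)
                if fam == "bl_madj":
                    out[i] = observe_raw(spec, state, u, post_state=new_state)
                else:
                    out[i] = observe_raw(spec, state, u)
                state = new_state
    return out


def calibrate_lambda(spec: ModelSpec, sequence: InputSequence) -> ModelSpec:
    """Set the normalization pair so g~ has mean 0 on standards, 1 on deviants.

    Means are taken over the *included* trials of the calibration
    sequence.  The null model normalizes to the all-zero series.
    """
    if spec.family == "null":
        return replace(spec, lambda0=0.0, lambda1=0.0)
    raw = raw_series(spec, sequence)
    keep = sequence.included
    std = raw[keep & (sequence.codes == 0)]
    dev = raw[keep & (sequence.codes == 1)]
    if std.size == 0 or dev.size == 0:
        raise ValueError("calibration sequence needs both standards and deviants")
    m_s, m_d = float(std.mean()), float(dev.mean())
    if m_d == m_s:
        raise ValueError(f"degenerate normalization for {spec.name}: equal class means")
    lam1 = 1.0 / (m_d - m_s)
    return replace(spec, lambda0=-m_s * lam1, lambda1=lam1)


def predict_series(spec: ModelSpec, sequence: InputSequence) -> np.ndarray:
    """Normalized prediction series g~_i = lambda0 + lambda1 * g_i, one per trial."""
    if not spec.is_calibrated:
        raise ValueError(f"model {spec.name} is not calibrated; call calibrate_lambda first")
    if spec.family == "null":
        return np.zeros(len(sequence))
    return spec.lambda0 + spec.lambda1 * raw_series(spec, sequence)


def separability_correlations(
    sequences, tau_ssa: float = 10, tau_bl: float = 20
) -> dict:
    """Pairwise prediction correlations of the recovery candidate models.

    For each sequence, computes the Pearson correlations between the
    normalized prediction series of SSA(tau_ssa) and each of the three
    Bayesian-learning outputs at tau_bl, plus all BL-BL pairs; averages
    over sequences.  Returns the summary statistics that characterize
    how hard the candidate set is to tell apart under a given design:
    ``ssa_bl`` (mean SSA-BL correlation over the three outputs),
    ``bl_pairwise`` (mean of the three BL-BL correlations) and
    ``surp_pwpe`` (the single most-correlated pair).
    """
    ssa_bl, bl_pairs, sp = [], [], []
    bl_fams = list(BL_FAMILIES)
    for seq in sequences:
        g_ssa = predict_series(calibrate_lambda(ModelSpec("ssa", tau_ssa), seq), seq)
        g_bl = {
            f: predict_series(calibrate_lambda(ModelSpec(f, tau_bl), seq), seq)
            for f in bl_fams
        }
        ssa_bl.append(np.mean([np.corrcoef(g_ssa, g_bl[f])[0, 1] for f in bl_fams]))
        pair_r = [
            np.corrcoef(g_bl[a], g_bl[b])[0, 1]
            for i, a in enumerate(bl_fams)
            for b in bl_fams[i + 1 :]
        ]
        bl_pairs.append(np.mean(pair_r))
        sp.append(np.corrcoef(g_bl["bl_surp"], g_bl["bl_pwpe"])[0, 1])
    return {
        "ssa_bl": float(np.mean(ssa_bl)),
        "bl_pairwise": float(np.mean(bl_pairs)),
        "surp_pwpe": float(np.mean(sp)),
        "n_sequences": len(ssa_bl),
    }


def default_model_grid() -> list[ModelSpec]:
    """The 27-model candidate space: null, dd, 7 ssa and 3x6 bl models."""
    grid = [ModelSpec("null"), ModelSpec("dd")]
    grid += [ModelSpec("ssa", tau) for tau in SSA_TAU_GRID]
    for fam in BL_FAMILIES:
        grid += [ModelSpec(fam, tau) for tau in BL_TAU_GRID]
    return grid
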