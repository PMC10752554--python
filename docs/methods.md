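# Methods

This note documents the models, the numerical procedures and the design
choices behind `mmndyn`, and states precisely what the synthetic-data
generator does and does not emulate.

## Observation framework

All candidate models share one observation equation per latency window:

    y_i = φ₀ + φ₁ · g̃_i + ε_i,    ε_i ~ N(0, σ⁻¹),

where y_i is the window- and ROI-averaged EEG amplitude (μV) of trial i
and g̃_i the model's normalized prediction. The normalization pair
λ = (λ₀, λ₁) is estimated per subject from the model's own noise-free
prediction series over the *included* trials — λ₁ = 1/(m_d − m_s),
λ₀ = −m_s·λ₁ with m_s, m_d the raw class means — so that g̃ averages 0
on standards and 1 on deviants of the calibration sequence. φ₀ is then
interpretable as the mean standard response and φ₁ as the mean
deviant−standard difference for every model, which makes evidence
comparable across models. λ is not a fitted parameter. (Whether the
original analysis calibrated per subject or once per design is not
documented; both normalize identically on the calibration set, and the
per-subject choice keeps the interpretation exact for each subject.)

The null model has no regressor; it is fitted through the same code
path with an all-zero prediction series, which leaves the φ₁ posterior
at its prior and contributes exactly zero to the evidence — identical
to an intercept-only model.

## Evolution functions

**Adaptation (ssa).** Responsiveness states (x₀, x₁) start at (1, 1) —
no adaptation before the first tone. The population tuned to the
presented tone decays multiplicatively with K_a = e^(−1/τ_a); the other
recovers toward 1 with K_r = e^(−1/τ_r). τ_r = 2τ_a throughout,
following the electrophysiological observation that recovery is about
twice as slow as adaptation. States provably remain in (0, 1].

**Bayesian learning (bl_*).** Pseudo-counts (α, β) start at (1, 1) (a
flat Beta prior; also required because the KL read-out is undefined at
zero). Each trial: α ← u + αK_t, β ← (1−u) + βK_t. Counts stay
positive and are asymptotically bounded by 1/(1−K_t). The three
read-outs use the pre-update (prior) state; the model-adjustment
read-out also uses the post-update state and is evaluated with the
closed-form Beta KL divergence written in log-Beta/digamma form — no
Gamma ratios, so large pseudo-counts (slow forgetting) cannot overflow.
The closed form is verified against numerical quadrature of the
divergence integral to 1e−8 over a parameter lattice in [0.5, 50]².

Evolution runs over *every* trial of the continuous stimulus stream —
rejected trials, outliers and non-included conditions drive the
dynamics but never the likelihood. Hidden states re-initialize at
session boundaries only (sessions are hours apart).

## Variational inversion

With deterministic regressors and zero-covariance initial states, each
fit is Bayesian linear regression: Gaussian prior on (φ₀, φ₁) with
empirical means (mean of standards; deviant−standard difference) and
variance 10 μV², Gamma(0.1, 1) prior on the noise precision
(consistent with ~10 μV measurement noise). We use a mean-field
q(φ)q(σ) factorization with coordinate-ascent updates from sufficient
statistics; the free energy (ELBO) is computed with all additive
constants and is asserted non-decreasing at every iteration.
Convergence: ΔF < 1e−6 nats or 200 iterations (conservative for a
conjugate-like problem). On n=20 problems the ELBO sits within 0.05
nats of the exact log marginal likelihood obtained by integrating the
weights analytically and the precision by quadrature; only evidence
*differences* matter downstream, but the constants are kept so this
comparison is direct. Outliers (|y − mean| > 4 SD) are masked per
latency window, since amplitude scales differ across windows.

R²_obs = 1 − SS_res/SS_tot over fitted trials, with residuals at the
posterior-mean parameters ("percentage of variance explained"
semantics).

## Group inference

Fixed-effect BMC: per-model group log evidence is the sum over
subjects; posterior model probabilities are a max-stabilized softmax
under a uniform prior over the 27 models; family probabilities sum
member PMPs (equivalent to log-sum-exp of member evidences up to a
shared constant — the aggregation rule is not printed in the source
analysis, this is the standard choice). The Bayes factor of a model or
family against all others is posterior odds × (K−1), labeled by the
conventional 3/10/100 bands with half-open intervals [3,10), [10,100),
[100,∞) — a BF of exactly 10 is "strong".

The τ estimate within a family is the PMP-weighted mean of the τ grid,
normalized by the total family PMP. The printed form of the averaging
formula divides by the grid size |T| instead, which would not return τ
for a degenerate single-model posterior; we implement the normalized
weighted mean and note the discrepancy rather than assuming it was the
behavior of the original code. Reported in stimulus units; multiply by
the stimulus-onset asynchrony (≈1.06 s for design 1, 0.58 s for
design 2) for seconds.

**SNR.** snr = 1 + μ²/σ² with μ the deviant−standard mean difference
and σ² the pooled within-class intertrial variance. Thresholds
(0.001, 0.008, 0.024) apply to the *excess* SNR μ²/σ², the only scale
on which such magnitudes are meaningful. Whether the original μ was the
class difference or a grand mean is not documented; the class
difference is used because the recovery grid scales exactly that
quantity. SNR-thresholded inference keeps, per latency, subjects with
excess SNR strictly above threshold and reruns the family BMC; empty
subsets flag the latency instead of emitting inference.

## Model recovery

Candidates default to SSA(τ_a=10) + the three BL outputs at τ_t=20 —
the most mutually correlated single-τ representatives, making recovery
conservative; the static controls can be added. Per (amplitude, noise)
cell and true model, each subject's own sequence is simulated 5 times;
every candidate is refitted to every realization; 1000 bootstrap
samples (200 in the scaled-down test configuration) draw one
realization per subject, sum log evidences, and record the arg-max-PMP
winner (ties, which effectively never occur with continuous evidence,
break to the lowest candidate index). Confusion matrices are summarized
by TPR (diagonal), PPV (column-normalized diagonal, undefined for a
never-selected model), and L1 distances to the identity and uniform
(1/K) matrices. Time-resolved recovery maps each subject to the grid
cell nearest their observed (amplitude, noise) in log-log Euclidean
distance.

## Synthetic data

The generator states the two study designs:

* **study1**: one session, 750 stimuli, 150 deviants (20%).
* **study2**: two sessions, each a continuous stream of 1680 stimuli —
  three blocks of eight alternating 70-stimulus periods with exactly 14
  deviants each — of which the four "safe" periods of the middle
  (control) block are flagged included: 280 modeled stimuli (56
  deviants) per session, 560/112 per participant. The full stream
  drives evolution; only included trials enter likelihoods. Emulating
  the full stream matters: with a truncated 560-stimulus stream the
  initialization transient inflates model differences and the
  separability correlations drop by ~0.05.

Standard-run lengths are drawn uniformly from {2..8} (the run-length
law of the original designs is unreported; this honors "variable-length
standard runs, no consecutive deviants" and is seedable), runs trimmed
or the tail padded to hit the exact deviant count. Simulated amplitudes
are y = baseline + amplitude·g̃ + N(0, noise²); baseline defaults to
0 μV since only the difference response drives model discrimination.
The default recovery grid crosses 6 amplitudes (0.25–4.5 μV) with 5
noise SDs (6.4–15.6 μV): 30 pairs, log-spaced, spanning excess SNR
~5·10⁻⁴–0.5 — covering the thresholds above which inference becomes
reliable (~0.02–0.03) from both sides. The exact grid values of the
original analysis are unprinted; the grid is configurable.

What the generator does **not** emulate: continuous-time EEG (channels,
filtering, epoching — the package consumes window/ROI-averaged
amplitudes), ISI/temporal-jitter effects (models are trial-indexed),
non-Gaussian or temporally correlated trial noise, latency-varying
effect topographies (the cohort simulator applies one effect at all
windows), and between-subject heterogeneity of the generative
mechanism. A green recovery or calibration test therefore establishes
correctness of the pipeline under the stated noise model, not
robustness to real-EEG artifacts.

## MMN screening and absolute fit

Subject screening fits offset + amplitude·exp(−(t−peak)²/(2w²)) to the
difference waveform by bounded least squares with 5 starting peaks
spread over the allowed window, amplitude ≤ 0, peak ∈ [100, 200] ms,
width ∈ [5, 100] ms (width bounds chosen for stability). A fitted
|amplitude| < 1e−3 μV counts as the optimizer converging on zero — no
detectable MMN, subject excluded; the exact zero-tolerance is ours.

R²_max = SS of the φ₁-scaled centered predictions over SS of the
centered data: the ceiling a model could explain had it generated the
data. Adequacy is judged by the group distribution of
log(R²_obs/R²_max) (log for normality; two-sided one-sample t-test
against 0 with back-transformed estimate and 95% CI). Under the true
model the CI covers 1; under a mismatched model the ratio falls below 1
— by only ~2% when the mismatched model correlates with the truth at
0.93, so the ratio test is a coarse adequacy check, not a model
selector.

## Scaling choices in the test suite

The acceptance tests run the recovery checks with n_boot = 200 instead
of 1000 and a 28-subject cohort (the smaller study's final sample), and
assert "near-identity" at the highest-SNR cell as every diagonal entry
≥ 0.95 with mean ≥ 0.97 — at 200 bootstraps a residual 2–3% confusion
between the surprise and prediction-error outputs (prediction
correlation > 0.99) is expected and does not indicate a defect.
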