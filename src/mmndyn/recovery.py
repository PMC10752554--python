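"""Simulation-based model recovery (confusion analysis).

Can the fixed-effect model-comparison pipeline identify the true
generative mechanism under a given design, sample size and SNR?  For
each candidate model we simulate noisy trial series for every subject's
own input sequence at a chosen (amplitude, noise) cell, refit all
candidates, and repeat group-level BMC over bootstrap samples that draw
one noise realization per subject.  Selection frequencies fill a
row-stochastic confusion matrix A whose rows index the generating model
and columns the selected one; A is summarized by per-model sensitivity
(TPR, the diagonal), specificity (PPV, column-normalized diagonal), and
L1 distances to the identity matrix (perfect recovery) and to the
uniform matrix with entries 1/K (random selection).  Low SNR drives A
away from identity while staying far from uniform (bias); low sample
size drives it toward uniform (randomness).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inversion import default_priors, fit_model
from .models import ModelSpec, calibrate_lambda, predict_series
from .sequences import InputSequence
from .simulate import SimulationGrid, simulate_responses

__all__ = [
    "ConfusionMatrix",
    "RecoverySummary",
    "default_recovery_candidates",
    "run_recovery",
    "confusion_metrics",
    "sample_size_curve",
    "time_resolved_recovery",
]


@dataclass
class ConfusionMatrix:
    """Row-stochastic selection-frequency matrix from bootstrap recovery."""

    entries: np.ndarray              # (K, K); rows: true model, cols: selected
    labels: list
    cell: tuple | None = None        # (amplitude, noise) grid cell
    n_boot: int = 0

    def __post_init__(self) -> None:
        A = np.asarray(self.entries, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("confusion matrix must be square")
        if not np.allclose(A.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("confusion-matrix rows must sum to 1")
        self.entries = A


@dataclass
class RecoverySummary:
    """Per-model TPR/PPV and matrix-distance summaries of a confusion matrix."""

    tpr: np.ndarray
    ppv: np.ndarray          # NaN where a model was never selected
    dist_identity: float     # L1 distance to the identity matrix
    dist_uniform: float      # L1 distance to the all-1/K matrix
    labels: list = field(default_factory=list)


def default_recovery_candidates() -> list[ModelSpec]:
    """The restricted simulation space: SSA(tau_a=10) + the three BL(tau_t=20).

    tau_t = 20 makes the three Bayesian-learning outputs maximally
    correlated (conservative for separability) and tau_a = 10 maximizes
    the SSA-BL correlation.
    """
    return [
        ModelSpec("ssa", 10),
        ModelSpec("bl_surp", 20),
        ModelSpec("bl_pwpe", 20),
        ModelSpec("bl_madj", 20),
    ]


def _evidence_cube(candidates, sequences, amplitude, noise, n_real, rng,
                   tol=1e-6, max_iter=200):
    """Per-subject log evidences for all (true model, realization, candidate).

    Returns an array of shape (n_subjects, K_true, n_real, K_cand).
    """
    K = len(candidates)
    N = len(sequences)
    out = np.empty((N, K, n_real, K))
    for s, seq in enumerate(sequences):
        cal = [calibrate_lambda(c, seq) for c in candidates]
        series = [predict_series(c, seq) for c in cal]
        mask = seq.fit_mask
        for i_true in range(K):
            y_all = (
                amplitude * series[i_true][:, None]
                + rng.normal(0.0, noise, size=(len(seq), n_real))
            )
            for r in range(n_real):
                y = y_all[:, r]
                priors = default_priors(y[mask], seq.codes[mask])
                for j, g in enumerate(series):
                    out[s, i_true, r, j] = fit_model(
                        y, g, mask, priors, tol, max_iter
                    ).free_energy
    return out


def _bootstrap_confusion(F, n_boot, rng, subject_idx=None):
    """Confusion matrix from a per-subject evidence cube by bootstrap ffx-BMC.

    Each bootstrap sample draws one noise realization per subject
    (subjects themselves are not resampled unless ``subject_idx``
    subsamples them), sums log evidences across subjects, and records
    the arg-max winner; ties break toward the lowest candidate index.
    """
    N, K, n_real, _ = F.shape
    if subject_idx is None:
        subject_idx = np.arange(N)
    counts = np.zeros((K, K), dtype=np.int64)
    n_sub = len(subject_idx)
    for _ in range(n_boot):
        draw = rng.integers(0, n_real, size=n_sub)
        group_F = F[subject_idx, :, draw, :].sum(axis=0)  # (K_true, K_cand)
        counts[np.arange(K), np.argmax(group_F, axis=1)] += 1
    return counts / n_boot


def run_recovery(
    candidates: list[ModelSpec],
    sequences: list[InputSequence],
    grid: SimulationGrid | None = None,
    cells: list[tuple] | None = None,
    n_boot: int = 1000,
    n_realizations: int | None = None,
    seed: int | None = None,
) -> dict[tuple, ConfusionMatrix]:
    """Full recovery analysis: one confusion matrix per (amplitude, noise) cell.

    For each cell and each true model, every subject's sequence is
    simulated ``n_realizations`` times; candidates are refitted and
    group BMC is bootstrapped ``n_boot`` times over noise realizations.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate models")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if grid is None:
        grid = SimulationGrid()
    if cells is None:
        cells = grid.pairs
    n_real = n_realizations or grid.n_realizations
    rng = np.random.default_rng(seed)
    labels = [c.name for c in candidates]
    out = {}
    for cell in cells:
        amp, noise = cell
        F = _evidence_cube(candidates, sequences, amp, noise, n_real, rng)
        A = _bootstrap_confusion(F, n_boot, rng)
        out[cell] = ConfusionMatrix(A, labels, cell=cell, n_boot=n_boot)
    return out


def confusion_metrics(cm: ConfusionMatrix) -> RecoverySummary:
    """TPR, PPV and L1 distances to the identity and uniform matrices."""
    A = cm.entries
    K = A.shape[0]
    tpr = np.diag(A).copy()
    col = A.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = np.where(col > 0, np.diag(A) / col, np.nan)
    dist_id = float(np.abs(A - np.eye(K)).sum())
    dist_unif = float(np.abs(A - np.full((K, K), 1.0 / K)).sum())
    return RecoverySummary(tpr, ppv, dist_id, dist_unif, list(cm.labels))


def sample_size_curve(
    candidates,
    sequences,
    cell: tuple,
    sizes,
    n_boot: int = 1000,
    n_realizations: int = 5,
    seed: int | None = None,
):
    """Recovery summaries at decreasing sample sizes for one grid cell.

    Each bootstrap subsamples ``size`` subjects without replacement, so
    the curves isolate the sample-size effect at fixed SNR.  Returns
    {size: (ConfusionMatrix, RecoverySummary)}.
    """
    for size in sizes:
        if size < 2:
            raise ValueError("sample sizes must be >= 2")
        if size > len(sequences):
            raise ValueError("sample size exceeds available subjects")
    rng = np.random.default_rng(seed)
    amp, noise = cell
    F = _evidence_cube(candidates, sequences, amp, noise, n_realizations, rng)
    K = len(candidates)
    labels = [c.name for c in candidates]
    out = {}
    for size in sizes:
        counts = np.zeros((K, K), dtype=np.int64)
        for _ in range(n_boot):
            idx = rng.choice(len(sequences), size=size, replace=False)
            draw = rng.integers(0, n_realizations, size=size)
            group_F = F[idx, :, draw, :].sum(axis=0)
            counts[np.arange(K), np.argmax(group_F, axis=1)] += 1
        cm = ConfusionMatrix(counts / n_boot, labels, cell=cell, n_boot=n_boot)
        out[size] = (cm, confusion_metrics(cm))
    return out


def nearest_cell(cells, amplitude, noise):
    """Grid cell nearest to (amplitude, noise) in log-log Euclidean distance."""
    la, ln = np.log(amplitude), np.log(noise)
    d = [(np.log(a) - la) ** 2 + (np.log(s) - ln) ** 2 for a, s in cells]
    return cells[int(np.argmin(d))]


def time_resolved_recovery(
    candidates,
    sequences,
    subject_amp_noise: dict,
    grid: SimulationGrid | None = None,
    n_boot: int = 1000,
    n_realizations: int = 5,
    seed: int | None = None,
):
    """SNR-matched recovery per latency window.

    ``subject_amp_noise`` maps window -> list of per-subject
    (amplitude, noise) estimates (observed MMN amplitude and intertrial
    SD).  Each subject is simulated at the grid cell nearest to their
    observed values and a confusion matrix is assembled per window.
    Returns {window: (ConfusionMatrix, RecoverySummary)}.
    """
    if grid is None:
        grid = SimulationGrid()
    rng = np.random.default_rng(seed)
    K = len(candidates)
    labels = [c.name for c in candidates]
    cells = grid.pairs
    out = {}
    # Cache evidence cubes per (subject, cell): a subject mapped to the
    # same cell at several windows is simulated once.
    cube_cache: dict = {}
    for window, estimates in subject_amp_noise.items():
        if len(estimates) != len(sequences):
            raise ValueError("one (amplitude, noise) estimate per subject required")
        per_subject = []
        for s, est in enumerate(estimates):
            cell = nearest_cell(cells, *est)
            key = (s, cell)
            if key not in cube_cache:
                cube_cache[key] = _evidence_cube(
                    candidates, [sequences[s]], cell[0], cell[1],
                    n_realizations, rng,
                )[0]
            per_subject.append(cube_cache[key])
        F = np.stack(per_subject)  # (N, K, n_real, K)
        A = _bootstrap_confusion(F, n_boot, rng)
        cm = ConfusionMatrix(A, labels, n_boot=n_boot)
        out[window] = (cm, confusion_metrics(cm))
    return out
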