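"""Oddball stimulus sequences.

An auditory oddball experiment presents a stream of frequent *standard*
tones (code 0) interrupted by rare *deviant* tones (code 1).  Both study
designs emulated here use a 20% deviant rate and never present two
deviants in a row; deviants terminate standard runs of variable length.
The :class:`InputSequence` produced here is the drive for every model
evolution function downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InputSequence",
    "generate_oddball_sequence",
    "study1_sequence",
    "study2_sequence",
    "STUDY_PRESETS",
]


@dataclass
class InputSequence:
    """An ordered oddball stimulus sequence with per-trial masks.

    Attributes
    ----------
    codes : ndarray of int
        Stimulus identity per trial, 0 = standard, 1 = deviant.
    session_id : ndarray of int
        Session label per trial.  Hidden states of every dynamic model are
        re-initialized at each session boundary (sessions are recorded
        hours apart and share no adaptation/learning history).
    included : ndarray of bool
        Condition-of-interest flag: trials that may enter the likelihood.
    rejected : ndarray of bool
        Artifact flag: rejected trials still drive model evolution but
        never the likelihood.
    """

    codes: np.ndarray
    session_id: np.ndarray = None
    included: np.ndarray = None
    rejected: np.ndarray = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if not np.isin(self.codes, (0, 1)).all():
            raise ValueError("stimulus codes must be 0 (standard) or 1 (deviant)")
        n = self.codes.size
        if self.session_id is None:
            self.session_id = np.zeros(n, dtype=np.int64)
        else:
            self.session_id = np.asarray(self.session_id, dtype=np.int64)
        if self.included is None:
            self.included = np.ones(n, dtype=bool)
        else:
            self.included = np.asarray(self.included, dtype=bool)
        if self.rejected is None:
            self.rejected = np.zeros(n, dtype=bool)
        else:
            self.rejected = np.asarray(self.rejected, dtype=bool)
        for name in ("session_id", "included", "rejected"):
            if getattr(self, name).shape != self.codes.shape:
                raise ValueError(f"{name} must have the same length as codes")

    def __len__(self) -> int:
        return self.codes.size

    @property
    def n_deviants(self) -> int:
        return int(self.codes.sum())

    @property
    def fit_mask(self) -> np.ndarray:
        """Trials eligible for the likelihood (included and not rejected)."""
        return self.included & ~self.rejected

    def sessions(self):
        """Yield (session label, trial-index array) in presentation order."""
        for sid in np.unique(self.session_id):
            yield sid, np.flatnonzero(self.session_id == sid)


def generate_oddball_sequence(
    n_stimuli: int,
    p_deviant: float = 0.2,
    min_run: int = 2,
    max_run: int = 8,
    seed: int | None = None,
) -> InputSequence:
    """Generate a single-session oddball sequence with an exact deviant count.

    Standard-run lengths are drawn uniformly from ``{min_run..max_run}``,
    each run terminated by a single deviant; runs are then trimmed or the
    tail padded so the sequence has exactly ``round(n_stimuli*p_deviant)``
    deviants in ``n_stimuli`` trials.  Every deviant is preceded by at
    least ``min_run`` standards, so no two deviants are ever adjacent.

    Parameters
    ----------
    n_stimuli : int
        Total number of trials (>= 1).
    p_deviant : float
        Deviant rate in [0, 0.5).
    min_run, max_run : int
        Bounds of the standard-run-length distribution.
    seed : int, optional
        Seed for the run-length draws; a fixed seed gives a
        bit-reproducible sequence.
    """
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    if not (0 <= p_deviant < 0.5):
        raise ValueError("p_deviant must lie in [0, 0.5)")
    if min_run < 1 or max_run < min_run:
        raise ValueError("need 1 <= min_run <= max_run")

    n_dev = int(round(n_stimuli * p_deviant))
    if n_dev * (min_run + 1) > n_stimuli:
        raise ValueError(
            f"infeasible constraint: {n_dev} deviants each needing "
            f"{min_run} preceding standards do not fit in {n_stimuli} trials"
        )
    if n_dev == 0:
        return InputSequence(np.zeros(n_stimuli, dtype=np.int64))

    rng = np.random.default_rng(seed)
    n_std = n_stimuli - n_dev
    runs = rng.integers(min_run, max_run + 1, size=n_dev)
    # Trim runs (never below min_run) until the standards fit; leftover
    # standards become a trailing tail after the last deviant.
    excess = int(runs.sum()) - n_std
    while excess > 0:
        shrinkable = np.flatnonzero(runs > min_run)
        if shrinkable.size == 0:  # pragma: no cover - guarded by feasibility check
            raise RuntimeError("run trimming failed")
        take = rng.choice(shrinkable)
        step = min(excess, runs[take] - min_run)
        runs[take] -= step
        excess -= step
    tail = n_std - int(runs.sum())

    codes = np.zeros(n_stimuli, dtype=np.int64)
    pos = 0
    for r in runs:
        pos += int(r)
        codes[pos] = 1
        pos += 1
    assert pos + tail == n_stimuli
    return InputSequence(codes)


def study1_sequence(seed: int | None = None) -> InputSequence:
    """Study 1 design: one session of 750 stimuli with 150 deviants (20%)."""
    return generate_oddball_sequence(750, 0.2, seed=seed)


def study2_sequence(seed: int | None = None) -> InputSequence:
    """Study 2 design: two sessions, 280 included stimuli (56 deviants) each.

    Each session is a continuous stream of 1680 stimuli — three blocks of
    eight alternating 70-stimulus periods (safe/threat), each period an
    oddball segment with exactly 14 deviants.  Only the four safe periods
    of the control block (the middle one) are flagged *included*: 280
    trials with 56 deviants per session, 560/112 per participant, exactly
    the modeled counts of the design.  The full stream drives model
    evolution; the two sessions were acquired hours apart and carry
    distinct session labels, so hidden states restart at the boundary.
    """
    n_blocks, n_periods, period_len = 3, 8, 70
    session_len = n_blocks * n_periods * period_len
    ss = np.random.SeedSequence(seed).spawn(2 * n_blocks * n_periods)
    codes, session, included = [], [], []
    k = 0
    for sess in range(2):
        for block in range(n_blocks):
            for period in range(n_periods):
                seg = generate_oddball_sequence(
                    period_len, 0.2, seed=int(ss[k].generate_state(1)[0] % 2**31)
                )
                k += 1
                codes.append(seg.codes)
                # control block is the middle one; safe periods alternate first
                is_modeled = block == 1 and period % 2 == 0
                included.append(np.full(period_len, is_modeled))
        session.append(np.full(session_len, sess))
    return InputSequence(
        np.concatenate(codes),
        session_id=np.concatenate(session),
        included=np.concatenate(included),
    )


STUDY_PRESETS = {"study1": study1_sequence, "study2": study2_sequence}
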