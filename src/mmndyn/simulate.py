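"""Model-based synthetic trial amplitudes and ERP fixtures.

Simulated single-trial amplitudes follow the same observation equation
used for fitting:

    y_i = baseline + amplitude * g~_i + eps_i,  eps_i ~ N(0, noise_sd^2)

with g~ the calibrated prediction series (mean 0 on standards, 1 on
deviants of the calibration set), so ``amplitude`` is exactly the
simulated deviant-minus-standard difference response in muV.  The
default amplitude x noise grid factorially crosses 6 amplitudes with 5
noise levels — 30 pairs spanning the excess-SNR range observed in real
MMN recordings — and 5 noise realizations per pair, i.e. 150 synthetic
datasets per model and participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import ModelSpec, predict_series
from .sequences import InputSequence

__all__ = ["SimulationGrid", "simulate_responses", "generate_validation_erp"]


@dataclass(frozen=True)
class SimulationGrid:
    """Factorial amplitude (muV) x noise-SD (muV) grid for model recovery.

    Defaults give 30 pairs whose excess SNR (amplitude^2 / noise^2) spans
    roughly 5e-4 to 0.5, covering the thresholds used for SNR-filtered
    inference (0.001 / 0.008 / 0.024).
    """

    amplitude_levels: tuple = (0.25, 0.45, 0.8, 1.4, 2.5, 4.5)
    noise_levels: tuple = (6.4, 8.0, 10.0, 12.5, 15.6)
    n_realizations: int = 5

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if any(a <= 0 for a in self.amplitude_levels) or any(
            s <= 0 for s in self.noise_levels
        ):
            raise ValueError("amplitude and noise levels must be positive")

    @property
    def pairs(self) -> list[tuple[float, float]]:
        """All (amplitude, noise) cells, amplitude-major order."""
        return [(a, s) for a in self.amplitude_levels for s in self.noise_levels]

    @property
    def n_datasets(self) -> int:
        """Synthetic datasets per model per participant."""
        return len(self.pairs) * self.n_realizations

    def excess_snr(self, pair: tuple[float, float]) -> float:
        a, s = pair
        return a * a / (s * s)


def simulate_responses(
    model: ModelSpec,
    sequence: InputSequence,
    amplitude: float,
    noise_sd: float,
    n_realizations: int = 1,
    seed: int | None = None,
    baseline: float = 0.0,
) -> np.ndarray:
    """Simulate noisy trial amplitudes under a calibrated model.

    Returns an (n_trials, n_realizations) array of muV amplitudes; the
    realizations share the deterministic part and differ only in the
    Gaussian noise draw.  Reproducible for a fixed seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    if not model.is_calibrated:
        raise ValueError(f"model {model.name} must be calibrated before simulation")
    g = predict_series(model, sequence)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=(n_realizations, g.size))
    return (baseline + amplitude * g + eps).T


def generate_validation_erp(
    amplitude: float,
    peak_latency: float,
    width: float,
    offset: float,
    noise_sd: float,
    times: np.ndarray,
    seed: int | None = None,
) -> np.ndarray:
    """Synthetic deviant-minus-standard difference waveform (fixture).

    A Gaussian deflection ``offset + amplitude*exp(-(t-peak)^2/(2 width^2))``
    plus white noise, on the given time grid (ms).  An MMN-like waveform
    has negative amplitude; zero amplitude emulates a participant without
    a detectable MMN.
    """
    times = np.asarray(times, dtype=float)
    if times.size > 1 and not (np.diff(times) > 0).all():
        raise ValueError("times must be strictly increasing")
    if width <= 0:
        raise ValueError("width must be > 0")
    rng = np.random.default_rng(seed)
    wave = offset + amplitude * np.exp(-((times - peak_latency) ** 2) / (2.0 * width**2))
    if noise_sd > 0:
        wave = wave + rng.normal(0.0, noise_sd, size=times.size)
    return wave
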