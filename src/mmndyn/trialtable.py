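"""Tabular interchange format and end-to-end pipeline.

The trial table is the package's single data container: one row per
presented stimulus, columns for identity and masks, plus one amplitude
column (muV) per 10 ms latency window named by its start (w045..w245).
It is plain TSV/CSV on disk — the upstream EEG preprocessing that
produces window- and ROI-averaged single-trial amplitudes is outside
this package's scope.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sequences import InputSequence

__all__ = [
    "DEFAULT_WINDOW_STARTS",
    "window_label",
    "TrialTable",
    "read_trial_table",
    "write_trial_table",
    "simulate_cohort",
    "RunConfig",
    "run_pipeline",
]

#: 21 non-overlapping 10 ms windows from 45 to 255 ms post-stimulus.
DEFAULT_WINDOW_STARTS = tuple(range(45, 255, 10))

REQUIRED_COLUMNS = ("subject_id", "session_id", "trial_index", "u", "included", "rejected")


def window_label(start_ms: int) -> str:
    return f"w{start_ms:03d}"


class TrialTable:
    """Per-subject trial x latency amplitude matrix with masks.

    Wraps a tidy DataFrame; rows are ordered by presentation within
    subject and session.
    """

    def __init__(self, df: pd.DataFrame):
        self.df = _validate(df)
        self.window_labels = [c for c in df.columns if _is_window_col(c)]

    def __len__(self) -> int:
        return len(self.df)

    def subjects(self) -> list:
        return list(dict.fromkeys(self.df["subject_id"]))

    def _rows(self, subject) -> pd.DataFrame:
        return self.df[self.df["subject_id"] == subject]

    def sequence(self, subject) -> InputSequence:
        r = self._rows(subject)
        return InputSequence(
            codes=r["u"].to_numpy(),
            session_id=r["session_id"].to_numpy(),
            included=r["included"].to_numpy(dtype=bool),
            rejected=r["rejected"].to_numpy(dtype=bool),
        )

    def amplitudes(self, subject, window=None) -> np.ndarray:
        r = self._rows(subject)
        if window is None:
            return r[self.window_labels].to_numpy(dtype=float)
        return r[window].to_numpy(dtype=float)


def _is_window_col(name: str) -> bool:
    return isinstance(name, str) and name.startswith("w") and name[1:].isdigit()


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")
    bad_u = df.index[~df["u"].isin([0, 1])].tolist()
    if bad_u:
        raise ValueError(f"non-binary stimulus code u in rows {bad_u[:10]}")
    windows = [c for c in df.columns if _is_window_col(c)]
    if not windows:
        raise ValueError("trial table has no amplitude window columns (w###)")
    starts = sorted(int(c[1:]) for c in windows)
    if len(starts) > 1:
        gaps = np.diff(starts)
        if not (gaps == gaps[0]).all():
            raise ValueError(f"window columns are not a contiguous grid: {starts}")
    for (subj, sess), grp in df.groupby(["subject_id", "session_id"], sort=False):
        ti = grp["trial_index"].to_numpy()
        if not (np.diff(ti) > 0).all():
            raise ValueError(
                f"trial_index not strictly increasing for subject {subj!r} session {sess!r}"
            )
    return df


def read_trial_table(path) -> TrialTable:
    """Read and validate a trial table from TSV (default) or CSV by extension."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return TrialTable(pd.read_csv(path, sep=sep))


def write_trial_table(table: TrialTable, path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table.df.to_csv(path, sep=sep, index=False)


def simulate_cohort(
    model,
    n_subjects: int,
    preset: str = "study1",
    amplitude: float = 2.0,
    noise_sd: float = 8.0,
    seed: int | None = None,
    window_starts=DEFAULT_WINDOW_STARTS,
) -> TrialTable:
    """Simulate a cohort trial table under one generative model.

    Each subject gets their own oddball sequence from the named study
    preset and independent Gaussian trial noise per latency window; the
    deterministic part is identical across windows (one effect at all
    latencies — a deliberately simple stand-in for a latency-resolved
    effect profile).
    """
    from .models import calibrate_lambda, predict_series
    from .sequences import STUDY_PRESETS

    rng = np.random.default_rng(seed)
    frames = []
    for s in range(n_subjects):
        seq = STUDY_PRESETS[preset](seed=int(rng.integers(2**31)))
        cal = calibrate_lambda(model, seq)
        g = predict_series(cal, seq)
        d = {
            "subject_id": f"S{s:03d}",
            "session_id": seq.session_id,
            "trial_index": np.concatenate(
                [np.arange(idx.size) for _, idx in seq.sessions()]
            ),
            "u": seq.codes,
            "included": seq.included,
            "rejected": seq.rejected,
        }
        for w in window_starts:
            noise = rng.normal(0.0, noise_sd, size=len(seq))
            d[window_label(w)] = amplitude * g + noise
        frames.append(pd.DataFrame(d))
    return TrialTable(pd.concat(frames, ignore_index=True))


@dataclass
class RunConfig:
    """Configuration of an end-to-end analysis run."""

    windows: tuple = DEFAULT_WINDOW_STARTS
    model_grid: list | None = None       # default: the 27-model space
    family_map: dict = field(
        default_factory=lambda: {"null": "ctrl", "dd": "ctrl"}
    )
    snr_thresholds: tuple = (0.001, 0.008, 0.024)
    run_validation: bool = True
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if self.model_grid is not None and len(self.model_grid) == 0:
            raise ValueError("model grid must not be empty")
        if not self.windows:
            raise ValueError("window grid must not be empty")


def run_pipeline(config: RunConfig, table: TrialTable) -> dict:
    """Chain fitting, group BMC/BMA, SNR subsetting and goodness-of-fit.

    Returns a bundle of tidy DataFrames; when ``config.out_dir`` is set,
    every artifact is also written as TSV next to a JSON manifest
    recording the seed and a hash of the configuration.
    """
    from .group import compute_snr, family_bmc, subset_by_snr
    from .gof import r2_max
    from .inversion import fit_all
    from .models import default_model_grid

    config.validate()
    specs = config.model_grid if config.model_grid is not None else default_model_grid()
    labels = [window_label(w) if isinstance(w, int) else w for w in config.windows]
    labels = [w for w in labels if w in table.window_labels]
    if not labels:
        raise ValueError("no requested window present in the trial table")

    evidence = fit_all(table, specs, windows=labels)
    comparison = family_bmc(evidence, family_map=config.family_map)

    snr_rows = []
    for subject in table.subjects():
        seq = table.sequence(subject)
        mask = seq.fit_mask
        for w in labels:
            y = table.amplitudes(subject, w)
            rec = compute_snr(y[mask], seq.codes[mask])
            snr_rows.append(
                dict(subject=subject, window=w, mu=rec.mu,
                     sigma2=rec.sigma2, excess_snr=rec.excess_snr)
            )
    snr = pd.DataFrame(snr_rows)

    thresholded = {
        thr: subset_by_snr(evidence, snr, thr) for thr in config.snr_thresholds
    }

    # Absolute goodness-of-fit of the per-window winning model.
    from .models import calibrate_lambda, predict_series

    gof_rows = []
    best = (
        evidence.groupby(["window", "model"])["F"].sum().reset_index()
        .sort_values("F").groupby("window").tail(1)
    )
    best_by_window = dict(zip(best["window"], best["model"]))
    spec_by_name = {s.name: s for s in specs}
    for subject in table.subjects():
        seq = table.sequence(subject)
        mask = seq.fit_mask
        for w in labels:
            name = best_by_window[w]
            row = evidence[
                (evidence.subject == subject)
                & (evidence.model == name)
                & (evidence.window == w)
            ].iloc[0]
            g = predict_series(calibrate_lambda(spec_by_name[name], seq), seq)
            y = table.amplitudes(subject, w)
            r2m = r2_max(g[mask], y[mask], phi1=row.phi1) if name != "null" else np.nan
            gof_rows.append(
                dict(subject=subject, window=w, model=name,
                     r2_obs=row.r2_obs, r2_max=r2m)
            )
    gof = pd.DataFrame(gof_rows)

    bundle = dict(
        evidence=evidence, comparison=comparison, snr=snr,
        thresholded=thresholded, gof=gof,
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        evidence.to_csv(out / "evidence.tsv", sep="\t", index=False)
        comparison.to_csv(out / "family_bmc.tsv", sep="\t", index=False)
        snr.to_csv(out / "snr.tsv", sep="\t", index=False)
        gof.to_csv(out / "gof.tsv", sep="\t", index=False)
        for thr, df in thresholded.items():
            df.to_csv(out / f"family_bmc_snr_{thr}.tsv", sep="\t", index=False)
        cfg_desc = dict(
            windows=list(labels), n_models=len(specs), seed=config.seed,
            snr_thresholds=list(config.snr_thresholds),
        )
        manifest = dict(
            config=cfg_desc,
            config_hash=hashlib.sha256(
                json.dumps(cfg_desc, sort_keys=True).encode()
            ).hexdigest(),
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle
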