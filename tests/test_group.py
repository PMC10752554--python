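"""Group-level fixed-effect model comparison, averaging and SNR utilities."""

import numpy as np
import pandas as pd
import pytest

import mmndyn as m
from mmndyn.group import (
    bayes_factor_vs_all,
    bf_snr_association,
    bma_tau,
    compute_snr,
    family_pmp,
    group_log_evidence,
    kass_raftery_label,
    posterior_model_probability,
)


def _evidence_frame(values):
    """Tidy evidence table from {subject: {model: F}} at one window."""
    rows = []
    for subj, d in values.items():
        for model, F in d.items():
            rows.append(dict(subject=subj, model=model, family=model,
                             tau=np.nan, window="w145", F=F))
    return pd.DataFrame(rows)


class TestGroupEvidence:
    def test_two_subjects_sum(self):
        ev = _evidence_frame({"a": {"m1": -3.0}, "b": {"m1": -4.5}})
        out = group_log_evidence(ev)
        assert out.loc[0, "log_evidence"] == pytest.approx(-7.5)

    def test_single_subject_identity_and_oracle(self, rng):
        vals = {f"s{i}": {f"m{j}": rng.normal() for j in range(4)} for i in range(6)}
        ev = _evidence_frame(vals)
        out = group_log_evidence(ev).set_index("model")["log_evidence"]
        for j in range(4):
            expect = sum(vals[s][f"m{j}"] for s in vals)
            assert out[f"m{j}"] == pytest.approx(expect)

    def test_empty_subset_raises(self):
        ev = _evidence_frame({"a": {"m1": 0.0}})
        with pytest.raises(ValueError):
            group_log_evidence(ev, subjects=[])


class TestPMP:
    def test_equal_evidences_uniform(self):
        assert np.allclose(posterior_model_probability(np.zeros(4)), 0.25)

    def test_ln3_difference(self):
        p = posterior_model_probability(np.array([np.log(3.0), 0.0]))
        assert np.allclose(p, [0.75, 0.25])

    def test_matches_longdouble_softmax_oracle(self, rng):
        le = rng.normal(scale=30, size=12)
        ref = np.exp(np.longdouble(le))
        ref = (ref / ref.sum()).astype(float)
        assert np.allclose(posterior_model_probability(le), ref, atol=1e-12)

    def test_invariant_to_additive_constant(self, rng):
        le = rng.normal(size=9)
        a = posterior_model_probability(le)
        b = posterior_model_probability(le + 1234.5)
        assert np.allclose(a, b, atol=1e-12)
        assert a.sum() == pytest.approx(1.0, abs=1e-12)


class TestFamilies:
    def test_identity_and_sum(self):
        p = np.full(7, 0.1)
        fams = np.array(["ssa"] * 7)
        out = family_pmp(p, fams)
        assert out["ssa"] == pytest.approx(0.7)

    def test_groupby_oracle(self, rng):
        p = rng.dirichlet(np.ones(10))
        fams = np.array(list("aabbbcccdd"))
        out = family_pmp(p, fams)
        for f in "abcd":
            assert out[f] == pytest.approx(p[fams == f].sum())


class TestBayesFactors:
    @pytest.mark.parametrize(
        "pmp,K,expect", [(0.5, 2, 1.0), (0.9, 10, 81.0)]
    )
    def test_forced_arithmetic(self, pmp, K, expect):
        assert bayes_factor_vs_all(pmp, K) == pytest.approx(expect)

    def test_degenerate_warns(self):
        with pytest.warns(RuntimeWarning):
            assert np.isinf(bayes_factor_vs_all(1.0, 3))

    @pytest.mark.parametrize(
        "bf,label",
        [(2.9, "inconclusive"), (3.0, "substantial"), (10.0, "strong"),
         (99.9, "strong"), (150.0, "decisive"), (1000.0, "decisive")],
    )
    def test_kass_raftery_bands(self, bf, label):
        assert kass_raftery_label(bf) == label


class TestBMA:
    def test_degenerate_posterior_returns_tau(self):
        assert bma_tau([0, 0, 1.0], [5, 10, 20]) == 20

    def test_uniform_over_bl_grid(self):
        taus = [5, 10, 20, 30, 50, 100]
        assert bma_tau(np.ones(6), taus) == pytest.approx(35.8333, abs=1e-3)

    def test_weighted_mean_oracle_and_bounds(self, rng):
        taus = np.array([5.0, 10, 20, 30, 50, 100])
        w = rng.dirichlet(np.ones(6))
        est = bma_tau(w, taus)
        assert est == pytest.approx(float(np.average(taus, weights=w)))
        assert taus.min() <= est <= taus.max()

    def test_seconds_conversion(self):
        assert bma_tau([1.0], [20.0], soa=0.58) == pytest.approx(11.6)

    def test_zero_weight_raises(self):
        with pytest.raises(ValueError):
            bma_tau([0.0, 0.0], [5, 10])


class TestSNR:
    def test_zero_difference_gives_one(self, rng):
        y = rng.normal(0, 2, 400)
        u = rng.integers(0, 2, 400)
        y = y - (u == 1) * (y[u == 1].mean()) - (u == 0) * (y[u == 0].mean())
        rec = compute_snr(y, u)
        assert rec.snr == pytest.approx(1.0, abs=1e-12)

    def test_mu_equal_sd_gives_two(self):
        std = np.array([-1.0, 1.0] * 50)
        pooled_sd = std.std(ddof=1)  # both classes share this spread
        y = np.concatenate([std, std + pooled_sd])
        u = np.concatenate([np.zeros(100, int), np.ones(100, int)])
        assert compute_snr(y, u).snr == pytest.approx(2.0)

    def test_monte_carlo_against_design(self, study1_seq, rng):
        """Simulated data at (amplitude a, noise s) shows snr ~ 1 + a^2/s^2."""
        dd = m.calibrate_lambda(m.ModelSpec("dd"), study1_seq)
        a, s = 3.0, 4.0
        snrs = [
            compute_snr(
                m.simulate_responses(dd, study1_seq, a, s, seed=k)[:, 0],
                study1_seq.codes,
            ).snr
            for k in range(40)
        ]
        assert np.mean(snrs) == pytest.approx(1 + a**2 / s**2, rel=0.03)

    def test_pure_noise_snr_near_one(self, study1_seq):
        dd = m.calibrate_lambda(m.ModelSpec("dd"), study1_seq)
        snrs = [
            compute_snr(
                m.simulate_responses(dd, study1_seq, 0.0, 5.0, seed=k)[:, 0],
                study1_seq.codes,
            ).snr
            for k in range(40)
        ]
        assert np.mean(snrs) == pytest.approx(1.0, abs=0.01)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            compute_snr(np.ones(10), np.array([0, 1] * 5))


class TestSubsetBySNR:
    def _setup(self):
        ev = []
        snr = []
        for s in range(6):
            for model, F in (("a", -s), ("b", -2.0 * s - 0.5)):
                ev.append(dict(subject=f"s{s}", model=model, family=model,
                               tau=np.nan, window="w145", F=F))
            snr.append(dict(subject=f"s{s}", window="w145", excess_snr=0.005 * s))
        return pd.DataFrame(ev), pd.DataFrame(snr)

    def test_threshold_zero_keeps_nearly_all(self):
        ev, snr = self._setup()
        out = m.subset_by_snr(ev, snr, 0.0)
        assert out["n_subjects"].iloc[0] == 5  # s0 has excess 0.0, not > 0

    def test_threshold_above_all_flags_window(self):
        ev, snr = self._setup()
        out = m.subset_by_snr(ev, snr, 1.0)
        assert out["flagged"].all()

    def test_membership_matches_filter_oracle(self):
        ev, snr = self._setup()
        thr = 0.012
        out = m.subset_by_snr(ev, snr, thr)
        keep = {r.subject for r in snr.itertuples() if r.excess_snr > thr}
        assert out["n_subjects"].iloc[0] == len(keep)


class TestBFSNRAssociation:
    def test_perfectly_linear(self):
        snr = np.linspace(0.001, 0.05, 10)
        logbf = 100 * snr - 2.0
        slope, icpt, r2, snr0 = bf_snr_association(logbf, snr)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(100.0)
        assert snr0 == pytest.approx(0.02)

    def test_constant_logbf_zero_slope(self):
        snr = np.linspace(0, 1, 8)
        slope, *_ = bf_snr_association(np.full(8, 1.5), snr)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_noisy_linear_matches_ols_oracle(self, rng):
        x = rng.uniform(0, 0.05, 40)
        y = 80 * x - 1 + rng.normal(0, 0.3, 40)
        slope, icpt, r2, _ = bf_snr_association(y, x)
        X = np.column_stack([x, np.ones(40)])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert slope == pytest.approx(beta[0])
        assert icpt == pytest.approx(beta[1])

    def test_degenerate_variance_raises(self):
        with pytest.raises(ValueError):
            bf_snr_association(np.ones(5), np.ones(5))
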