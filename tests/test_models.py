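"""Evolution/observation functions, normalization and prediction series."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import mmndyn as m
from mmndyn.models import (
    ModelSpec,
    beta_kl,
    bl_evolve,
    calibrate_lambda,
    observe_raw,
    predict_series,
    raw_series,
    ssa_evolve,
)


class TestSSAEvolution:
    def test_single_standard_from_rest(self):
        x0, x1 = ssa_evolve((1.0, 1.0), 0, tau_a=10)
        assert x0 == pytest.approx(math.exp(-0.1), abs=1e-12)
        assert x1 == 1.0  # fully recovered state stays at ceiling

    def test_n_standards_closed_form_vs_loop(self):
        state = (1.0, 1.0)
        for _ in range(17):
            state = ssa_evolve(state, 0, tau_a=10)
        assert state[0] == pytest.approx(math.exp(-0.1) ** 17, rel=1e-12)

    def test_symmetry_of_deviant_branch(self):
        # deviant input adapts x1 and recovers x0
        x0, x1 = ssa_evolve((0.5, 0.5), 1, tau_a=10)
        kr = math.exp(-1 / 20)
        assert x0 == pytest.approx(1 - 0.5 * kr)
        assert x1 == pytest.approx(0.5 * math.exp(-0.1))

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            ssa_evolve((1.0, 1.0), 0, tau_a=0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        tau=st.sampled_from([3, 10, 20, 30, 50, 100, 200]),
        codes=st.lists(st.integers(0, 1), min_size=1, max_size=200),
    )
    def test_responsiveness_stays_in_unit_interval(self, tau, codes):
        state = (1.0, 1.0)
        for u in codes:
            state = ssa_evolve(state, u, tau)
            assert 0 < state[0] <= 1 and 0 < state[1] <= 1


class TestBLEvolution:
    def test_perfect_memory_limit(self):
        # Kt -> 1 is plain counting; emulate with huge tau
        a, b = bl_evolve((1.0, 1.0), 1, tau_t=1e12)
        assert a == pytest.approx(2.0, abs=1e-9)
        assert b == pytest.approx(1.0, abs=1e-9)

    def test_memoryless_limit(self):
        a, b = bl_evolve((7.0, 3.0), 1, tau_t=1e-3)
        assert a == pytest.approx(1.0, abs=1e-6)
        assert b == pytest.approx(0.0, abs=1e-6)

    def test_standard_run_geometric_closed_form(self):
        tau = 20.0
        kt = math.exp(-1 / tau)
        state = (1.0, 1.0)
        for _ in range(100):
            state = bl_evolve(state, 0, tau)
        assert state[0] == pytest.approx(kt**100, rel=1e-10)
        assert state[1] == pytest.approx(kt**100 + (1 - kt**100) / (1 - kt), rel=1e-10)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        tau=st.sampled_from([5, 10, 20, 30, 50, 100]),
        codes=st.lists(st.integers(0, 1), min_size=50, max_size=300),
    )
    def test_pseudocount_fixed_point_bound(self, tau, codes):
        kt = math.exp(-1 / tau)
        bound = 1.0 / (1.0 - kt) + 1e-9
        state = (1.0, 1.0)
        for i, u in enumerate(codes):
            state = bl_evolve(state, u, tau)
            assert state[0] > 0 and state[1] > 0
            if i >= 20:  # after burn-in the initial count has decayed below the bound
                assert state[0] <= bound and state[1] <= bound


class TestObservations:
    def test_null_and_dd(self):
        assert observe_raw(ModelSpec("null"), None, 1) == 0.0
        assert observe_raw(ModelSpec("dd"), None, 1) == 1.0
        assert observe_raw(ModelSpec("dd"), None, 0) == 0.0

    def test_surprise_symmetric_belief(self):
        spec = ModelSpec("bl_surp", 20)
        for u in (0, 1):
            assert observe_raw(spec, (3.0, 3.0), u) == pytest.approx(math.log(2))

    def test_pwpe_flat_prior_deviant(self):
        # Beta(1,1): mean 1/2, variance 1/12 -> (1 - 1/2) * 12 = 6
        assert observe_raw(ModelSpec("bl_pwpe", 20), (1.0, 1.0), 1) == pytest.approx(6.0)

    def test_madj_flat_to_updated(self):
        spec = ModelSpec("bl_madj", 20)
        val = observe_raw(spec, (1.0, 1.0), 1, post_state=(2.0, 1.0))
        # KL(Beta(1,1) || Beta(2,1)) = ln 2 - psi(2) + psi(1) + ... = 1 - ln 2
        assert val == pytest.approx(0.30685281944005469, abs=1e-9)

    def test_madj_requires_positive_parameters(self):
        with pytest.raises(ValueError):
            beta_kl((0.0, 1.0), (1.0, 1.0))

    def test_nonfinite_state_rejected(self):
        with pytest.raises(ValueError):
            observe_raw(ModelSpec("ssa", 10), (np.nan, 1.0), 0)


@pytest.mark.parametrize(
    "prior,posterior",
    [
        ((0.5, 0.5), (1.4, 0.6)),
        ((1.0, 1.0), (2.0, 1.0)),
        ((2.0, 8.0), (2.9, 8.1)),
        ((10.0, 40.0), (10.8, 40.2)),
        ((50.0, 50.0), (49.0, 51.0)),
        ((0.7, 30.0), (1.7, 29.5)),
    ],
)
def test_beta_kl_matches_quadrature(prior, posterior):
    """Closed-form KL equals numerical integration of the divergence integral."""
    a1, b1 = prior
    a2, b2 = posterior

    def integrand(x):
        lp = stats.beta.logpdf(x, a1, b1)
        lq = stats.beta.logpdf(x, a2, b2)
        return np.exp(lp) * (lp - lq)

    num, err = integrate.quad(integrand, 0.0, 1.0, limit=200)
    assert beta_kl(prior, posterior) == pytest.approx(num, abs=1e-8)


class TestCalibration:
    def test_dd_identity_normalization(self, study1_seq):
        spec = calibrate_lambda(ModelSpec("dd"), study1_seq)
        assert spec.lambda0 == pytest.approx(0.0)
        assert spec.lambda1 == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "spec",
        [ModelSpec("ssa", 10), ModelSpec("bl_surp", 20),
         ModelSpec("bl_pwpe", 20), ModelSpec("bl_madj", 20)],
        ids=lambda s: s.name,
    )
    def test_normalized_class_means(self, study1_seq, spec):
        cal = calibrate_lambda(spec, study1_seq)
        g = predict_series(cal, study1_seq)
        assert g[study1_seq.codes == 0].mean() == pytest.approx(0.0, abs=1e-10)
        assert g[study1_seq.codes == 1].mean() == pytest.approx(1.0, abs=1e-10)

    def test_ssa_deviant_population_less_adapted(self, study1_seq):
        """Forward simulation: deviant-tuned responsiveness exceeds standard-tuned
        on average, so the normalization scale is positive."""
        cal = calibrate_lambda(ModelSpec("ssa", 10), study1_seq)
        assert cal.lambda1 > 0
        raw = raw_series(ModelSpec("ssa", 10), study1_seq)
        assert raw[study1_seq.codes == 1].mean() > raw[study1_seq.codes == 0].mean()

    def test_uncalibrated_predict_raises(self, study1_seq):
        with pytest.raises(ValueError, match="not calibrated"):
            predict_series(ModelSpec("ssa", 10), study1_seq)


class TestPredictionSeries:
    def test_null_is_zero_dd_is_codes(self, study1_seq):
        null = calibrate_lambda(ModelSpec("null"), study1_seq)
        assert not predict_series(null, study1_seq).any()
        dd = calibrate_lambda(ModelSpec("dd"), study1_seq)
        assert np.allclose(predict_series(dd, study1_seq), study1_seq.codes)

    def test_surp_pwpe_correlation_exceeds_099(self, study1_seq):
        g1 = predict_series(calibrate_lambda(ModelSpec("bl_surp", 20), study1_seq), study1_seq)
        g2 = predict_series(calibrate_lambda(ModelSpec("bl_pwpe", 20), study1_seq), study1_seq)
        assert np.corrcoef(g1, g2)[0, 1] > 0.99

    def test_session_boundaries_reset_states(self, study2_seq):
        """Predictions of session 2 equal predictions of session 2 run alone."""
        spec = ModelSpec("ssa", 10)
        raw_full = raw_series(spec, study2_seq)
        _, idx2 = list(study2_seq.sessions())[1]
        alone = m.InputSequence(study2_seq.codes[idx2])
        assert np.allclose(raw_full[idx2], raw_series(spec, alone))

    def test_rejected_trials_still_drive_evolution(self, study1_seq):
        noisy = m.InputSequence(
            study1_seq.codes,
            rejected=np.arange(len(study1_seq)) % 5 == 0,
        )
        assert np.allclose(
            raw_series(ModelSpec("ssa", 10), noisy),
            raw_series(ModelSpec("ssa", 10), study1_seq),
        )


def test_default_model_grid_composition():
    grid = m.default_model_grid()
    fams = [s.family for s in grid]
    assert fams.count("ssa") == 7 and fams.count("null") == 1 and fams.count("dd") == 1
    for f in ("bl_surp", "bl_pwpe", "bl_madj"):
        assert fams.count(f) == 6
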