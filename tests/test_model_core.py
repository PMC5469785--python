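"""Unit and property tests for the removal-probability machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from eradimix import (
    CountData,
    ModelParams,
    SurveyDesign,
    detection_link,
    effective_probs,
    marginal_loglik,
    removal_probabilities,
)
from oracles import enumerate_fates, marginal_loglik_bruteforce


class TestDetectionLink:
    @pytest.mark.parametrize(
        "beta0, beta1, temp, expected",
        [
            (0.0, 0.0, -3.0, 1.0 - np.exp(-1.0)),
            (0.0, 0.0, 25.0, 1.0 - np.exp(-1.0)),
            (-2.0, 0.05, 20.0, 1.0 - np.exp(-np.exp(-1.0))),
        ],
    )
    def test_closed_form(self, beta0, beta1, temp, expected):
        assert detection_link(beta0, beta1, temp) == pytest.approx(expected, rel=1e-12)

    def test_extreme_negative_predictor_is_essentially_zero(self):
        assert detection_link(-50.0, 0.0, 0.0) < 1e-20

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            detection_link(np.inf, 0.0, 20.0)
        with pytest.raises(ValueError):
            detection_link(0.0, 1.0, np.nan)

    def test_vectorised_over_temperature(self):
        temps = np.array([0.0, 10.0, 20.0])
        out = detection_link(-1.0, 0.1, temps)
        assert out.shape == (3,)
        assert (np.diff(out) > 0).all()  # warmer months are more detectable


class TestEffectiveProbs:
    def test_lost_trap_zeroes_detection_only(self):
        hold = np.array([[1, 0], [1, 1]])
        chem = np.ones((2, 2), dtype=int)
        design = SurveyDesign(hold=hold, chem=chem)
        params = ModelParams(c_const=0.279, d_const=0.00539)
        c, d = effective_probs(params, design)
        assert c[0, 1] == 0.0
        assert d[0, 1] == 0.00539  # bait still kills at a lost-trap month
        assert c[0, 0] == 0.279

    def test_point_estimates_pass_through(self):
        design = SurveyDesign.constant(1, 1)
        c, d = effective_probs(ModelParams(c_const=0.279, d_const=0.00539), design)
        assert (c == 0.279).all() and (d == 0.00539).all()

    def test_chemical_term_off_zeroes_death(self):
        design = SurveyDesign.constant(3, 2)
        params = ModelParams(c_const=0.3, d_const=0.2, chemical_term=False)
        _, d = effective_probs(params, design)
        assert (d == 0.0).all()

    def test_temperature_link_requires_series(self):
        design = SurveyDesign.constant(3, 2)
        params = ModelParams(use_temperature=True, beta0=-1.0, beta1=0.05)
        with pytest.raises(ValueError, match="temperature"):
            effective_probs(params, design)

    def test_temperature_link_varies_by_survey(self):
        design = SurveyDesign.constant(3, 2, temperature=np.array([5.0, 15.0, 25.0]))
        params = ModelParams(use_temperature=True, beta0=-2.0, beta1=0.05)
        c, _ = effective_probs(params, design)
        expected = detection_link(-2.0, 0.05, design.temperature)
        assert np.allclose(c, expected[:, None])


class TestRemovalProbabilities:
    def test_pure_death_sequence(self):
        """With no trapping, the first-death probabilities follow the
        geometric pattern; at the second survey (1 - 0.9) * 0.9 = 0.09."""
        rp = removal_probabilities(np.zeros((2, 1)), np.full((2, 1), 0.9))
        assert rp.delta[0, 0] == pytest.approx(0.9, abs=1e-15)
        assert rp.delta[1, 0] == pytest.approx(0.09, abs=1e-15)
        assert (rp.pi_prime == 0.0).all()

    def test_certain_first_capture(self):
        c = np.array([[1.0], [0.5], [0.5]])
        d = np.zeros((3, 1))
        rp = removal_probabilities(c, d)
        assert rp.pi_prime[0, 0] == 1.0
        assert rp.phi[0, 0] == 0.0
        assert (rp.pi_prime[1:, 0] == 0.0).all()

    def test_matches_exact_fate_enumeration(self):
        c_val, d_val = 0.279, 0.00539
        rp = removal_probabilities(np.full(3, c_val), np.full(3, d_val))
        pi, delta, alive = enumerate_fates(["0.279"] * 3, ["0.00539"] * 3)
        assert np.allclose(rp.pi_prime[:, 0], [float(p) for p in pi], atol=1e-14)
        assert np.allclose(rp.delta[:, 0], [float(x) for x in delta], atol=1e-14)
        assert rp.phi[-1, 0] == pytest.approx(float(alive), abs=1e-14)
        assert rp.pi_prime[0, 0] == pytest.approx(0.277496, abs=1e-6)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            removal_probabilities(np.array([[1.2]]), np.array([[0.0]]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        cd=hnp.arrays(
            float,
            st.tuples(st.integers(1, 8), st.integers(1, 4), st.just(2)),
            elements=st.floats(0.0, 1.0),
        )
    )
    def test_fates_partition_exhaustively(self, cd):
        """Capture, death and final survival partition an individual's fate:
        the three joint probabilities sum to one at every point."""
        rp = removal_probabilities(cd[..., 0], cd[..., 1])
        assert (rp.conservation_gap() < 1e-12).all()
        assert (np.diff(rp.phi, axis=0) <= 1e-15).all()
        for arr in (rp.pi_prime, rp.delta, rp.phi):
            assert ((arr >= 0.0) & (arr <= 1.0)).all()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        data=st.tuples(
            hnp.arrays(float, (5, 1), elements=st.floats(0.01, 0.99)),
            hnp.arrays(float, (5, 1), elements=st.floats(0.0, 0.9)),
            st.integers(0, 3),
            st.floats(0.01, 0.09),
        )
    )
    def test_raising_death_rate_cannot_raise_later_capture(self, data):
        c, d, t_mod, bump = data
        rp = removal_probabilities(c, d)
        d2 = d.copy()
        d2[t_mod, 0] = min(d2[t_mod, 0] + bump, 1.0)
        rp2 = removal_probabilities(c, d2)
        assert (rp2.pi_prime[t_mod:, 0] <= rp.pi_prime[t_mod:, 0] + 1e-12).all()

    def test_chemical_term_off_reduces_to_base_removal_model(self):
        """d = 0 recovers the capture-only cell probabilities
        pi_t = prod_{k<t}(1-c_k) c_t."""
        rng = np.random.default_rng(7)
        c = rng.uniform(0.05, 0.6, size=(6, 3))
        rp = removal_probabilities(c, np.zeros_like(c))
        base = np.empty_like(c)
        for i in range(c.shape[1]):
            surv = 1.0
            for t in range(c.shape[0]):
                base[t, i] = surv * c[t, i]
                surv *= 1.0 - c[t, i]
        assert np.allclose(rp.pi_prime, base, atol=1e-14)
        assert (rp.delta == 0.0).all()


class TestMarginalLoglik:
    def test_single_point_single_survey_vs_bruteforce(self):
        design = SurveyDesign.constant(1, 1)
        data = CountData(y=np.array([[3]]))
        params = ModelParams(c_const=0.5, d_const=0.0, mu=2.0, sigma=1.0)
        got = marginal_loglik(params, design, data)
        want = marginal_loglik_bruteforce(
            *effective_probs(params, design), 2.0, 1.0, data.y
        )
        assert got == pytest.approx(want, abs=1e-10)

    def test_all_zero_counts_vs_truncated_sum(self):
        design = SurveyDesign.constant(5, 3)
        data = CountData(y=np.zeros((5, 3), dtype=int))
        params = ModelParams(c_const=0.3, d_const=0.05, mu=4.0, sigma=1.5)
        got = marginal_loglik(params, design, data)
        c, d = effective_probs(params, design)
        want = marginal_loglik_bruteforce(c, d, 4.0, 1.5, data.y, n_max=2000)
        assert got == pytest.approx(want, abs=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        c_val=st.floats(0.1, 0.8),
        d_val=st.floats(0.0, 0.3),
        mu=st.floats(0.5, 6.0),
        sigma=st.floats(0.4, 3.0),
    )
    def test_matches_bruteforce_on_random_small_instances(
        self, seed, c_val, d_val, mu, sigma
    ):
        rng = np.random.default_rng(seed)
        T, P = int(rng.integers(1, 5)), int(rng.integers(1, 4))
        hold = rng.integers(0, 2, size=(T, P))
        hold[rng.integers(0, T), :] = 1  # keep at least one active survey
        chem = rng.integers(0, 2, size=(T, P))
        design = SurveyDesign(hold=hold, chem=chem)
        params = ModelParams(c_const=c_val, d_const=d_val, mu=mu, sigma=sigma)
        c, d = effective_probs(params, design)
        y = rng.poisson(0.8, size=(T, P)) * (hold > 0)
        data = CountData(y=y)
        got = marginal_loglik(params, design, data)
        want = marginal_loglik_bruteforce(c, d, mu, sigma, y, n_max=3000)
        assert got == pytest.approx(want, abs=1e-8)

    def test_impossible_data_gives_minus_inf(self):
        # all traps lost yet a removal recorded: zero capture probability
        design = SurveyDesign(hold=np.zeros((2, 1), int), chem=np.ones((2, 1), int))
        data = CountData(y=np.zeros((2, 1), int))
        data.y[0, 0] = 2  # bypass construction-time validation
        data.n = data.y.sum(axis=0)
        params = ModelParams(c_const=0.3, d_const=0.1, mu=5.0, sigma=1.0)
        assert marginal_loglik(params, design, data, strict=False) == -np.inf

    def test_strict_mode_rejects_counts_in_lost_traps(self):
        design = SurveyDesign(hold=np.array([[0], [1]]), chem=np.ones((2, 1), int))
        data = CountData(y=np.array([[1], [0]]))
        params = ModelParams(c_const=0.3, d_const=0.1, mu=5.0, sigma=1.0)
        with pytest.raises(ValueError, match="lost"):
            marginal_loglik(params, design, data)

    def test_survey_permutation_changes_only_the_multinomial_factor(self):
        """Permuting the survey order of the counts (constant c, d, full
        design) shifts the log likelihood by exactly the multinomial
        cell-weight difference; the n_i marginal term is invariant because
        the total capture probability is unchanged."""
        rng = np.random.default_rng(3)
        T, P = 5, 2
        design = SurveyDesign.constant(T, P)
        y = rng.poisson(2.0, size=(T, P))
        perm = rng.permutation(T)
        params = ModelParams(c_const=0.4, d_const=0.05, mu=8.0, sigma=1.0)
        c, d = effective_probs(params, design)
        from eradimix import removal_probabilities as rprob
        from scipy.special import xlogy

        log_pi = np.log(rprob(c, d).pi_prime)
        ll1 = marginal_loglik(params, design, CountData(y=y))
        ll2 = marginal_loglik(params, design, CountData(y=y[perm]))
        predicted = (xlogy(y[perm], np.exp(log_pi)) - xlogy(y, np.exp(log_pi))).sum()
        assert ll2 - ll1 == pytest.approx(predicted, abs=1e-9)


class TestDomainTypes:
    def test_design_rejects_non_binary(self):
        with pytest.raises(ValueError, match="hold"):
            SurveyDesign(hold=np.array([[2]]), chem=np.array([[1]]))

    def test_design_rejects_bad_temperature_length(self):
        with pytest.raises(ValueError, match="temperature"):
            SurveyDesign.constant(3, 2, temperature=np.array([1.0, 2.0]))

    def test_counts_derive_and_check_totals(self):
        y = np.array([[1, 0], [2, 3]])
        data = CountData(y=y)
        assert np.array_equal(data.n, [3, 3])
        with pytest.raises(ValueError, match="column sums"):
            CountData(y=y, n=np.array([3, 4]))

    def test_params_validate_ranges(self):
        with pytest.raises(ValueError):
            ModelParams(c_const=1.5)
        with pytest.raises(ValueError):
            ModelParams(mu=-1.0)
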