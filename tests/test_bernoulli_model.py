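import numpy as np
import pytest

import thintail as tt
from thintail.bernoulli_model import (
    batch_moments,
    enumeration_moments_slow,
    oracle_moments,
)
from thintail.word_stats import ball_codes, encode


@pytest.fixture
def binary_comp():
    # a two-letter alphabet embedded in ACGT: G and T never occur
    return tt.CompositionModel.from_probs(0.6, 0.4, 0.0, 0.0)


class TestWordProbability:
    def test_uniform_product(self, uniform):
        assert tt.word_probability("AAAAA", uniform) == pytest.approx(4.0**-5)

    def test_zero_factor(self):
        c = tt.CompositionModel.from_probs(1.0, 0.0, 0.0, 0.0)
        assert tt.word_probability("ACGTA", c) == 0.0

    def test_single_letter(self):
        c = tt.CompositionModel.from_probs(0.5, 0.2, 0.2, 0.1)
        assert tt.word_probability("A", c) == 0.5


class TestExpectation:
    def test_closed_form_worked_example(self, uniform):
        ws = tt.hamming_ball("ACGAC", 1)
        assert tt.set_expectation(ws, uniform, 12) == pytest.approx(8 * 16 / 1024)

    def test_single_window(self, uniform):
        ws = tt.hamming_ball("GATTA", 1)
        assert tt.set_expectation(ws, uniform, 5) == pytest.approx(16 / 1024)

    def test_L_shorter_than_m_is_error(self, uniform):
        with pytest.raises(ValueError):
            tt.set_expectation(tt.hamming_ball("ACGAC", 1), uniform, 4)


class TestVariance:
    def test_single_window_is_bernoulli(self, uniform):
        ws = tt.hamming_ball("ACGTA", 1)
        P = sum(tt.word_probability(w, uniform) for w in ws.members)
        assert tt.set_variance(ws, uniform, 5) == pytest.approx(P * (1 - P))

    def test_self_overlapping_word_has_inflated_variance(self, uniform):
        # AAAAA overlaps itself at every shift; ACGTA at none. Equal expectation,
        # so the difference is pure overlap covariance. Both sides were verified
        # against the enumeration oracle at L=8 before freezing this assertion.
        va = tt.set_variance(tt.hamming_ball("AAAAA", 0), uniform, 50)
        vb = tt.set_variance(tt.hamming_ball("ACGTA", 0), uniform, 50)
        assert va > vb

    def test_variance_nonnegative_and_linear_growth(self, uniform):
        ws = tt.hamming_ball("ACGAC", 1)
        v = [tt.set_variance(ws, uniform, L) for L in (2000, 4000, 8000)]
        assert all(x > 0 for x in v)
        # slope stabilizes: V ~ const * L for large L
        s1 = (v[1] - v[0]) / 2000
        s2 = (v[2] - v[1]) / 4000
        assert s1 == pytest.approx(s2, rel=1e-3)


class TestOracleEquivalence:
    """Analytic moments vs exhaustive enumeration on small instances."""

    def test_two_letter_toy_case(self, binary_comp):
        # {AA} at L=3 over {A,C}: E = 2 * 0.36 = 0.72 by hand
        ws = tt.WordSet(seed="AA", j=0, members=frozenset({"AA"}))
        om = oracle_moments(ws, binary_comp, 3, alphabet="AC")
        assert om.expectation == pytest.approx(2 * 0.6**2)
        assert tt.set_expectation(ws, binary_comp, 3) == pytest.approx(om.expectation)
        assert tt.set_variance(ws, binary_comp, 3) == pytest.approx(om.variance)

    def test_oracle_agrees_with_slow_enumeration(self, binary_comp, uniform):
        # the vectorized oracle is pinned to a per-sequence scan through
        # count_set_occurrences on tiny instances
        for ws, c, L, alpha in [
            (tt.hamming_ball("AC", 1), uniform, 5, "ACGT"),
            (tt.WordSet(seed="AAC", j=0, members=frozenset({"AAC", "CCA"})), binary_comp, 7, "AC"),
        ]:
            fast = oracle_moments(ws, c, L, alphabet=alpha)
            slow = enumeration_moments_slow(ws, c, L, alphabet=alpha)
            assert fast.expectation == pytest.approx(slow.expectation, abs=1e-12)
            assert fast.variance == pytest.approx(slow.variance, abs=1e-12)

    @pytest.mark.parametrize("trial", range(40))
    def test_randomized_small_instances(self, trial):
        rng = np.random.default_rng(1000 + trial)
        binary = rng.random() < 0.5
        if binary:
            alphabet = "AC"
            p = rng.uniform(0.2, 0.8)
            c = tt.CompositionModel.from_probs(p, 1 - p, 0.0, 0.0)
            L = int(rng.integers(2, 13))
        else:
            alphabet = "ACGT"
            probs = rng.dirichlet([5, 5, 5, 5])
            c = tt.CompositionModel({b: probs[i] for i, b in enumerate("ACGT")})
            L = int(rng.integers(2, 9))
        m = int(rng.integers(2, min(5, L) + 1))
        j = int(rng.integers(0, 2))
        seed = "".join(rng.choice(list(alphabet), m))
        ws = tt.hamming_ball(seed, j)
        om = oracle_moments(ws, c, L, alphabet=alphabet)
        assert tt.set_expectation(ws, c, L) == pytest.approx(om.expectation, abs=1e-9)
        assert tt.set_variance(ws, c, L) == pytest.approx(om.variance, abs=1e-9)

    def test_guard_rejects_huge_instances(self, uniform):
        with pytest.raises(ValueError, match="enumeration guard"):
            oracle_moments(tt.hamming_ball("ACGAC", 0), uniform, 20)


class TestBatchMoments:
    def test_batch_equals_reference_implementation(self, uniform):
        rng = np.random.default_rng(3)
        seeds = ["".join(rng.choice(list("ACGT"), 5)) for _ in range(25)]
        codes = np.stack([encode(s) for s in seeds])
        members = ball_codes(codes, 1)
        E, V = batch_moments(members, uniform.as_array(), 300)
        for k, s in enumerate(seeds):
            ws = tt.hamming_ball(s, 1)
            assert E[k] == pytest.approx(tt.set_expectation(ws, uniform, 300), rel=1e-12)
            assert V[k] == pytest.approx(tt.set_variance(ws, uniform, 300), rel=1e-10)

    def test_self_only_covariance_variant(self, uniform):
        rng = np.random.default_rng(4)
        seeds = ["AAAAA", "ACGTA", "TATAT"]
        codes = np.stack([encode(s) for s in seeds])
        members = ball_codes(codes, 1)
        _, V_full = batch_moments(members, uniform.as_array(), 200, include_cross=True)
        _, V_self = batch_moments(members, uniform.as_array(), 200, include_cross=False)
        for k, s in enumerate(seeds):
            ws = tt.hamming_ball(s, 1)
            assert V_self[k] == pytest.approx(tt.set_variance(ws, uniform, 200, include_cross=False), rel=1e-10)
        assert not np.allclose(V_full, V_self)


class TestMonteCarloConsistency:
    def test_sample_moments_match_analytic(self, uniform):
        # empirical mean/variance of the set count over simulated Bernoulli
        # sequences must sit within 3 standard errors of the analytic E and V
        ws = tt.hamming_ball("ACGAC", 1)
        L, n_sim = 2000, 5000
        E = tt.set_expectation(ws, uniform, L)
        V = tt.set_variance(ws, uniform, L)
        rng = np.random.default_rng(2024)
        member_codes = np.sort(
            np.array([sum("ACGT".index(ch) * 4**i for i, ch in enumerate(w[::-1])) for w in ws.members])
        )
        pow4 = 4 ** np.arange(4, -1, -1, dtype=np.int64)
        counts = np.empty(n_sim)
        for i in range(n_sim):
            codes = rng.integers(0, 4, L)
            win = np.lib.stride_tricks.sliding_window_view(codes, 5).astype(np.int64) @ pow4
            counts[i] = np.isin(win, member_codes).sum()
        se_mean = np.sqrt(V / n_sim)
        assert abs(counts.mean() - E) < 3 * se_mean
        # SE of a sample variance ~ V * sqrt(2/(n-1)) for near-normal counts
        se_var = V * np.sqrt(2.0 / (n_sim - 1))
        assert abs(counts.var(ddof=1) - V) < 3 * se_var
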