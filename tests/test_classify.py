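import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holosep import (
    InvalidParameterError,
    KmerCountTable,
    ReadFragment,
    build_rank_index,
    expected_kmer_observance,
    fragment_likelihood,
    init_priors,
    posterior_symbiont,
    score_fragments,
    scores_to_frame,
)

probs = st.floats(0.0, 1.0, allow_nan=False)


def _toy_table(occs):
    """Per-strand 1-mer table so that sequence letters index occurrences
    directly: A, C, G, T get the given counts."""
    return KmerCountTable(
        k=1, canonical=False,
        codes=np.arange(4, dtype=np.int64),
        code_counts=np.asarray(occs, dtype=np.int64),
    )


class TestPriors:
    def test_equal_sizes_give_even_prior(self):
        assert init_priors(3e6, 3e6).prior_q == pytest.approx(0.5)

    def test_size_proportionality(self):
        p = init_priors(9e6, 1e6)
        assert p.prior_q == pytest.approx(0.1)
        assert p.prior_q + p.prior_s == pytest.approx(1.0)

    @pytest.mark.parametrize("s,q", [(0, 1e6), (1e6, -5)])
    def test_nonpositive_sizes_rejected(self, s, q):
        with pytest.raises(InvalidParameterError):
            init_priors(s, q)


class TestExpectedObservance:
    def test_worked_substitution(self):
        assert expected_kmer_observance(
            1, 1, 1000, 100, 0.5, 100_000, 10_000
        ) == pytest.approx(5.5)

    def test_pure_host_mixture_drops_symbiont_term(self):
        val = expected_kmer_observance(2, 7, 1000, 100, 1.0, 50_000, 5_000)
        assert val == pytest.approx(2 * 1000 * 100 / 50_000)

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(InvalidParameterError):
            expected_kmer_observance(1, 1, 1000, 100, 1.5, 1e5, 1e4)


class TestFragmentLikelihood:
    def test_max_occurrence_kmers_score_one(self):
        table = _toy_table([1, 2, 10, 10])
        index = build_rank_index(table)
        frag = ReadFragment(id="f", seq1="GT")
        assert fragment_likelihood(frag, table, index, "symbiont") == 1.0

    def test_mean_of_two_tails(self):
        # C sits at occurrence 2 (cdf 0.5), G at 10 (cdf 1.0): mean 0.75
        table = _toy_table([1, 2, 10, 10])
        index = build_rank_index(table)
        frag = ReadFragment(id="f", seq1="CG")
        assert fragment_likelihood(frag, table, index, "symbiont") == 0.75

    def test_total_ties_score_one_under_both_origins(self):
        table = _toy_table([4, 4, 4, 4])
        index = build_rank_index(table)
        frag = ReadFragment(id="f", seq1="ACGT")
        assert fragment_likelihood(frag, table, index, "symbiont") == 1.0
        assert fragment_likelihood(frag, table, index, "host") == 1.0

    def test_mates_are_pooled(self):
        table = _toy_table([1, 2, 10, 10])
        index = build_rank_index(table)
        paired = ReadFragment(id="f", seq1="C", seq2="G")
        joint = ReadFragment(id="f", seq1="CG")
        assert fragment_likelihood(
            paired, table, index, "symbiont"
        ) == fragment_likelihood(joint, table, index, "symbiont")

    def test_unscorable_fragment_returns_none(self):
        table = KmerCountTable(k=5, codes=np.array([0], dtype=np.int64),
                               code_counts=np.array([3], dtype=np.int64))
        index = build_rank_index(table)
        frag = ReadFragment(id="f", seq1="NNNNNNN")
        assert fragment_likelihood(frag, table, index, "symbiont") is None


class TestPosterior:
    def test_symmetry(self):
        assert posterior_symbiont(0.4, 0.4, init_priors(1, 1)) == pytest.approx(0.5)

    def test_plug_in_arithmetic(self):
        assert posterior_symbiont(1.0, 0.25, init_priors(1, 1)) == pytest.approx(0.8)

    def test_zero_numerator(self):
        assert posterior_symbiont(0.0, 0.3, init_priors(1, 1)) == 0.0

    def test_degenerate_falls_back_to_prior(self):
        params = init_priors(9, 1)
        assert posterior_symbiont(None, None, params) == params.prior_q
        assert posterior_symbiont(0.0, 0.0, params) == params.prior_q

    def test_negative_likelihood_rejected(self):
        with pytest.raises(InvalidParameterError):
            posterior_symbiont(-0.1, 0.5, init_priors(1, 1))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(lq=probs, ls=probs, q_hat=st.floats(1e3, 1e9))
    def test_host_and_symbiont_posteriors_sum_to_one(self, lq, ls, q_hat):
        params = init_priors(1e7, q_hat)
        p_sym = posterior_symbiont(lq, ls, params)
        # host posterior by the mirrored formula
        num = ls * params.prior_s
        p_host = num / (num + lq * params.prior_q) if (lq or ls) else params.prior_s
        assert p_sym + p_host == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(lq1=probs, lq2=probs, ls=st.floats(1e-6, 1.0))
    def test_monotone_in_symbiont_likelihood(self, lq1, lq2, ls):
        params = init_priors(5e6, 1e6)
        lo, hi = sorted([lq1, lq2])
        assert (posterior_symbiont(lo, ls, params)
                <= posterior_symbiont(hi, ls, params) + 1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(lq=st.floats(1e-6, 1.0), ls=st.floats(1e-6, 1.0),
           c=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, lq, ls, c):
        params = init_priors(5e6, 1e6)
        assert posterior_symbiont(lq, ls, params) == pytest.approx(
            posterior_symbiont(c * lq, c * ls, params), rel=1e-9
        )


class TestScoreFragments:
    @pytest.fixture()
    def toy(self):
        table = _toy_table([1, 2, 10, 10])
        return table, build_rank_index(table)

    def test_degenerate_fragment_scored_at_prior(self, toy):
        table, index = toy
        params = init_priors(9, 1)
        (score,) = score_fragments(
            [ReadFragment(id="x", seq1="NN")], table, index, params
        )
        assert score.degenerate and score.m == 0
        assert score.posterior_q == params.prior_q
        assert math.isnan(score.like_q)

    def test_sum_mode_matches_manual_composition(self, toy):
        table, index = toy
        params = init_priors(2, 1)
        frag = ReadFragment(id="x", seq1="CG")
        (score,) = score_fragments([frag], table, index, params)
        lq = fragment_likelihood(frag, table, index, "symbiont")
        ls = fragment_likelihood(frag, table, index, "host")
        assert score.m == 2
        assert score.posterior_q == pytest.approx(
            posterior_symbiont(lq, ls, params)
        )

    def test_product_mode_stays_in_unit_interval_and_orders_like_sum(self, toy):
        table, index = toy
        params = init_priors(2, 1)
        frags = [ReadFragment(id="hi", seq1="GGTT"),
                 ReadFragment(id="lo", seq1="AACC")]
        for mode in ("sum", "product"):
            hi, lo = score_fragments(frags, table, index, params,
                                     likelihood=mode)
            assert 0.0 <= lo.posterior_q <= hi.posterior_q <= 1.0

    def test_frame_columns(self, toy):
        table, index = toy
        params = init_priors(2, 1)
        frame = scores_to_frame(
            score_fragments([ReadFragment(id="x", seq1="CG")],
                            table, index, params)
        )
        assert list(frame.columns) == [
            "id", "m", "like_q", "like_s", "posterior_q", "degenerate"
        ]
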