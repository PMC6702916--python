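import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holosep import (
    EmptyIndexError,
    InvalidParameterError,
    KmerCountTable,
    build_rank_index,
    count_kmers,
    rank_tail_probability,
    reverse_complement,
)
from conftest import naive_kmer_counts

dna = st.text(alphabet="ACGT", min_size=0, max_size=200)
dna_n = st.text(alphabet="ACGTN", min_size=0, max_size=200)


@pytest.mark.parametrize(
    "reads,k,expected",
    [
        (["ACGT"], 3, {"ACG": 2}),  # ACG and CGT are reverse complements
        (["AC"], 3, {}),            # read shorter than k
        (["ACGNACG"], 3, {"ACG": 2}),  # N-containing windows skipped
        ([], 5, {}),                # empty stream is a valid empty table
        (["acgt"], 3, {"ACG": 2}),  # case-insensitive
    ],
)
def test_count_kmers_examples(reads, k, expected):
    table = count_kmers(reads, k)
    assert table.counts == expected
    assert table.n_distinct == len(expected)
    assert table.n_total == sum(expected.values())


def test_count_kmers_rejects_nonpositive_k():
    with pytest.raises(InvalidParameterError):
        count_kmers(["ACGT"], 0)


def test_table_invariants_on_random_reads():
    rng = np.random.default_rng(0)
    reads = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(20)]
    table = count_kmers(reads, 5)
    for kmer, n in table.counts.items():
        assert len(kmer) == 5 and set(kmer) <= set("ACGT")
        assert kmer == min(kmer, reverse_complement(kmer))
        assert n >= 1
    assert sum(table.counts.values()) == table.n_total
    assert len(table.counts) == table.n_distinct


@settings(max_examples=50, deadline=None, derandomize=True)
@given(reads=st.lists(dna_n, max_size=8), k=st.sampled_from([3, 5, 21]))
def test_count_kmers_matches_naive_oracle(reads, k):
    assert count_kmers(reads, k).counts == naive_kmer_counts(reads, k)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(read=dna, k=st.sampled_from([3, 7]))
def test_reverse_complement_counting_invariance(read, k):
    fwd = count_kmers([read], k).counts
    rev = count_kmers([reverse_complement(read)], k).counts
    assert fwd == rev


def test_noncanonical_counting_keeps_strands_apart():
    table = count_kmers(["ACGT"], 3, canonical=False)
    assert table.counts == {"ACG": 1, "CGT": 1}


def test_min_count_drops_singletons():
    table = count_kmers(["AAAT", "AAA"], 3, min_count=2)
    assert table.counts == {"AAA": 2}  # AAT seen once, dropped


def _index_from_occurrences(occs):
    codes = np.arange(len(occs), dtype=np.int64)
    table = KmerCountTable(k=3, codes=codes,
                           code_counts=np.asarray(occs, dtype=np.int64))
    return build_rank_index(table)


def test_rank_index_example():
    idx = _index_from_occurrences([10, 10, 2, 1])
    assert idx.cdf_leq == {1: 0.25, 2: 0.5, 10: 1.0}
    assert idx.sf_geq == {1: 1.0, 2: 0.75, 10: 0.5}


@pytest.mark.parametrize("occs", [[7], [4, 4, 4]])
def test_rank_index_degenerate_distributions(occs):
    idx = _index_from_occurrences(occs)
    level = occs[0]
    assert idx.cdf_leq[level] == 1.0
    assert idx.sf_geq[level] == 1.0


def test_rank_index_tail_complementarity():
    idx = _index_from_occurrences([10, 10, 2, 1, 5, 5, 5])
    fracs = dict(zip(idx.occurrence_levels.tolist(),
                     idx.level_fractions.tolist()))
    for o in idx.occurrence_levels.tolist():
        assert idx.cdf_leq[o] + idx.sf_geq[o] - fracs[o] == pytest.approx(1.0)


def test_empty_table_has_no_rank_index():
    with pytest.raises(EmptyIndexError):
        build_rank_index(count_kmers([], 3))


@pytest.mark.parametrize(
    "o,origin,expected",
    [
        (10, "symbiont", 1.0),
        (1, "symbiont", 0.25),
        (1, "host", 1.0),
        (2, "symbiont", 0.5),
        (5, "symbiont", 0.5),  # between levels: step resolves downward
        (10, "host", 0.5),
    ],
)
def test_rank_tail_probability_examples(o, origin, expected):
    idx = _index_from_occurrences([10, 10, 2, 1])
    assert rank_tail_probability(idx, o, origin) == pytest.approx(expected)


def test_rank_tail_direction_flag_swaps_tails():
    idx = _index_from_occurrences([10, 10, 2, 1])
    assert rank_tail_probability(
        idx, 1, "symbiont", rank_direction="freq-low-first"
    ) == rank_tail_probability(idx, 1, "host")


def test_rank_tail_monotonicity():
    rng = np.random.default_rng(1)
    idx = _index_from_occurrences(rng.integers(1, 40, size=200))
    grid = np.arange(1, 45)
    sym = [rank_tail_probability(idx, o, "symbiont") for o in grid]
    host = [rank_tail_probability(idx, o, "host") for o in grid]
    assert all(a <= b + 1e-12 for a, b in zip(sym, sym[1:]))
    assert all(a >= b - 1e-12 for a, b in zip(host, host[1:]))


def test_below_minimum_occurrence_clamps_with_warning():
    idx = _index_from_occurrences([5, 5, 9])
    with pytest.warns(UserWarning):
        assert rank_tail_probability(idx, 1, "symbiont") == pytest.approx(2 / 3)
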