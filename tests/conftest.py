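import numpy as np
import pytest

import holosep as hs
from holosep.kmer_index import build_rank_index, count_kmers


def naive_kmer_counts(reads, k, canonical=True):
    """Brute-force dictionary counter: the counting oracle."""
    counts = {}
    for read in reads:
        read = read.upper()
        for i in range(len(read) - k + 1):
            w = read[i : i + k]
            if set(w) <= set("ACGT"):
                if canonical:
                    w = min(w, hs.reverse_complement(w))
                counts[w] = counts.get(w, 0) + 1
    return counts


def best_contiguous_split_inertia(values):
    """Exhaustive 1-D 2-cluster optimum: the K-means oracle.

    The 2-means optimum in one dimension is a contiguous split of the sorted
    values; try all n-1 splits and return the minimal SSE.
    """
    v = np.sort(np.asarray(values, dtype=float))
    best = np.inf
    for cut in range(1, v.size):
        lo, hi = v[:cut], v[cut:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        best = min(best, sse)
    return best


def fragment_seqs(fragments):
    for f in fragments:
        yield f.seq1
        if f.seq2 is not None:
            yield f.seq2


@pytest.fixture(scope="session")
def preset_dataset():
    """The default desk-scale mixture: 200 kb host, 20 kb symbiont, 20 k
    pairs of 2x100 bp at R=0.5 — a 10x coverage asymmetry."""
    return hs.simulate_reads()


@pytest.fixture(scope="session")
def preset_counts(preset_dataset):
    table = count_kmers(fragment_seqs(preset_dataset.fragments), 21)
    return table, build_rank_index(table)


@pytest.fixture(scope="session")
def preset_separation(preset_dataset, preset_counts):
    table, index = preset_counts
    return hs.separate_fragments(
        preset_dataset.fragments,
        host_size=preset_dataset.params.s,
        symbiont_size=preset_dataset.params.q,
        table=table, index=index,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A lighter mixture for I/O and CLI tests (same 10x coverage ratio)."""
    return hs.simulate_reads(s=20_000, q=2_000, n_fragments=2_000,
                             read_length=50, insert=150, seed=7)
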