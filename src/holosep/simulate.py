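"""Synthetic holobiont mixtures with known truth labels.

The generator emulates the premise the classifier exploits: one large host
genome and one much smaller symbiont genome sequenced uniformly in a single
library, so that at comparable read mass the symbiont sits at far higher
coverage and the k-mer occurrence spectrum of the pooled reads is bimodal.

Fragments are paired-end: mate 1 reads the insert's 5' end on the forward
strand, mate 2 the 3' end reverse-complemented. Errors are i.i.d.
substitutions; indels and quality modeling are out of scope. Every quantity
is driven by one seed, so outputs are reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .classify import ReadFragment, expected_kmer_observance
from .errors import InvalidParameterError
from .kmer_index import KmerCountTable, count_kmers, reverse_complement

__all__ = [
    "SimulationParams",
    "SyntheticDataset",
    "simulate_genome",
    "simulate_reads",
    "single_copy_symbiont_check",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationParams:
    """Desk-scale defaults: a 200 kb host and 20 kb symbiont stand in for the
    snail-scale originals, 20k pairs of 2x100 bp at insert 300 with the host
    contributing half the base pairs — a 10x coverage asymmetry."""

    s: int = 200_000              # host genome size, bp
    q: int = 20_000               # symbiont genome size, bp
    n_fragments: int = 20_000     # read pairs
    read_length: int = 100        # l, bp per mate
    insert: int = 300             # outer fragment span, bp
    host_fraction: float = 0.5    # R: expected fraction of bp from the host
    error_rate: float = 0.0       # per-base substitution probability
    gc_host: float = 0.41
    gc_symbiont: float = 0.43
    seed: int = 42


@dataclass
class SyntheticDataset:
    host_genome: str
    symbiont_genome: str
    fragments: List[ReadFragment]
    truth: Dict[str, str]         # fragment id -> "host" | "symbiont"
    params: SimulationParams = field(default_factory=SimulationParams)


def simulate_genome(length: int, gc: float = 0.5, seed: int | None = None,
                    rng: np.random.Generator | None = None) -> str:
    """I.i.d. random genome with P(G)+P(C)=gc, G/C and A/T equiprobable."""
    if length < 1:
        raise InvalidParameterError(f"genome length must be >= 1, got {length}")
    if not 0.0 <= gc <= 1.0:
        raise InvalidParameterError(f"gc must be in [0,1], got {gc}")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=length, p=p)
    return _BASES[draws].tobytes().decode("ascii")


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < error_rate)[0]
    if hit.size:
        # substitute with one of the three other bases
        cur = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(cur + rng.integers(1, 4, size=hit.size)) % 4]
    return arr.tobytes().decode("ascii")


def simulate_reads(
    params: SimulationParams | None = None, **overrides
) -> SyntheticDataset:
    """Draw a paired-end read mixture with truth labels.

    Each fragment's origin is host with probability ``host_fraction`` (per-
    fragment and per-base-pair host fractions coincide because read length is
    constant); its start is uniform over the origin genome; mate 2 is the
    reverse complement of the insert's far end.
    """
    if params is None:
        params = SimulationParams(**overrides)
    elif overrides:
        raise InvalidParameterError("pass either params or keyword overrides")
    p = params
    if p.insert < p.read_length:
        raise InvalidParameterError("insert size must be >= read length")
    if min(p.s, p.q) <= p.insert:
        raise InvalidParameterError("both genomes must be longer than the insert")
    if not 0.0 <= p.host_fraction <= 1.0:
        raise InvalidParameterError("host_fraction must be in [0,1]")
    if not 0.0 <= p.error_rate < 1.0:
        raise InvalidParameterError("error_rate must be in [0,1)")
    rng = np.random.default_rng(p.seed)
    host = simulate_genome(p.s, p.gc_host, rng=rng)
    symbiont = simulate_genome(p.q, p.gc_symbiont, rng=rng)
    genomes = {"host": host, "symbiont": symbiont}
    is_host = rng.random(p.n_fragments) < p.host_fraction
    l = p.read_length
    fragments: List[ReadFragment] = []
    truth: Dict[str, str] = {}
    qual = "I" * l
    for i in range(p.n_fragments):
        origin = "host" if is_host[i] else "symbiont"
        g = genomes[origin]
        start = int(rng.integers(0, len(g) - p.insert + 1))
        mate1 = g[start : start + l]
        mate2 = reverse_complement(g[start + p.insert - l : start + p.insert])
        mate1 = _mutate(mate1, p.error_rate, rng)
        mate2 = _mutate(mate2, p.error_rate, rng)
        fid = f"frag{i:06d}"
        fragments.append(ReadFragment(id=fid, seq1=mate1, seq2=mate2,
                                      qual1=qual, qual2=qual))
        truth[fid] = origin
    return SyntheticDataset(
        host_genome=host, symbiont_genome=symbiont,
        fragments=fragments, truth=truth, params=p,
    )


def single_copy_symbiont_check(
    dataset: SyntheticDataset, table: KmerCountTable
) -> Tuple[float, float, float, int]:
    """Monte-Carlo cross-check of the expected-observance model.

    Finds k-mers occurring exactly once in the symbiont genome and never in
    the host genome, and compares their mean occurrence in the read table
    against the expected-observance formula. Reads of length l contribute
    l-k+1 k-mer tokens each and the genome offers q-k+1 k-mer positions, so
    the formula is evaluated with those effective lengths (at error rate 0
    the token accounting is then exact).

    Returns (empirical_mean, expected, standard_error, n_single_copy).
    """
    p = dataset.params
    k = table.k
    sym_table = count_kmers([dataset.symbiont_genome], k,
                            canonical=table.canonical)
    host_table = count_kmers([dataset.host_genome], k,
                             canonical=table.canonical)
    single = sym_table.codes[sym_table.code_counts == 1]
    in_host = np.isin(single, host_table.codes)
    single = single[~in_host]
    if single.size == 0:
        raise InvalidParameterError("no single-copy symbiont k-mers found")
    pos = np.searchsorted(table.codes, single)
    pos = np.minimum(pos, max(table.codes.size - 1, 0))
    hit = table.codes.size > 0
    occ = np.where(
        hit & (table.codes[pos] == single), table.code_counts[pos], 0
    ).astype(float)
    n_sym = sum(1 for v in dataset.truth.values() if v == "symbiont")
    realized_r = 1.0 - n_sym / p.n_fragments
    expected = expected_kmer_observance(
        n_s=0.0, n_q=1.0,
        n=2 * p.n_fragments,            # mates, each of effective length l-k+1
        l=p.read_length - k + 1,
        r=realized_r,
        s=float(p.s), q=float(p.q - k + 1),
    )
    se = float(np.std(occ, ddof=1) / np.sqrt(occ.size))
    return float(np.mean(occ)), float(expected), se, int(single.size)
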