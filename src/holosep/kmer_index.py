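"""Canonical k-mer counting and the occurrence-rank index.

The classifier rests on the k-mer occurrence spectrum of the whole read set:
reads from a small, high-coverage symbiont genome carry k-mers that recur many
times, while reads from the large, low-coverage host genome carry rare k-mers.
This module counts k-mers (strand-merged by default, as read orientation is
arbitrary) and converts an occurrence count into a rank-tail probability —
the fraction of distinct k-mers no more (or no less) frequent than a given one.

k-mers are packed into 2-bit-per-base integers so that counting a read set of
~10^7 tokens fits comfortably in memory and runs vectorized in numpy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Dict, Iterable, Mapping

import numpy as np

from .errors import EmptyIndexError, InvalidParameterError

__all__ = [
    "KmerCountTable",
    "RankIndex",
    "count_kmers",
    "build_rank_index",
    "rank_tail_probability",
    "reverse_complement",
]

# base -> 2-bit code; anything else (incl. N) maps to -1 and poisons its windows
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _b, _v in zip(b"ACGT", range(4)):
    _BASE_CODE[_b] = _v
    _BASE_CODE[_b + 32] = _v  # lowercase

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode_bases(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def _window_codes(bases: np.ndarray, k: int, canonical: bool) -> np.ndarray:
    """2-bit integer codes of all valid (N-free) length-k windows.

    Runs in O(n·k) with O(n) memory: k strided adds instead of an explicit
    (n, k) window matrix.
    """
    n = bases.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    nwin = n - k + 1
    invalid = bases < 0
    clean = np.where(invalid, 0, bases).astype(np.int64)
    fwd = np.zeros(nwin, dtype=np.int64)
    rev = np.zeros(nwin, dtype=np.int64)
    for j in range(k):
        col = clean[j : j + nwin]
        fwd += col << (2 * (k - 1 - j))
        rev += (3 - col) << (2 * j)
    # window is valid iff it contains no invalid base
    bad = np.cumsum(np.concatenate(([0], invalid.astype(np.int64))))
    ok = (bad[k:] - bad[:-k]) == 0
    codes = np.minimum(fwd, rev) if canonical else fwd
    return codes[ok]


def _decode(code: int, k: int) -> str:
    out = []
    for j in range(k):
        out.append("ACGT"[(code >> (2 * (k - 1 - j))) & 3])
    return "".join(out)


@dataclass
class KmerCountTable:
    """Occurrence counts of distinct (canonical) k-mers over a read set.

    Counts are stored as parallel sorted arrays of 2-bit codes and counts;
    the string-keyed :attr:`counts` mapping is materialized lazily.
    """

    k: int
    canonical: bool = True
    codes: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    code_counts: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    @property
    def n_distinct(self) -> int:
        return int(self.codes.size)

    @property
    def n_total(self) -> int:
        return int(self.code_counts.sum())

    @cached_property
    def counts(self) -> Dict[str, int]:
        """Mapping canonical k-mer string -> occurrence count."""
        return {
            _decode(int(c), self.k): int(n)
            for c, n in zip(self.codes, self.code_counts)
        }

    def sequence_occurrences(self, seq: str) -> np.ndarray:
        """Occurrence counts of the k-mers of ``seq`` found in the table.

        k-mers absent from the table (or windows containing N) are dropped.
        """
        codes = _window_codes(_encode_bases(seq), self.k, self.canonical)
        if codes.size == 0 or self.codes.size == 0:
            return np.empty(0, dtype=np.int64)
        pos = np.searchsorted(self.codes, codes)
        pos = np.minimum(pos, self.codes.size - 1)
        hit = self.codes[pos] == codes
        return self.code_counts[pos[hit]]

    def occurrence_of(self, kmer: str) -> int:
        """Occurrence count of one k-mer string (0 if absent)."""
        if len(kmer) != self.k:
            raise InvalidParameterError(
                f"k-mer length {len(kmer)} != table k={self.k}"
            )
        occ = self.sequence_occurrences(kmer)
        return int(occ[0]) if occ.size else 0


def count_kmers(
    reads: Iterable[str],
    k: int,
    *,
    canonical: bool = True,
    min_count: int = 1,
) -> KmerCountTable:
    """Count canonical k-mers across a stream of DNA sequences.

    Every N-free window of length ``k`` contributes one token to its canonical
    form (lexicographic minimum of the window and its reverse complement, which
    coincides with the numeric minimum under the A<C<G<T 2-bit encoding).
    Reads shorter than ``k`` contribute nothing. ``min_count`` drops k-mers
    rarer than the threshold after counting (1 keeps everything).
    """
    if k <= 0:
        raise InvalidParameterError(f"k must be a positive integer, got {k}")
    if 2 * k > 62:
        raise InvalidParameterError(f"k={k} exceeds the 31-base packing limit")
    chunks = []
    buf: list[str] = []
    buf_len = 0
    for seq in reads:
        buf.append(seq)
        buf_len += len(seq)
        if buf_len >= 4_000_000:
            chunks.append(_window_codes(_encode_bases("N".join(buf)), k, canonical))
            buf, buf_len = [], 0
    if buf:
        chunks.append(_window_codes(_encode_bases("N".join(buf)), k, canonical))
    if chunks:
        codes, counts = np.unique(np.concatenate(chunks), return_counts=True)
    else:
        codes = np.empty(0, dtype=np.int64)
        counts = np.empty(0, dtype=np.int64)
    if min_count > 1:
        keep = counts >= min_count
        codes, counts = codes[keep], counts[keep]
    return KmerCountTable(k=k, canonical=canonical, codes=codes,
                          code_counts=counts)


@dataclass
class RankIndex:
    """Cumulative rank-tail fractions over distinct k-mer occurrence levels.

    ``cdf_leq(o)`` is the fraction of distinct k-mers with occurrence <= o;
    ``sf_geq(o)`` the fraction with occurrence >= o. Tied occurrences share a
    rank: both tails count every tied k-mer. Fractions are over distinct
    k-mers, not k-mer tokens.
    """

    occurrence_levels: np.ndarray
    level_fractions: np.ndarray  # fraction of distinct k-mers at each level

    def __post_init__(self) -> None:
        self._cdf = np.cumsum(self.level_fractions)
        self._sf = np.cumsum(self.level_fractions[::-1])[::-1]

    @property
    def cdf_leq(self) -> Mapping[int, float]:
        return dict(zip(self.occurrence_levels.tolist(), self._cdf.tolist()))

    @property
    def sf_geq(self) -> Mapping[int, float]:
        return dict(zip(self.occurrence_levels.tolist(), self._sf.tolist()))

    def _level_pos(self, o: np.ndarray) -> np.ndarray:
        # step function: occurrence between levels resolves to the level below
        pos = np.searchsorted(self.occurrence_levels, o, side="right") - 1
        if np.any(pos < 0):
            warnings.warn(
                "occurrence below the minimum indexed level; clamping "
                "(reads and index appear mismatched)",
                stacklevel=3,
            )
            pos = np.maximum(pos, 0)
        return pos

    def tail(self, o: np.ndarray | int, origin: str) -> np.ndarray | float:
        """Vectorized rank-tail probability; see :func:`rank_tail_probability`."""
        arr = np.atleast_1d(np.asarray(o, dtype=np.int64))
        pos = self._level_pos(arr)
        out = self._cdf[pos] if origin == "symbiont" else self._sf[pos]
        return float(out[0]) if np.isscalar(o) or np.asarray(o).ndim == 0 else out


def build_rank_index(table: KmerCountTable) -> RankIndex:
    """Build the rank-tail index over the distinct k-mers of ``table``."""
    if table.n_distinct == 0:
        raise EmptyIndexError(
            "cannot build a rank index from an empty k-mer table"
        )
    levels, level_counts = np.unique(table.code_counts, return_counts=True)
    return RankIndex(
        occurrence_levels=levels.astype(np.int64),
        level_fractions=level_counts / table.n_distinct,
    )


def rank_tail_probability(
    index: RankIndex,
    o: int,
    origin: str,
    *,
    rank_direction: str = "freq-high-first",
) -> float:
    """Rank-tail probability of occurrence ``o`` under the given origin.

    With ranks ordered most-frequent-first (the default), a symbiont-origin
    k-mer scores the fraction of distinct k-mers no more frequent than it
    (high occurrence => high symbiont tail, matching the premise that the
    small symbiont genome is sequenced at much higher coverage), and the
    host tail is the complementary fraction at least as frequent.
    ``rank_direction='freq-low-first'`` swaps the two conventions.
    """
    if origin not in ("symbiont", "host"):
        raise InvalidParameterError(f"unknown origin {origin!r}")
    if rank_direction not in ("freq-high-first", "freq-low-first"):
        raise InvalidParameterError(f"unknown rank direction {rank_direction!r}")
    if rank_direction == "freq-low-first":
        origin = "host" if origin == "symbiont" else "symbiont"
    return float(index.tail(int(o), origin))
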