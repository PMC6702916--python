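"""Bayesian scoring of read fragments against the k-mer occurrence spectrum.

A fragment (a read or a mated pair) is scored by pooling the rank-tail
probabilities of all its k-mers under each origin hypothesis and combining
them with genome-size-proportional priors:

    P(symbiont | O) = L_q * P(q) / (L_q * P(q) + L_s * P(s))

where L_q is the summed (here: mean, which cancels in the ratio) symbiont
rank-tail over the fragment's k-mers and L_s the complementary host tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .kmer_index import KmerCountTable, RankIndex

__all__ = [
    "MixtureParams",
    "ReadFragment",
    "FragmentScore",
    "init_priors",
    "expected_kmer_observance",
    "fragment_likelihood",
    "posterior_symbiont",
    "score_fragments",
    "scores_to_frame",
]


@dataclass
class MixtureParams:
    """Mixture geometry and origin priors.

    s_hat / q_hat are the (estimated) host and symbiont genome sizes in bp;
    the priors are proportional to them, reflecting that under uniform
    sequencing a fragment lands on a genome in proportion to its size at
    equal copy number. n (fragment count), l (read length in bp) and
    host_fraction (expected fraction of read base pairs from the host) are
    informational and not used in scoring.
    """

    s_hat: float
    q_hat: float
    prior_q: float
    prior_s: float
    n: Optional[int] = None
    l: Optional[int] = None
    host_fraction: Optional[float] = None


@dataclass
class ReadFragment:
    """A single read or a mated pair: the unit of classification.

    Mates of a pair are never classified separately; quality strings are
    carried only so FASTQ output can round-trip untouched.
    """

    id: str
    seq1: str
    seq2: Optional[str] = None
    qual1: Optional[str] = None
    qual2: Optional[str] = None


@dataclass
class FragmentScore:
    id: str
    m: int                      # scored k-mers, both mates pooled
    like_q: float               # mean symbiont rank-tail
    like_s: float               # mean host rank-tail
    posterior_q: float
    degenerate: bool            # no scorable k-mers; posterior fell back to prior
    median_occurrence: float    # coverage diagnostic for cluster identification


def init_priors(
    s_hat: float,
    q_hat: float,
    *,
    n: Optional[int] = None,
    l: Optional[int] = None,
    host_fraction: Optional[float] = None,
) -> MixtureParams:
    """Genome-size-proportional priors: P(q) = q_hat / (s_hat + q_hat).

    Genome sizes of the closest available relatives suffice: because the two
    genomes differ by an order of magnitude, the posterior is insensitive to
    sizeable estimation error (a property the test suite checks).
    """
    if s_hat <= 0 or q_hat <= 0:
        raise InvalidParameterError(
            f"genome sizes must be positive, got s_hat={s_hat}, q_hat={q_hat}"
        )
    prior_q = q_hat / (s_hat + q_hat)
    return MixtureParams(
        s_hat=float(s_hat), q_hat=float(q_hat),
        prior_q=prior_q, prior_s=1.0 - prior_q,
        n=n, l=l, host_fraction=host_fraction,
    )


def expected_kmer_observance(
    n_s: float, n_q: float, n: float, l: float, r: float, s: float, q: float
) -> float:
    """Expected occurrence of a k-mer in the read mixture.

    A k-mer occurring ``n_s`` times in the host genome (size ``s``) and
    ``n_q`` times in the symbiont genome (size ``q``) is expected, under
    uniform coverage by ``n`` reads of ``l`` bp of which fraction ``r`` of
    base pairs are host-derived, to be observed

        n_s * n*l*r / s  +  n_q * n*l*(1-r) / q

    times. The value is an expectation, not an integer.
    """
    if not 0.0 <= r <= 1.0:
        raise InvalidParameterError(f"host fraction r must be in [0,1], got {r}")
    if s <= 0 or q <= 0 or n <= 0 or l <= 0:
        raise InvalidParameterError("n, l, s and q must all be positive")
    if n_s < 0 or n_q < 0:
        raise InvalidParameterError("genome occurrence counts cannot be negative")
    return n_s * n * l * r / s + n_q * n * l * (1.0 - r) / q


def _fragment_occurrences(
    fragment: ReadFragment, table: KmerCountTable
) -> np.ndarray:
    occ = table.sequence_occurrences(fragment.seq1)
    if fragment.seq2 is not None:
        occ = np.concatenate([occ, table.sequence_occurrences(fragment.seq2)])
    return occ


def fragment_likelihood(
    fragment: ReadFragment,
    table: KmerCountTable,
    index: RankIndex,
    origin: str,
    *,
    rank_direction: str = "freq-high-first",
) -> Optional[float]:
    """Mean rank-tail probability over the fragment's k-mers (both mates).

    k-mers absent from the table are skipped and do not count toward m.
    Returns None when no k-mer is scorable; the caller must fall back to the
    prior.
    """
    if rank_direction == "freq-low-first":
        origin = "host" if origin == "symbiont" else "symbiont"
    occ = _fragment_occurrences(fragment, table)
    if occ.size == 0:
        return None
    return float(np.mean(index.tail(occ, origin)))


def posterior_symbiont(
    like_q: Optional[float], like_s: Optional[float], params: MixtureParams
) -> float:
    """Posterior probability of symbiont origin given the two likelihoods.

    Degenerate inputs (no scorable k-mers, or both likelihoods zero) return
    the prior. Multiplying both likelihoods by the same positive constant
    leaves the posterior unchanged, which is why reporting means rather than
    sums is posterior-neutral.
    """
    if like_q is None or like_s is None:
        return params.prior_q
    if like_q < 0 or like_s < 0:
        raise InvalidParameterError("likelihoods cannot be negative")
    num = like_q * params.prior_q
    den = num + like_s * params.prior_s
    if den == 0.0:
        return params.prior_q
    return num / den


def score_fragments(
    fragments: Iterable[ReadFragment],
    table: KmerCountTable,
    index: RankIndex,
    params: MixtureParams,
    *,
    likelihood: str = "sum",
    rank_direction: str = "freq-high-first",
) -> List[FragmentScore]:
    """Score every fragment; the pipeline workhorse.

    ``likelihood='sum'`` (default) pools per-k-mer tails additively, as the
    posterior's likelihood term; ``'product'`` multiplies them (computed in
    log space; the reported like_q/like_s are then geometric means).
    """
    if likelihood not in ("sum", "product"):
        raise InvalidParameterError(f"unknown likelihood mode {likelihood!r}")
    swap = rank_direction == "freq-low-first"
    scores: List[FragmentScore] = []
    log_pq = math.log(params.prior_q)
    log_ps = math.log(params.prior_s)
    for frag in fragments:
        occ = _fragment_occurrences(frag, table)
        m = int(occ.size)
        if m == 0:
            scores.append(FragmentScore(
                id=frag.id, m=0, like_q=math.nan, like_s=math.nan,
                posterior_q=params.prior_q, degenerate=True,
                median_occurrence=math.nan,
            ))
            continue
        tq = index.tail(occ, "symbiont")
        ts = index.tail(occ, "host")
        if swap:
            tq, ts = ts, tq
        if likelihood == "sum":
            like_q = float(np.mean(tq))
            like_s = float(np.mean(ts))
            post = posterior_symbiont(like_q, like_s, params)
        else:
            lq = float(np.sum(np.log(tq)))
            ls = float(np.sum(np.log(ts)))
            post = 1.0 / (1.0 + math.exp(
                min(700.0, max(-700.0, ls + log_ps - lq - log_pq))
            ))
            like_q = math.exp(lq / m)
            like_s = math.exp(ls / m)
        scores.append(FragmentScore(
            id=frag.id, m=m, like_q=like_q, like_s=like_s,
            posterior_q=post, degenerate=False,
            median_occurrence=float(np.median(occ)),
        ))
    return scores


def scores_to_frame(scores: Sequence[FragmentScore]) -> pd.DataFrame:
    """Tabulate scores in the column order the `classify` subcommand emits."""
    return pd.DataFrame(
        {
            "id": [s.id for s in scores],
            "m": [s.m for s in scores],
            "like_q": [s.like_q for s in scores],
            "like_s": [s.like_s for s in scores],
            "posterior_q": [s.posterior_q for s in scores],
            "degenerate": [s.degenerate for s in scores],
        }
    )
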