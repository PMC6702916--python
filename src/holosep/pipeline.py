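"""End-to-end separation: count -> score -> cluster -> call origins."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .classify import (
    FragmentScore,
    MixtureParams,
    ReadFragment,
    init_priors,
    score_fragments,
)
from .cluster import ClusterResult, identify_symbiont_cluster, kmeans_1d
from .errors import DegenerateClusteringError
from .kmer_index import KmerCountTable, RankIndex, build_rank_index, count_kmers

__all__ = ["SeparationResult", "separate_fragments", "call_origins"]


@dataclass
class SeparationResult:
    scores: List[FragmentScore]
    predicted: Dict[str, str]          # fragment id -> "host" | "symbiont"
    cluster: Optional[ClusterResult]   # None when the 0.5-threshold fallback ran
    params: MixtureParams
    warnings: List[str] = field(default_factory=list)

    def summary(self) -> dict:
        n_sym = sum(1 for v in self.predicted.values() if v == "symbiont")
        out = {
            "n_fragments": len(self.scores),
            "n_symbiont": n_sym,
            "n_host": len(self.scores) - n_sym,
            "n_degenerate": sum(s.degenerate for s in self.scores),
            "prior_q": self.params.prior_q,
            "warnings": list(self.warnings),
        }
        if self.cluster is not None:
            post = np.array([s.posterior_q for s in self.scores])
            out["cluster_mean_posteriors"] = [
                float(post[self.cluster.labels == lab].mean())
                if np.any(self.cluster.labels == lab) else None
                for lab in (0, 1)
            ]
            out["cluster_centers"] = [float(c) for c in self.cluster.centers]
            out["coverage_ratio"] = self.cluster.coverage_ratio
            out["warnings"] += self.cluster.warnings
        return out


def call_origins(
    scores: Sequence[FragmentScore],
    *,
    feature: str = "logit",
) -> tuple[Dict[str, str], Optional[ClusterResult], List[str]]:
    """Cluster posteriors (K-means, K=2) and call each fragment's origin.

    By default the clustered scalar is the posterior log-odds
    log(p/(1-p)) rather than p itself: a change of prior shifts every
    fragment's log-odds by the same constant, and 1-D K-means is
    translation-invariant, so the resulting partition — hence the final
    separation — does not depend on the genome-size priors. It also spreads
    the compressed tails of the posterior, where K-means on raw
    probabilities tends to misplace its boundary. ``feature="posterior"``
    clusters the raw probabilities. Identical values (degenerate
    clustering) fall back to a 0.5 posterior threshold with a warning.
    """
    posteriors = np.array([s.posterior_q for s in scores])
    if feature == "logit":
        p = np.clip(posteriors, 1e-12, 1.0 - 1e-12)
        values = np.log(p / (1.0 - p))
    elif feature == "posterior":
        values = posteriors
    else:
        raise ValueError(f"unknown clustering feature {feature!r}")
    warnings: List[str] = []
    try:
        result = kmeans_1d(values)
    except DegenerateClusteringError:
        warnings.append(
            "all posteriors identical; fell back to a 0.5 posterior threshold"
        )
        predicted = {
            s.id: "symbiont" if s.posterior_q > 0.5 else "host" for s in scores
        }
        return predicted, None, warnings
    sym = identify_symbiont_cluster(result, scores)
    predicted = {
        s.id: "symbiont" if lab == sym else "host"
        for s, lab in zip(scores, result.labels)
    }
    return predicted, result, warnings


def separate_fragments(
    fragments: Sequence[ReadFragment],
    *,
    host_size: float,
    symbiont_size: float,
    k: int = 21,
    canonical: bool = True,
    min_count: int = 1,
    likelihood: str = "sum",
    rank_direction: str = "freq-high-first",
    cluster_feature: str = "logit",
    table: Optional[KmerCountTable] = None,
    index: Optional[RankIndex] = None,
) -> SeparationResult:
    """Run the full separation on an in-memory fragment list.

    The k-mer spectrum is computed from the very reads being classified
    (pass a prebuilt ``table``/``index`` to reuse counts across runs).
    """
    fragments = list(fragments)
    if table is None:
        def _seqs():
            for f in fragments:
                yield f.seq1
                if f.seq2 is not None:
                    yield f.seq2
        table = count_kmers(_seqs(), k, canonical=canonical,
                            min_count=min_count)
    if index is None:
        index = build_rank_index(table)
    lens = [len(f.seq1) for f in fragments[:1000]]
    params = init_priors(
        host_size, symbiont_size, n=len(fragments),
        l=int(np.median(lens)) if lens else None,
    )
    scores = score_fragments(
        fragments, table, index, params,
        likelihood=likelihood, rank_direction=rank_direction,
    )
    predicted, cluster, warns = call_origins(scores, feature=cluster_feature)
    return SeparationResult(
        scores=scores, predicted=predicted, cluster=cluster,
        params=params, warnings=warns,
    )
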