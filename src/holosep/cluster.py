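"""1-D K-means (K=2) partitioning of posterior probabilities.

In one dimension the K-means optimum is a threshold on the sorted values, so
Lloyd's algorithm with deterministic initialization at the data minimum and
maximum converges to the global optimum on the well-separated bimodal
posterior distributions the method produces — and every run is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .classify import FragmentScore
from .errors import DegenerateClusteringError, InvalidParameterError

__all__ = ["ClusterResult", "kmeans_1d", "identify_symbiont_cluster"]

#: below this symbiont/host coverage-diagnostic ratio the cluster identity
#: is flagged low-confidence (the spectrum premise barely holds)
LOW_CONFIDENCE_COVERAGE_RATIO = 1.5
#: minimum center separation below which the split itself is flagged
LOW_CONFIDENCE_CENTER_GAP = 0.2


@dataclass
class ClusterResult:
    centers: np.ndarray          # ascending, length 2
    labels: np.ndarray           # 0 = lower center, 1 = upper center
    n_iterations: int
    inertia: float               # within-cluster sum of squared deviations
    symbiont_cluster: int | None = None
    coverage_ratio: float | None = None
    warnings: List[str] = field(default_factory=list)


def kmeans_1d(
    values: Sequence[float], *, max_iter: int = 300, tol: float = 1e-10
) -> ClusterResult:
    """Lloyd's algorithm on scalars with centers initialized at min and max.

    Points equidistant from both centers are assigned to the lower one.
    Because the 2-cluster optimum in one dimension is a contiguous split of
    the sorted values, the Lloyd fixed point is refined by an exact
    prefix-sum search over all n-1 splits, so the returned partition is the
    global optimum, not merely a local one. Raises
    :class:`DegenerateClusteringError` when all values are identical
    (callers fall back to a 0.5 posterior threshold).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise InvalidParameterError("need at least two values to cluster")
    if tol < 0 or max_iter < 1:
        raise InvalidParameterError("tol must be >= 0 and max_iter >= 1")
    c0, c1 = float(v.min()), float(v.max())
    if c0 == c1:
        raise DegenerateClusteringError(
            "all posterior values identical; cannot form two clusters"
        )
    labels = np.zeros(v.size, dtype=np.int64)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        labels = (np.abs(v - c1) < np.abs(v - c0)).astype(np.int64)
        new0 = float(v[labels == 0].mean()) if np.any(labels == 0) else c0
        new1 = float(v[labels == 1].mean()) if np.any(labels == 1) else c1
        moved = max(abs(new0 - c0), abs(new1 - c1))
        c0, c1 = new0, new1
        if moved < tol:
            break
    if c0 > c1:  # keep centers ascending; relabel accordingly
        c0, c1 = c1, c0
        labels = 1 - labels
    inertia = float(np.sum((v - np.where(labels == 0, c0, c1)) ** 2))

    # exact refinement: best contiguous split of the sorted values
    order = np.argsort(v, kind="stable")
    sv = v[order]
    csum = np.cumsum(sv)
    csq = np.cumsum(sv * sv)
    cuts = np.arange(1, v.size)           # first `cut` points in cluster 0
    lo_sse = csq[cuts - 1] - csum[cuts - 1] ** 2 / cuts
    hi_n = v.size - cuts
    hi_sum = csum[-1] - csum[cuts - 1]
    hi_sse = (csq[-1] - csq[cuts - 1]) - hi_sum**2 / hi_n
    sse = lo_sse + hi_sse
    # among tied splits take the largest cut: boundary points fall to the
    # lower cluster, matching the equidistant tie rule
    best = int(np.nonzero(sse <= sse.min() + 1e-12)[0][-1]) + 1
    if sse[best - 1] < inertia - 1e-12:
        labels = np.zeros(v.size, dtype=np.int64)
        labels[order[best:]] = 1
        c0 = float(sv[:best].mean())
        c1 = float(sv[best:].mean())
        inertia = float(sse[best - 1])
    return ClusterResult(
        centers=np.array([c0, c1]), labels=labels,
        n_iterations=n_iter, inertia=inertia,
    )


def identify_symbiont_cluster(
    result: ClusterResult, scores: Sequence[FragmentScore]
) -> int:
    """Label the symbiont cluster and attach the coverage diagnostic.

    The cluster with the larger center (higher mean posterior of symbiont
    origin) is the symbiont by construction. As a guard, each cluster's mean
    fragment median-k-mer-occurrence is compared: the symbiont cluster should
    be the higher-coverage one, and a ratio under
    ``LOW_CONFIDENCE_COVERAGE_RATIO`` (or a center gap under
    ``LOW_CONFIDENCE_CENTER_GAP``) appends a low-confidence warning.
    """
    if len(scores) != result.labels.size:
        raise InvalidParameterError(
            "scores and cluster labels cover different fragment sets"
        )
    symbiont = 1  # centers are ascending: label 1 has the larger center
    med = np.array([s.median_occurrence for s in scores], dtype=float)
    ok = ~np.isnan(med)
    cov = []
    for lab in (0, 1):
        sel = ok & (result.labels == lab)
        cov.append(float(np.mean(med[sel])) if np.any(sel) else float("nan"))
    ratio = cov[symbiont] / cov[1 - symbiont] if cov[1 - symbiont] else float("inf")
    result.symbiont_cluster = symbiont
    result.coverage_ratio = ratio
    gap = float(result.centers[1] - result.centers[0])
    if gap < LOW_CONFIDENCE_CENTER_GAP:
        result.warnings.append(
            f"low confidence: cluster centers separated by only {gap:.3f}"
        )
    if not ratio >= LOW_CONFIDENCE_COVERAGE_RATIO:  # also catches NaN
        result.warnings.append(
            "low confidence: symbiont cluster coverage only "
            f"{ratio:.2f}x the host cluster"
        )
    return symbiont
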