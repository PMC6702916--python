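# Methods

## Model

A holobiont library mixes reads from a host genome of size *s* and a
symbiont genome of size *q* ≪ *s*. With *n* reads of *l* bp and a host
base-pair fraction *R*, uniform sequencing puts *nlR* bp on the host and
*nl(1−R)* bp on the symbiont, so a k-mer occurring N_s times in the host
genome and N_Q times in the symbiont genome is expected to be seen

    N_m = N_s · nlR/s + N_Q · nl(1−R)/q

times in the read set (`expected_kmer_observance`). Because *q* ≪ *s*, the
two genomes contribute k-mers at well-separated occurrence scales and the
pooled spectrum is bimodal.

Rather than fitting that two-component occurrence distribution
parametrically, the classifier works with occurrence **ranks**. Ordering the
distinct k-mers of the metagenome most-frequent-first, the per-k-mer
evidence for symbiont origin is the rank tail

    P(o_j | r ∈ q) = #{distinct k-mers with occurrence ≤ o_j} / #{distinct k-mers},

i.e. the fraction of k-mers no more frequent than k_j: symbiont k-mers,
living at high coverage, land deep in this tail. The host term — which the
two-hypothesis posterior needs but the rank construction alone does not
pin down — is taken as the complementary tail (fraction at least as
frequent), the mirror-image statistic. Both tails are computed over
*distinct* k-mers, with ties sharing a rank, and are step functions of the
occurrence level. A `rank_direction` flag flips the convention for users
who want the opposite ordering.

Per fragment (a mated pair pooled into one k-mer multiset of size *m*; the
two mates are never scored apart), the likelihood of each origin is the sum
of the per-k-mer tails, reported as the mean so it stays in [0, 1] — the
1/*m* factor cancels in the posterior

    P(r ∈ q | O) = L_q P(q) / (L_q P(q) + L_s P(s)),

with priors proportional to the genome-size estimates,
P(q) = q̂/(ŝ + q̂). A `likelihood="product"` mode multiplies the tails in
log space instead; it sharpens posteriors toward 0/1 and is provided for
comparison, not as the default. k-mers absent from the count table (e.g.
after `min_count` filtering, or windows containing N) are skipped and do
not count toward *m*; a fragment with *m* = 0 is flagged degenerate and
carries its prior as posterior.

## Clustering and the symbiont call

The per-fragment posteriors are split into two groups by K-means with
K = 2. Two implementation choices matter:

- **Exactness.** In one dimension the 2-means optimum is a contiguous split
  of the sorted values. `kmeans_1d` runs Lloyd's algorithm from a
  deterministic min/max initialization (ties go to the lower center) and
  then refines the fixed point with an exact prefix-sum search over all
  n−1 splits, so the returned partition is the global optimum and every run
  is reproducible. Identical inputs raise a degenerate-clustering error and
  the pipeline falls back to a 0.5 posterior threshold.
- **Feature scale.** The pipeline clusters the posterior **log-odds**
  log(p/(1−p)) rather than p. A change of prior adds the same constant
  log(P(q)/P(s)) to every fragment's log-odds, and 1-D K-means is invariant
  under translation, so the final partition provably does not depend on the
  genome-size estimates — the formal version of the observation that with an
  order-of-magnitude size difference the priors have little effect on the
  end result. It also undoes the compression of the posterior near 0 and 1,
  where K-means on raw probabilities places its boundary poorly when the
  prior skews the distribution. `call_origins(feature="posterior")` retains
  clustering on raw posteriors.

The cluster with the larger center is called symbiont — the posterior
measures symbiont origin, so this is definitional — but the call is guarded
by a diagnostic: the mean fragment median-k-mer-occurrence per cluster. The
symbiont cluster should be the high-coverage one; a ratio below 1.5, or a
center separation below 0.2, appends a low-confidence warning to the run
summary.

## Synthetic mixtures

`simulate_reads` draws i.i.d. random genomes (defaults: GC 0.41 host, 0.43
symbiont — round figures in the range reported for such symbioses; results
are insensitive to GC since the classifier sees only occurrence counts),
assigns each fragment to the host with probability *R*, places inserts
uniformly, reads *l* bp off each insert end (mate 2 reverse-complemented)
and applies i.i.d. substitution errors. The default preset — *s* = 200 kb,
*q* = 20 kb, *n* = 20 000 pairs of 2×100 bp, insert 300 bp, *R* = 0.5,
error 0, seed 42 — is a desk-scale stand-in for a snail-gill metagenome,
preserving the property that drives the method (a 10× genome-size and hence
10× coverage asymmetry) at ~1/10 000 of the data volume. One seed determines
everything byte-for-byte.

What the generator does **not** emulate: repeats and low-complexity tracts
(real host genomes share k-mers between loci and with the symbiont),
coverage biases (GC bias, uneven fragmentation), indels, quality-score
structure, multiple symbiont phylotypes, and free-living contaminants.
Passing tests therefore show the algorithm is implemented correctly and
separates mixtures whose spectra match its premise; they do not bound its
accuracy on real gill metagenomes, where shared and repeated k-mers blur
the two occurrence modes.

## Model self-consistency check

`single_copy_symbiont_check` compares the mean read-set occurrence of
k-mers that occur exactly once in the symbiont genome (and never in the
host) with the expectation formula. A read of *l* bp contributes *l*−*k*+1
k-mer tokens, not *l*, and a genome of *q* bp offers *q*−*k*+1 k-mer
positions, so the formula is evaluated with those effective lengths and the
realized host fraction; at error rate 0 this token accounting is exact and
the empirical mean matches to well within Monte-Carlo error.

## Numerical choices and defaults

| parameter | default | why |
|---|---|---|
| k (counting) | 21 | standard spectrum k: long enough that random 21-mer collisions are negligible (4²¹ ≫ genome sizes), short enough for dense per-read sampling; must be ≤ 31 (2-bit packing), odd avoids palindromes |
| canonical counting | on | read strand is arbitrary; `--no-canonical` for per-strand counts |
| min_count | 1 | keep all k-mers; raising it drops error singletons at the cost of degenerate fragments |
| K-means tol / max_iter | 1e−10 / 300 | scalar centers converge in a handful of iterations; tol far below posterior resolution |
| log-odds clamp | 1e−12 | keeps logit finite if a posterior saturates (product mode) |
| low-confidence thresholds | ratio 1.5, gap 0.2 | a spectrum whose two modes differ by <1.5× coverage cannot support the premise; centers closer than 0.2 mean the posterior landscape is unimodal |

Counting packs k-mers into 2-bit integers (A<C<G<T, so the numeric minimum
of a code and its reverse complement is the lexicographic canonical form)
and accumulates windows in O(n·k) vectorized passes; reads are concatenated
with `N` sentinels so window invalidation handles read boundaries and
ambiguous bases identically. Occurrence lookups and rank tails are binary
searches over sorted code and level arrays.

## Known limitations

- Exactly two sources; no re-estimation of priors and no handling of a
  second symbiont phylotype (a contig-level EM binner is the right tool
  there).
- The host tail is a modeling choice (mirror of the symbiont tail), not a
  derived quantity; alternative host models would change posterior scale
  though rarely the ranking.
- Memory is sized for desk-scale to ~10⁷-token read sets in RAM; counting a
  full animal-genome library needs a disk-backed counter, which is out of
  scope.
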