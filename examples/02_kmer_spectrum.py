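"""Count k-mers of a mixture and inspect the bimodal occurrence spectrum.

Host k-mers cluster around the host coverage, symbiont k-mers around the
(much higher) symbiont coverage; the rank index turns an occurrence count
into tail probabilities under each origin.
"""

import numpy as np

import holosep as hs
from holosep.kmer_index import build_rank_index, count_kmers

ds = hs.simulate_reads(s=100_000, q=10_000, n_fragments=5_000, seed=11)
seqs = [s for f in ds.fragments for s in (f.seq1, f.seq2)]
table = count_kmers(seqs, k=21)
index = build_rank_index(table)

print(f"{table.n_distinct:,} distinct canonical 21-mers, "
      f"{table.n_total:,} tokens")

logc = np.log(table.code_counts.astype(float))
modes = hs.kmeans_1d(logc)
lo, hi = np.exp(modes.centers)
print(f"spectrum modes near occurrence {lo:.0f} (host) and {hi:.0f} "
      f"(symbiont): bimodal, ratio {hi / lo:.1f}")

for occ in (round(lo), round(hi)):
    sym = hs.rank_tail_probability(index, occ, "symbiont")
    host = hs.rank_tail_probability(index, occ, "host")
    print(f"occurrence {occ:3d}: symbiont tail {sym:.3f}, host tail {host:.3f}")
# A high-occurrence k-mer has a symbiont tail near 1 (almost no k-mer is
# more frequent) and a small host tail — the per-k-mer evidence the
# classifier averages over each fragment.
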