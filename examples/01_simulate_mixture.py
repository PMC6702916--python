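"""Simulate a holobiont read mixture with known truth labels.

A 100 kb "host" genome and a 10 kb "symbiont" genome are sequenced together:
at equal read mass the tenfold-smaller symbiont genome ends up at tenfold
the coverage. That asymmetry is what the classifier exploits.
"""

import holosep as hs

ds = hs.simulate_reads(s=100_000, q=10_000, n_fragments=5_000,
                       read_length=100, insert=300, host_fraction=0.5,
                       seed=11)

n_host = sum(1 for v in ds.truth.values() if v == "host")
n_sym = len(ds.fragments) - n_host
bp = 2 * ds.params.read_length
cov_host = n_host * bp / ds.params.s
cov_sym = n_sym * bp / ds.params.q

print(f"fragments: {len(ds.fragments)} pairs "
      f"({n_host} host, {n_sym} symbiont)")
print(f"host coverage:     {cov_host:5.1f}x over {ds.params.s:,} bp")
print(f"symbiont coverage: {cov_sym:5.1f}x over {ds.params.q:,} bp")
print(f"coverage ratio:    {cov_sym / cov_host:.1f} "
      f"(~ genome size ratio {ds.params.s / ds.params.q:.0f})")
# The ratio matches the genome-size ratio because both genomes receive the
# same read mass; this is the bimodality the k-mer spectrum will show.
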