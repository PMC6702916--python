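"""Full pipeline: count -> score -> cluster -> call origins -> evaluate.

The per-fragment posterior log-odds are split with a two-center 1-D K-means
and the higher-posterior cluster is called symbiont; with truth labels in
hand the separation is scored with the symbiont as the positive class.
"""

import json

import holosep as hs

ds = hs.simulate_reads(s=100_000, q=10_000, n_fragments=5_000, seed=11)

result = hs.separate_fragments(
    ds.fragments, host_size=100_000, symbiont_size=10_000, k=21
)
print(json.dumps(result.summary(), indent=2))

report = hs.evaluate_separation(result.predicted, ds.truth,
                                scores=result.scores)
print(f"accuracy  {report.accuracy:.4f}")
print(f"precision {report.precision:.4f}  recall {report.recall:.4f}  "
      f"f1 {report.f1:.4f}")
# Precision is the purity of the symbiont read set handed to the assembler;
# recall is the fraction of true symbiont fragments it retains. The
# coverage_ratio diagnostic (~10) confirms the symbiont cluster is the
# high-coverage one.
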