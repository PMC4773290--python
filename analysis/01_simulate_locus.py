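"""Simulate the study locus and write it to disk as standard files.

Emits VCF genotypes, BED annotation intervals, phenotype TSVs, paired
control/FAIRE BAF records, a reference FASTA and the truth sidecar under
results/locus_bundle/.
"""

import numpy as np

import regulocal as rl
from _common import CAUSAL_IX, RESULTS, study_bundle

bundle, baf = study_bundle()
paths = rl.write_fixture_bundle(bundle, RESULTS / "locus_bundle", baf=baf)

maf = bundle.maf()
lead = bundle.variant_ids[CAUSAL_IX]
ld = rl.ld_with_lead(bundle.genotypes, bundle.variant_ids, lead)
strong = sum(1 for r in ld if r.r2 is not None and r.r2 >= 0.8)

print(f"simulated locus: {bundle.spec.n_variants} variants over "
      f"{bundle.spec.positions[-1] - bundle.spec.positions[0]:,} bp, "
      f"n={bundle.genotypes.shape[0]} samples")
print(f"MAF range {maf.min():.3f}-{maf.max():.3f}")
print(f"{strong} variants in strong LD (r2 >= 0.8) with the causal variant {lead}")
counts = {s: list(bundle.annotation_truth.values()).count(s) for s in ("within", "near", "none")}
print(f"annotation truth: {counts}")
for k, v in paths.items():
    print(f"  wrote {k}: {v}")
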