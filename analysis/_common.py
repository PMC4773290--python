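"""Shared study conditions for the analysis scripts.

One synthetic locus is used throughout: 60 variants in three 20-variant LD
blocks spanning ~250 kb, a cohort of 2000, and a single causal variant
(index 30) shared by the lipid trait and the expression phenotype at 0.4 SD
per allele copy, with a 0.1 BAF accessibility shift injected at the same
variant.  Seed 20 fixes everything.
"""

from pathlib import Path

import regulocal as rl

SEED = 20
RESULTS = Path(__file__).resolve().parent.parent / "results"
CAUSAL_IX = 30


def study_bundle():
    spec = rl.LocusSpec(n_variants=60, block_lengths=(20, 20, 20), seed=SEED)
    cfg = rl.CausalConfig(
        scenario="H4", trait_causal=CAUSAL_IX, expr_causal=CAUSAL_IX,
        beta_trait=0.4, beta_expr=0.4, noise_sd=1.0, n_samples=2000, seed=SEED,
    )
    bundle = rl.simulate_bundle(
        spec, cfg, fraction_within=0.2, fraction_near=0.1, force_within=[CAUSAL_IX]
    )
    baf = rl.simulate_faire_baf(
        bundle, {bundle.variant_ids[CAUSAL_IX]: 0.1}, baf_noise_sd=0.05, seed=SEED + 7
    )
    return bundle, baf


def variant_frame(bundle):
    import pandas as pd

    return pd.DataFrame({
        "variant": bundle.variant_ids,
        "chrom": bundle.spec.chrom,
        "pos": bundle.spec.positions,
        "ref": bundle.ref_alleles,
        "alt": bundle.alt_alleles,
    })
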