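import numpy as np
import pandas as pd
import pytest

import regulocal as rl


@pytest.fixture(scope="session")
def h4_bundle():
    """Strong shared-causal-variant locus: 60 variants, n=2000, beta=0.4."""
    spec = rl.LocusSpec(n_variants=60, block_lengths=(20, 20, 20), seed=11)
    cfg = rl.CausalConfig(
        scenario="H4", trait_causal=30, expr_causal=30,
        beta_trait=0.4, beta_expr=0.4, n_samples=2000, seed=11,
    )
    return rl.simulate_bundle(spec, cfg, fraction_within=0.2, fraction_near=0.1)


@pytest.fixture(scope="session")
def h4_variants(h4_bundle):
    return pd.DataFrame(
        {
            "variant": h4_bundle.variant_ids,
            "chrom": h4_bundle.spec.chrom,
            "pos": h4_bundle.spec.positions,
            "ref": h4_bundle.ref_alleles,
            "alt": h4_bundle.alt_alleles,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
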