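"""Replicate experiments over the synthetic locus.

Study conditions for the colocalisation recovery experiment: a 60-variant
locus in three LD blocks, a cohort of 2000, and a causal effect of 0.4
phenotype SD per allele copy on both the trait and expression (shared under
H4, block-separated under H3).  These drive the decision-rule checks and the
reported recovery numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coloc import ColocPriors, ColocResult, coloc_posteriors
from .eqtl import scan, stats_to_frame
from .simulate import CausalConfig, LocusSpec, simulate_haplotypes, simulate_traits


def coloc_replicate(
    seed: int,
    scenario: str = "H4",
    n_variants: int = 60,
    n_samples: int = 2000,
    beta: float = 0.4,
    noise_sd: float = 1.0,
    priors: ColocPriors = ColocPriors(),
) -> ColocResult:
    """Simulate one locus under H3/H4/H0 and colocalise trait vs expression.

    Under H4 the shared causal variant sits mid-locus; under H3 the two
    causal variants are placed in different LD blocks and founder choice is
    redrawn at every block boundary, so their truth LD is near zero.
    """
    b = n_variants // 3
    block_lengths = (b, b, n_variants - 2 * b)
    recomb = 1.0 if scenario == "H3" else 0.2
    spec = LocusSpec(
        n_variants=n_variants,
        block_lengths=block_lengths,
        recomb_prob=recomb,
        seed=seed,
    )
    mid = n_variants // 2
    causal = {
        "H0": dict(trait_causal=None, expr_causal=None),
        "H1": dict(trait_causal=mid, expr_causal=None),
        "H2": dict(trait_causal=None, expr_causal=mid),
        "H3": dict(trait_causal=b // 2, expr_causal=2 * b + b // 2),
        "H4": dict(trait_causal=mid, expr_causal=mid),
    }[scenario]
    config = CausalConfig(
        scenario=scenario,
        beta_trait=beta,
        beta_expr=beta,
        noise_sd=noise_sd,
        n_samples=n_samples,
        seed=seed,
        **causal,
    )
    haps = simulate_haplotypes(spec, n_samples)
    bundle = simulate_traits(haps, config, spec)
    variants = pd.DataFrame(
        {"variant": bundle.variant_ids, "chrom": spec.chrom, "pos": spec.positions}
    )
    s1, _ = scan(bundle.genotypes, variants, bundle.trait, trait_id="trait")
    s2, _ = scan(bundle.genotypes, variants, bundle.expression, trait_id="expression")
    return coloc_posteriors(stats_to_frame(s1), stats_to_frame(s2), priors)


def coloc_recovery(
    seeds,
    scenario: str = "H4",
    **kw,
) -> pd.DataFrame:
    """pp table over replicate seeds for one scenario."""
    rows = []
    for s in seeds:
        res = coloc_replicate(int(s), scenario=scenario, **kw)
        rows.append({"seed": int(s), **res.pp})
    return pd.DataFrame(rows)


def faire_null_rejection_rate(
    n_loci: int,
    seed: int,
    n_het: int = 10,
    noise_sd: float = 0.05,
    shift: float = 0.0,
    alpha: float = 0.05,
) -> float:
    """Fraction of replicate loci where the paired test rejects at alpha.

    Each locus contributes ``n_het`` heterozygotes whose control BAF is
    N(0.5, noise) and FAIRE BAF N(0.5 + shift, noise), clipped to [0, 1] —
    the generator's heterozygote model without the genotype plumbing.  The
    test itself runs through :func:`regulocal.faire.allelic_imbalance`.
    """
    from .faire import allelic_imbalance

    rng = np.random.default_rng(seed)
    samples = [f"S{i}" for i in range(n_het)]
    rejections = 0
    for k in range(n_loci):
        control = np.clip(rng.normal(0.5, noise_sd, n_het), 0, 1)
        faire = np.clip(rng.normal(0.5 + shift, noise_sd, n_het), 0, 1)
        records = pd.DataFrame(
            {
                "sample": samples * 2,
                "variant": f"locus{k}",
                "treatment": ["control"] * n_het + ["faire"] * n_het,
                "baf": np.concatenate([control, faire]),
            }
        )
        res = allelic_imbalance(records, samples)
        rejections += res.p < alpha
    return rejections / n_loci
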