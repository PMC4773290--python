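"""Candidate pool: strong LD with the lead SNP, genome-wide significance, or
eQTL evidence (union rule).

Writes results/candidates.tsv with per-variant provenance flags.
"""

import regulocal as rl
from regulocal.eqtl import stats_to_frame
from _common import CAUSAL_IX, RESULTS, study_bundle, variant_frame

bundle, _ = study_bundle()
variants = variant_frame(bundle)

stats_t, _ = rl.scan(bundle.genotypes, variants, bundle.trait, trait_id="trait")
gwas = stats_to_frame(stats_t, variants)
stats_e, _ = rl.scan(bundle.genotypes, variants, bundle.expression, trait_id="expression")
eqtl = stats_to_frame(stats_e, variants)

lead = gwas.loc[gwas["p"].idxmin(), "variant"]
ld = rl.ld_with_lead(bundle.genotypes, bundle.variant_ids, lead)
cand = rl.select_candidates(
    ld, gwas, eqtl, gene_anchor_pos=bundle.spec.positions[CAUSAL_IX]
)

df = cand.to_frame()
df["r2"] = df["variant"].map({r.variant_id: r.r2 for r in ld})
df["gwas_p"] = df["variant"].map(gwas.set_index("variant")["p"])
df["eqtl_p"] = df["variant"].map(eqtl.set_index("variant")["p"])
out = RESULTS / "candidates.tsv"
out.parent.mkdir(exist_ok=True)
df.to_csv(out, sep="\t", index=False)

print(f"lead SNP (min GWAS p): {lead}, p = {gwas['p'].min():.3e}")
print(f"candidate pool: {len(cand)} of {len(variants)} variants -> {out}")
print(df["flags"].value_counts().to_string())
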