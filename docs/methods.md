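# Methods

## Problem setting

At a locus where a GWAS signal for a quantitative trait overlaps an eQTL
for a nearby gene, the package asks three questions in sequence: which
variants could plausibly be causal (LD/significance), do the two signals
share a causal variant (colocalisation), and which candidates have direct
functional evidence (regulatory annotation overlap, allele-specific
chromatin accessibility)? Every statistical stage operates on standard
summary objects (dosage matrices, per-variant beta/se/p tables, BED
intervals, BAF records), so real data and simulated data follow the same
code path.

## Linkage disequilibrium and candidate selection

LD with the lead SNP is the squared Pearson correlation of genotype
dosages over pairwise-complete samples (composite LD). This is the
standard surrogate for haplotype r² when phase is unknown; an EM
haplotype-frequency estimator is deliberately out of scope. A site that is
monomorphic among informative samples has *undefined* LD and is reported
with a flag rather than r² = 0 — the two mean different things.

The candidate pool is a union of three rules with provenance recorded per
variant: r² ≥ 0.8 with the lead (inclusive threshold), GWAS p < 5×10⁻⁸
(strict) within 500 kb of the gene anchor, and eQTL significance combined
with the LD rule. The eQTL significance cut-off is not standardised in the
field; we default it to the genome-wide threshold and expose it as
configuration, as we do for whether the 500 kb window also applies to eQTL
hits. Raising any threshold can only shrink the pool (tested as an
anti-monotonicity property).

## Marginal association scan

Each polymorphic variant in the cis window (default anchor ± 200 kb,
bounds inclusive, 1-based coordinates as in VCF) is regressed against the
phenotype by OLS with an intercept; se comes from the residual variance on
n − 2 df and the two-sided p from Student-t. No covariates are fitted by
default (a covariate hook exists); phenotypes are used as given because
the simulator produces standardized values. A perfect fit (zero residual
variance) is reported with se = 0, p = 0 and a degenerate flag rather than
an error, so that downstream consumers can decide. The implementation is
verified to 1e-10 against an independent normal-equations oracle and
(during development) agreed with `scipy.stats.linregress` to machine
precision; null p-values pass a KS uniformity check.

## Colocalisation

Per variant and trait we compute Wakefield's asymptotic Bayes factor in
log form, log ABF = ½[log(1 − r) + r z²] with r = W/(V + W), z = beta/se,
V = se². The prior effect-size SD is 0.15 phenotype SD (W = 0.0225), the
conventional quantitative-trait choice; it is configurable per trait.
Where beta/se are unavailable, z is recovered from the two-sided p (signed
normal quantile) and V approximated by 1/(2 n f (1 − f)) for a
standardized trait — when both parameterisations are present, beta/se
wins.

Under the one-causal-variant-per-trait assumption the five hypothesis
weights are accumulated entirely in log space:

    L0 = 0
    L1 = log p1 + logsumexp(l1)
    L2 = log p2 + logsumexp(l2)
    L3 = log p1 + log p2 + logdiff(S1 + S2, S12)
    L4 = log p12 + S12,          S12 = logsumexp(l1 + l2)

with priors p1 = p2 = 1×10⁻⁴ and p12 = 1×10⁻⁵ (configurable, echoed in
every result). The logdiff for H3 excludes same-variant configurations
from the cross product; with a single shared variant H3 is exactly
impossible and gets posterior 0. If S12 numerically exceeds S1 + S2 the H3
weight is clamped to −∞ with a warning. Posteriors are the softmax of
L0..L4 and sum to 1 within 1e-12; the whole algebra is tested to 1e-10
against a direct enumeration oracle over the n + n + n(n−1) + n
configurations. A posterior strictly above 0.75 is labelled strong
evidence; 0.75 exactly is inconclusive.

Tables are joined on variant id with intersection semantics (singletons
dropped with a logged count) — colocalisation is only meaningful on the
shared variant set.

## Regulatory annotation

Variants are 1-based, intervals 0-based half-open (BED); the conversion
lives in exactly one function. Status per track is *within* (inside a
peak), *near* (nearest edge ≤ 500 bp), or *none*; the per-variant summary
takes the best status across tracks. The near boundary is **inclusive** at
exactly 500 bp — the field's prose conventions are genuinely ambiguous
here, so the band is a config parameter; inclusive is the default and the
choice only matters for variants at exactly the boundary. Intervals
sharing a track label are merged across cell types by default. The
interval-tree implementation is property-tested against a naive O(V·I)
distance scan.

A transcribed 46-variant reference grid (33 within, 13 near, across
promoter-histone / enhancer-histone / DNase / protein-bound tracks) ships
as a packaged TSV; it is test and demonstration data, never pipeline
input.

## Allele-specific FAIRE

Heterozygotes are called from the non-enriched channel as control BAF in
[0.5 − δ, 0.5 + δ] with δ = 0.15 (no field standard exists; the value
separates cleanly from the simulated homozygote clusters at the default
noise level, and is configurable). The imbalance statistic is a paired
t-test on dᵢ = BAF_faire,i − BAF_control,i over heterozygotes, n − 1 df,
two-sided. The enriched allele is B if mean(d) > 0 else A, and
`enrichment_pct` is the **relative** change of the enriched allele's mean
fraction (0.500 → 0.602 reads as 20.4%); an absolute percentage-point mode
is available since the field reports both and prose rarely says which.
No multiple-testing correction is applied across variants; raw p-values
are reported with the variant count. The reporter-assay companion is a
two-sample t-test on per-well reporter/control ratios between allele
groups.

Calibration (computed by the test suite, not asserted from memory): the
null rejection rate over 1000 replicate loci is within the binomial 95%
band of 5%, and power at shift 0.1, noise SD 0.05, 10 heterozygotes
exceeds 90%.

## Probe design

EMSA probes are 2·flank + 1 mers (default flank 15 bp → 31-mers) with the
variant base at the centre, one forward strand per allele plus exact
reverse complements. Only SNVs are supported. If the reference base at the
variant position matches neither declared allele, the design warns and
substitutes the declared alleles — probes are genomic context plus allele
substitution, so a stale reference should not block the design.

## Synthetic locus simulator

The generator emulates a ~250 kb locus with haplotype-block LD: each of
`n_founders` founder haplotypes per block is drawn with Bernoulli(½)
alleles; sampled haplotypes copy one founder per block, redraw the founder
between adjacent blocks with probability `recomb_prob`, and flip each site
with probability `mutation_prob`. This founder-copy model (not a
coalescent) was chosen because its LD is directly controllable and
closed-form checkable: with two founders and no mutation, within-block r²
is exactly 1; population r² for any site pair follows from the four
founder haplotype frequencies, and the dosage estimate converges to it.
Phenotypes are `beta · dosage + N(0, noise_sd)` with the causal index
pattern encoding the five colocalisation scenarios H0–H4. Annotation
intervals are placed to make a chosen fraction of variants within/near,
verified against the annotator and retried on collision. BAF records are
drawn per heterozygote around 0.5 (control) and 0.5 + shift (FAIRE),
clipped to [0, 1] — clipping rather than resampling, since the bias is
negligible at the stated noise levels. All randomness flows from one
integer seed; identical seeds give bit-identical bundles, and the truth
sidecar (JSON) is read only by tests.

What the simulator does **not** emulate: realistic recombination maps,
population structure, imputation uncertainty, array-intensity artefacts in
BAF, expression-normalisation pipelines (expression is treated as an
already-standardized quantitative trait), or winner's-curse effects in the
summary statistics. Passing tests therefore demonstrate the statistical
machinery is correct under a clean generative model, not that real-data
candidate counts or posteriors would be reproduced.

## Study conditions and problem sizes

The replicate experiments use a 60-variant locus in three 20-variant
blocks, four founders, recomb 0.2 (1.0 for the distinct-causal scenario,
so the two causal variants' truth r² is ~0), mutation 0.01, cohort
n = 2000, causal effect 0.4 SD per allele copy on both phenotypes, noise
SD 1 — a strong but realistic single-locus signal (~7% variance
explained). Recovery runs use 100 replicates; FAIRE calibration uses 1000
replicate loci of 10 heterozygotes. The decision rule recovers the
shared-causal hypothesis with median posterior well above the 0.75
threshold, and prefers the distinct-causal hypothesis on the
distinct-causal bundles in the clear majority of replicates (the H3/H4
contrast is the harder direction, since strong within-block LD makes the
two configurations genuinely similar).

## Pipeline

`run_pipeline` executes the stages in order, writes every stage artifact
(summary-stat TSVs, coloc JSON, annotation matrix, imbalance table,
report) under the output directory, and assigns tiers:
candidate → regulatory (annotation within/near) → functional_evidence
(regulatory + imbalance p < 0.05). Tier counts reconcile by construction
(each tier is a subset of the previous). Config is YAML with full defaults
(empty file = default simulate-mode run), unknown keys rejected with their
path, and a single seed controlling all randomness; re-running a config
reproduces byte-identical reports. Wet-lab decision points (EMSA bands,
luciferase shifts) enter as optional user-supplied evidence tables, not
computed stages.

## Known limitations

- One causal variant per trait is assumed by the colocalisation algebra;
  allelic heterogeneity pushes posterior mass toward H3/H4 mixtures it
  cannot represent.
- Dosage-correlation r² underestimates haplotype r² slightly under
  Hardy-Weinberg departures.
- The annotation near/within boundary at exactly 500 bp, the heterozygote
  BAF band, and the relative-vs-absolute enrichment definition are field
  conventions without a single standard; all three are configurable and
  the defaults are stated above.
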