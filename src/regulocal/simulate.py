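"""Synthetic locus simulator with known ground truth.

Emulates a ~250 kb lipid-locus neighbourhood: haplotypes arranged in LD
blocks (a founder-copy model, not a coalescent), a quantitative trait and an
expression phenotype driven by a shared or distinct causal variant,
regulatory-annotation intervals overlapping a chosen subset of variants, and
genotyping-array B-allele fractions with an injected chromatin-accessibility
imbalance.  Every stage of the localisation pipeline can be exercised
against the truth recorded here.

All randomness flows from one integer seed through a single
``numpy.random.Generator`` per bundle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

SCENARIOS = ("H0", "H1", "H2", "H3", "H4")


class InvalidSpecError(ValueError):
    """A locus or causal specification violates its invariants."""


@dataclass(frozen=True)
class LocusSpec:
    """Layout of a synthetic locus.

    Haplotypes are assembled block-by-block: each haplotype copies one of
    ``n_founders`` founder haplotypes per LD block, switching founder between
    adjacent blocks with probability ``recomb_prob``, then every site is
    flipped independently with probability ``mutation_prob``.
    """

    n_variants: int
    block_lengths: tuple[int, ...]
    n_founders: int = 4
    recomb_prob: float = 0.2
    mutation_prob: float = 0.01
    positions: tuple[int, ...] = ()
    chrom: str = "1"
    seed: int = 0
    span_bp: int = 250_000

    def __post_init__(self):
        if self.n_founders < 1:
            raise InvalidSpecError("n_founders must be >= 1")
        if sum(self.block_lengths) != self.n_variants:
            raise InvalidSpecError(
                f"block_lengths sum {sum(self.block_lengths)} != n_variants {self.n_variants}"
            )
        for p in (self.recomb_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise InvalidSpecError(f"probability {p} outside [0, 1]")
        if not self.positions:
            # Evenly spaced 1-based coordinates across the locus span.
            step = self.span_bp // (self.n_variants + 1)
            object.__setattr__(
                self,
                "positions",
                tuple((i + 1) * step for i in range(self.n_variants)),
            )
        if len(self.positions) != self.n_variants:
            raise InvalidSpecError("positions length != n_variants")
        if any(b >= a for a, b in zip(self.positions[1:], self.positions)):
            raise InvalidSpecError("positions must be strictly increasing")
        if self.positions[0] < 1:
            raise InvalidSpecError("positions are 1-based (>= 1)")

    @property
    def variant_ids(self) -> list[str]:
        return [f"rs{i + 1:05d}" for i in range(self.n_variants)]


@dataclass(frozen=True)
class CausalConfig:
    """Phenotype architecture for one simulated cohort.

    ``scenario`` follows the five colocalisation hypotheses: H0 neither
    phenotype has a causal variant at the locus, H1 trait only, H2 expression
    only, H3 both but distinct variants, H4 one shared causal variant.
    Effects are per allele copy on a standardized phenotype scale.
    """

    scenario: str
    trait_causal: int | None = None
    expr_causal: int | None = None
    beta_trait: float = 0.0
    beta_expr: float = 0.0
    noise_sd: float = 1.0
    n_samples: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise InvalidSpecError(f"unknown scenario {self.scenario!r}")
        t, e = self.trait_causal, self.expr_causal
        ok = {
            "H0": t is None and e is None,
            "H1": t is not None and e is None,
            "H2": t is None and e is not None,
            "H3": t is not None and e is not None and t != e,
            "H4": t is not None and t == e,
        }[self.scenario]
        if not ok:
            raise InvalidSpecError(
                f"causal indices ({t}, {e}) inconsistent with scenario {self.scenario}"
            )


@dataclass
class TruthBundle:
    """A fully simulated locus plus the ground truth used to generate it."""

    spec: LocusSpec
    genotypes: np.ndarray  # (n_samples, n_variants) dosages in {0,1,2}
    trait: np.ndarray
    expression: np.ndarray
    causal_truth: CausalConfig
    annotation_truth: dict[str, str] = field(default_factory=dict)
    annotation_intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
    imbalance_truth: dict[str, float] = field(default_factory=dict)
    ref_alleles: list[str] = field(default_factory=list)
    alt_alleles: list[str] = field(default_factory=list)

    @property
    def variant_ids(self) -> list[str]:
        return self.spec.variant_ids

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:04d}" for i in range(self.genotypes.shape[0])]

    def maf(self) -> np.ndarray:
        f = self.genotypes.mean(axis=0) / 2.0
        return np.minimum(f, 1.0 - f)


def simulate_haplotypes(spec: LocusSpec, n_samples: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate a ``(2 * n_samples, n_variants)`` grid of {0,1} alleles.

    Founder haplotypes are drawn once per block with Bernoulli(1/2) alleles;
    each sampled haplotype copies one founder per block, re-drawing the
    founder index between adjacent blocks with probability ``recomb_prob``,
    then flips each site with probability ``mutation_prob``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_hap = 2 * n_samples
    n_blocks = len(spec.block_lengths)
    founders = [
        rng.integers(0, 2, size=(spec.n_founders, L)).astype(np.int8)
        for L in spec.block_lengths
    ]
    # Founder index per haplotype per block, with Markov switching.
    idx = np.empty((n_hap, n_blocks), dtype=np.int64)
    idx[:, 0] = rng.integers(0, spec.n_founders, size=n_hap)
    for b in range(1, n_blocks):
        switch = rng.random(n_hap) < spec.recomb_prob
        fresh = rng.integers(0, spec.n_founders, size=n_hap)
        idx[:, b] = np.where(switch, fresh, idx[:, b - 1])
    haps = np.concatenate(
        [founders[b][idx[:, b]] for b in range(n_blocks)], axis=1
    )
    if spec.mutation_prob > 0:
        flips = rng.random(haps.shape) < spec.mutation_prob
        haps = np.where(flips, 1 - haps, haps).astype(np.int8)
    return haps


def simulate_traits(
    haplotypes: np.ndarray,
    config: CausalConfig,
    spec: LocusSpec,
    rng: np.random.Generator | None = None,
) -> TruthBundle:
    """Collapse haplotypes to dosages and draw trait + expression phenotypes.

    ``trait = beta_trait * g_causal + N(0, noise_sd)`` and analogously for
    expression; under H0 both phenotypes are pure noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_var = haplotypes.shape[1]
    for ix in (config.trait_causal, config.expr_causal):
        if ix is not None and not 0 <= ix < n_var:
            raise InvalidSpecError(f"causal index {ix} outside [0, {n_var})")
    g = (haplotypes[0::2] + haplotypes[1::2]).astype(np.int8)
    n = g.shape[0]
    trait = rng.normal(0.0, config.noise_sd, size=n)
    if config.trait_causal is not None:
        trait = trait + config.beta_trait * g[:, config.trait_causal]
    expression = rng.normal(0.0, config.noise_sd, size=n)
    if config.expr_causal is not None:
        expression = expression + config.beta_expr * g[:, config.expr_causal]
    bundle = TruthBundle(
        spec=spec,
        genotypes=g,
        trait=trait,
        expression=expression,
        causal_truth=config,
    )
    _assign_alleles(bundle, rng)
    return bundle


def _assign_alleles(bundle: TruthBundle, rng: np.random.Generator) -> None:
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=bundle.spec.n_variants)
    shift = rng.integers(1, 4, size=bundle.spec.n_variants)
    bundle.ref_alleles = list(bases[ref])
    bundle.alt_alleles = list(bases[(ref + shift) % 4])


def simulate_annotations(
    positions: Sequence[int],
    fraction_within: float,
    fraction_near: float,
    interval_length_bp: int = 200,
    near_gap_bp: int = 500,
    seed: int = 0,
    chrom: str = "1",
    track: str = "dnase",
    variant_ids: Sequence[str] | None = None,
    max_retries: int = 20,
    force_within: Sequence[int] = (),
) -> tuple[list[tuple[str, int, int, str]], dict[str, str]]:
    """Place annotation intervals so a chosen variant subset is within/near.

    Returns BED-style intervals (chrom, start0, end0, track) and a truth map
    variant_id -> {"within", "near", "none"}.  "within" variants get an
    interval covering their position; "near" variants an interval whose
    closest edge is 1..near_gap_bp away; all other variants stay farther than
    near_gap_bp from every interval (verified, with retries on collision).
    """
    if fraction_within + fraction_near > 1 + 1e-12:
        raise InvalidSpecError("fraction_within + fraction_near must be <= 1")
    positions = list(positions)
    n = len(positions)
    if variant_ids is None:
        variant_ids = [f"rs{i + 1:05d}" for i in range(n)]
    n_within = int(round(fraction_within * n))
    n_near = int(round(fraction_near * n))
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        order = rng.permutation(n)
        forced = set(force_within)
        extra = [i for i in order.tolist() if i not in forced]
        n_extra = max(0, n_within - len(forced))
        within_ix = forced | set(extra[:n_extra])
        near_ix = set(extra[n_extra:n_extra + n_near])
        intervals: list[tuple[str, int, int, str]] = []
        truth: dict[str, str] = {}
        for i, pos in enumerate(positions):
            p0 = pos - 1  # 0-based
            if i in within_ix:
                offset = int(rng.integers(0, interval_length_bp))
                start = max(0, p0 - offset)
                intervals.append((chrom, start, start + interval_length_bp, track))
                truth[variant_ids[i]] = "within"
            elif i in near_ix:
                gap = int(rng.integers(1, near_gap_bp + 1))
                if rng.random() < 0.5 and p0 - gap - interval_length_bp >= 0:
                    end = p0 - gap + 1  # nearest edge is end-1, distance gap
                    intervals.append((chrom, end - interval_length_bp, end, track))
                else:
                    start = p0 + gap
                    intervals.append((chrom, start, start + interval_length_bp, track))
                truth[variant_ids[i]] = "near"
            else:
                truth[variant_ids[i]] = "none"
        if _annotation_consistent(positions, variant_ids, intervals, truth, near_gap_bp):
            return intervals, truth
    raise InvalidSpecError(
        "could not place annotation intervals without contradicting labels; "
        "variants too dense for interval_length_bp/near_gap_bp"
    )


def _annotation_consistent(positions, variant_ids, intervals, truth, near_gap_bp) -> bool:
    for vid, pos in zip(variant_ids, positions):
        p0 = pos - 1
        status = "none"
        dist = np.inf
        for _, start, end, _ in intervals:
            if start <= p0 < end:
                status = "within"
                break
            dist = min(dist, start - p0 if p0 < start else p0 - (end - 1))
        if status != "within" and dist <= near_gap_bp:
            status = "near"
        if status != truth[vid]:
            return False
    return True


def simulate_faire_baf(
    bundle: TruthBundle,
    imbalance: Mapping[str, float],
    baf_noise_sd: float = 0.02,
    seed: int = 0,
    variants: Sequence[str] | None = None,
):
    """Draw paired control/FAIRE B-allele fractions per sample and variant.

    Heterozygote control BAF ~ N(0.5, sd); heterozygote FAIRE BAF ~
    N(0.5 + shift, sd) where ``shift`` is the injected accessibility
    imbalance for that variant (0 elsewhere); homozygote BAF ~ N(0, sd) or
    N(1, sd).  Draws are clipped to [0, 1].  Returns a list of
    (sample, variant, treatment, baf) rows.
    """
    import pandas as pd

    for v, s in imbalance.items():
        if not -0.5 < s < 0.5:
            raise InvalidSpecError(f"imbalance shift {s} for {v} outside (-0.5, 0.5)")
    rng = np.random.default_rng(seed)
    vids = bundle.variant_ids
    if variants is None:
        variants = list(imbalance)
    rows = []
    samples = bundle.sample_ids
    for vid in variants:
        j = vids.index(vid)
        shift = float(imbalance.get(vid, 0.0))
        dos = bundle.genotypes[:, j]
        centre_control = np.where(dos == 1, 0.5, dos / 2.0)
        centre_faire = np.where(dos == 1, 0.5 + shift, dos / 2.0)
        baf_c = np.clip(rng.normal(centre_control, baf_noise_sd), 0.0, 1.0)
        baf_f = np.clip(rng.normal(centre_faire, baf_noise_sd), 0.0, 1.0)
        for s, bc, bf in zip(samples, baf_c, baf_f):
            rows.append((s, vid, "control", float(bc)))
            rows.append((s, vid, "faire", float(bf)))
    bundle.imbalance_truth.update({v: float(imbalance.get(v, 0.0)) for v in variants})
    return pd.DataFrame(rows, columns=["sample", "variant", "treatment", "baf"])


def simulate_bundle(
    spec: LocusSpec,
    config: CausalConfig,
    fraction_within: float = 0.0,
    fraction_near: float = 0.0,
    near_gap_bp: int = 500,
    interval_length_bp: int = 200,
    force_within: Sequence[int] = (),
) -> TruthBundle:
    """Convenience wrapper: haplotypes + phenotypes + annotations, one seed."""
    rng = np.random.default_rng(spec.seed)
    haps = simulate_haplotypes(spec, config.n_samples, rng)
    bundle = simulate_traits(haps, config, spec, rng)
    if fraction_within or fraction_near or force_within:
        anno_seed = int(rng.integers(0, 2**31 - 1))
        intervals, truth = simulate_annotations(
            spec.positions,
            fraction_within,
            fraction_near,
            interval_length_bp=interval_length_bp,
            near_gap_bp=near_gap_bp,
            seed=anno_seed,
            chrom=spec.chrom,
            variant_ids=bundle.variant_ids,
            force_within=force_within,
        )
        bundle.annotation_intervals = intervals
        bundle.annotation_truth = truth
    else:
        bundle.annotation_truth = {v: "none" for v in bundle.variant_ids}
    return bundle


def write_fixture_bundle(bundle: TruthBundle, out_dir: str | Path, baf: "pd.DataFrame | None" = None) -> dict[str, Path]:
    """Write the bundle to disk as VCF + BED + TSV + FASTA + truth JSON.

    The truth JSON is a test-only sidecar; the pipeline never reads it.
    """
    import pandas as pd

    from .io import write_bed, write_fasta_reference, write_vcf

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["vcf"] = write_vcf(
            out / "locus.vcf",
            chrom=bundle.spec.chrom,
            positions=bundle.spec.positions,
            ids=bundle.variant_ids,
            refs=bundle.ref_alleles,
            alts=bundle.alt_alleles,
            genotypes=bundle.genotypes,
            samples=bundle.sample_ids,
        )
        paths["bed"] = write_bed(out / "annotations.bed", bundle.annotation_intervals)
        pheno = pd.DataFrame({"sample": bundle.sample_ids, "value": bundle.trait})
        paths["trait"] = out / "trait.tsv"
        pheno.to_csv(paths["trait"], sep="\t", index=False)
        expr = pd.DataFrame({"sample": bundle.sample_ids, "value": bundle.expression})
        paths["expression"] = out / "expression.tsv"
        expr.to_csv(paths["expression"], sep="\t", index=False)
        if baf is not None:
            paths["baf"] = out / "baf.tsv"
            baf.to_csv(paths["baf"], sep="\t", index=False)
        paths["fasta"] = write_fasta_reference(
            out / "reference.fa",
            chrom=bundle.spec.chrom,
            length=bundle.spec.positions[-1] + 100,
            positions=bundle.spec.positions,
            ref_alleles=bundle.ref_alleles,
            seed=bundle.spec.seed,
        )
        truth = {
            "spec": dataclasses.asdict(bundle.spec),
            "causal": dataclasses.asdict(bundle.causal_truth),
            "annotation_truth": bundle.annotation_truth,
            "imbalance_truth": bundle.imbalance_truth,
            "maf": bundle.maf().tolist(),
        }
        paths["truth"] = out / "truth.json"
        paths["truth"].write_text(json.dumps(truth, indent=1))
        return paths
    except OSError as exc:
        raise OSError(f"writing fixture bundle under {out}: {exc}") from exc
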