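"""End-to-end localisation workflow.

Stages, in order: obtain genotypes and phenotypes (simulated locus or user
files), LD with the lead SNP, candidate selection, cis association scans for
the trait and the expression phenotype, trait-expression colocalisation,
regulatory-annotation overlap, and allele-specific FAIRE imbalance.  The
output is a prioritisation report assigning each candidate a tier:

    candidate           selected by LD / significance rules
    regulatory          additionally within or near an annotation
    functional_evidence additionally allelic imbalance at p < 0.05

mirroring the funnel that narrows hundreds of associated variants in strong
LD down to a handful with direct functional support.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as annot
from . import coloc as coloc_mod
from . import eqtl as eqtl_mod
from . import io as io_mod
from . import ld as ld_mod
from . import simulate as sim

log = logging.getLogger(__name__)

TIERS = ("candidate", "regulatory", "functional_evidence")


class ConfigError(ValueError):
    pass


@dataclass
class Thresholds:
    r2_min: float = 0.8
    p_gwas: float = 5e-8
    p_eqtl: float = 5e-8
    window_kb: float = 500.0
    cis_kb: float = 200.0
    near_bp: int = 500
    coloc_threshold: float = 0.75
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w: float = 0.0225
    het_delta: float = 0.15

    def __post_init__(self):
        checks = {
            "r2_min": (self.r2_min, 0.0, 1.0),
            "p_gwas": (self.p_gwas, 0.0, 1.0),
            "p_eqtl": (self.p_eqtl, 0.0, 1.0),
            "coloc_threshold": (self.coloc_threshold, 0.0, 1.0),
            "het_delta": (self.het_delta, 0.0, 0.5),
        }
        for name, (v, lo, hi) in checks.items():
            if not lo <= v <= hi:
                raise ConfigError(f"thresholds.{name}={v} outside [{lo}, {hi}]")
        if self.window_kb < 0 or self.cis_kb < 0 or self.near_bp < 0:
            raise ConfigError("window sizes must be non-negative")
        coloc_mod.ColocPriors(p1=self.p1, p2=self.p2, p12=self.p12, w1=self.w, w2=self.w)

    def priors(self) -> coloc_mod.ColocPriors:
        return coloc_mod.ColocPriors(p1=self.p1, p2=self.p2, p12=self.p12, w1=self.w, w2=self.w)


@dataclass
class PipelineConfig:
    out_dir: str = "regulocal_out"
    seed: int = 0
    lead: str | None = None
    anchor_pos: int | None = None
    log_level: str = "INFO"
    thresholds: Thresholds = field(default_factory=Thresholds)
    simulate: dict | None = None
    inputs: dict | None = None

    def __post_init__(self):
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'simulate' and 'inputs' must be given")


_INPUT_KEYS = {"vcf", "gwas", "eqtl", "bed", "baf", "trait", "expression"}
_SIM_KEYS = {
    "n_variants", "block_lengths", "n_founders", "recomb_prob", "mutation_prob",
    "n_samples", "scenario", "trait_causal", "expr_causal", "beta_trait",
    "beta_expr", "noise_sd", "fraction_within", "fraction_near", "imbalance",
    "baf_noise_sd",
}


def validate_config(path: str | Path | None = None, raw: dict | None = None) -> PipelineConfig:
    """Load + validate a YAML config, filling documented defaults.

    Unknown keys are rejected with their field path.  An empty file yields
    the full default configuration (in simulate mode).
    """
    if raw is None:
        raw = yaml.safe_load(Path(path).read_text()) if path is not None else {}
        raw = raw or {}
    known = {"out_dir", "seed", "lead", "anchor_pos", "log_level", "thresholds", "simulate", "inputs"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    thr_raw = raw.get("thresholds") or {}
    unknown = set(thr_raw) - {f.name for f in dataclasses.fields(Thresholds)}
    if unknown:
        raise ConfigError(f"unknown keys under thresholds: {sorted(unknown)}")
    thresholds = Thresholds(**thr_raw)
    simulate = raw.get("simulate")
    inputs = raw.get("inputs")
    if simulate is None and inputs is None:
        simulate = {}
    if simulate is not None:
        unknown = set(simulate) - _SIM_KEYS
        if unknown:
            raise ConfigError(f"unknown keys under simulate: {sorted(unknown)}")
    if inputs is not None:
        unknown = set(inputs) - _INPUT_KEYS
        if unknown:
            raise ConfigError(f"unknown keys under inputs: {sorted(unknown)}")
    return PipelineConfig(
        out_dir=raw.get("out_dir", "regulocal_out"),
        seed=int(raw.get("seed", 0)),
        lead=raw.get("lead"),
        anchor_pos=raw.get("anchor_pos"),
        log_level=raw.get("log_level", "INFO"),
        thresholds=thresholds,
        simulate=simulate,
        inputs=inputs,
    )


def default_locus_spec(seed: int, n_variants: int = 60, n_samples: int = 500, **kw) -> sim.LocusSpec:
    """Study-condition locus: 60 variants in three 20-variant LD blocks."""
    block = kw.pop("block_lengths", None)
    if block is None:
        b = n_variants // 3
        block = (b, b, n_variants - 2 * b)
    return sim.LocusSpec(
        n_variants=n_variants,
        block_lengths=tuple(block),
        n_founders=kw.pop("n_founders", 4),
        recomb_prob=kw.pop("recomb_prob", 0.2),
        mutation_prob=kw.pop("mutation_prob", 0.01),
        seed=seed,
        **kw,
    )


def _simulate_stage(cfg: PipelineConfig):
    s = dict(cfg.simulate or {})
    n_variants = int(s.get("n_variants", 60))
    n_samples = int(s.get("n_samples", 500))
    spec_kw = {}
    for key in ("block_lengths", "n_founders", "recomb_prob", "mutation_prob"):
        if key in s:
            spec_kw[key] = s[key]
    spec = default_locus_spec(cfg.seed, n_variants=n_variants, n_samples=n_samples, **spec_kw)
    scenario = s.get("scenario", "H4")
    causal_default = n_variants // 2
    config = sim.CausalConfig(
        scenario=scenario,
        trait_causal=s.get("trait_causal", causal_default if scenario in ("H1", "H3", "H4") else None),
        expr_causal=s.get(
            "expr_causal",
            causal_default if scenario in ("H2", "H4") else (causal_default + n_variants // 3 if scenario == "H3" else None),
        ),
        beta_trait=float(s.get("beta_trait", 0.4)),
        beta_expr=float(s.get("beta_expr", 0.4)),
        noise_sd=float(s.get("noise_sd", 1.0)),
        n_samples=n_samples,
        seed=cfg.seed,
    )
    force = [i for i in (config.trait_causal, config.expr_causal) if i is not None]
    bundle = sim.simulate_bundle(
        spec,
        config,
        fraction_within=float(s.get("fraction_within", 0.2)),
        fraction_near=float(s.get("fraction_near", 0.1)),
        force_within=sorted(set(force)),
    )
    imbalance = s.get("imbalance")
    if imbalance is None and config.trait_causal is not None:
        imbalance = {bundle.variant_ids[config.trait_causal]: 0.1}
    baf = sim.simulate_faire_baf(
        bundle,
        imbalance or {},
        baf_noise_sd=float(s.get("baf_noise_sd", 0.05)),
        seed=cfg.seed + 7,
    ) if imbalance else None
    return bundle, baf


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Execute all stages; write artifacts under ``config.out_dir``.

    Returns the prioritisation report (also written as TSV + JSON summary).
    Deterministic given the config seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    stage = "setup"
    try:
        if config.simulate is not None:
            stage = "simulate"
            bundle, baf = _simulate_stage(config)
            sim.write_fixture_bundle(bundle, out / "bundle", baf=baf)
            variants = pd.DataFrame(
                {
                    "variant": bundle.variant_ids,
                    "chrom": bundle.spec.chrom,
                    "pos": bundle.spec.positions,
                    "ref": bundle.ref_alleles,
                    "alt": bundle.alt_alleles,
                }
            )
            dosages = bundle.genotypes
            trait = bundle.trait
            expression = bundle.expression
            intervals = pd.DataFrame(
                bundle.annotation_intervals, columns=["chrom", "start", "end", "track"]
            )
            gwas_df = eqtl_df = None
        else:
            stage = "load"
            variants, dosages, samples = io_mod.read_vcf(config.inputs["vcf"])
            trait = expression = None
            if config.inputs.get("trait"):
                ph = io_mod.read_phenotype(config.inputs["trait"]).set_index("sample")
                trait = ph.loc[samples, "value"].to_numpy()
            if config.inputs.get("expression"):
                ph = io_mod.read_phenotype(config.inputs["expression"]).set_index("sample")
                expression = ph.loc[samples, "value"].to_numpy()
            beds = config.inputs.get("bed") or []
            intervals = (
                pd.concat([io_mod.read_bed(b) for b in beds], ignore_index=True)
                if beds
                else pd.DataFrame(columns=["chrom", "start", "end", "track"])
            )
            gwas_df = io_mod.read_summary_stats(config.inputs["gwas"]) if config.inputs.get("gwas") else None
            eqtl_df = io_mod.read_summary_stats(config.inputs["eqtl"]) if config.inputs.get("eqtl") else None
            baf = io_mod.read_baf(config.inputs["baf"]) if config.inputs.get("baf") else None

        anchor = config.anchor_pos or int(np.median(variants["pos"]))
        chrom = str(variants["chrom"].iloc[0])
        window = eqtl_mod.cis_window(anchor, chrom=chrom, half_width_bp=int(thr.cis_kb * 1000))

        stage = "association"
        if gwas_df is None and trait is not None:
            stats_t, _ = eqtl_mod.scan(dosages, variants, trait, window=window, trait_id="trait")
            gwas_df = eqtl_mod.stats_to_frame(stats_t, variants)
        if eqtl_df is None and expression is not None:
            stats_e, _ = eqtl_mod.scan(dosages, variants, expression, window=window, trait_id="expression")
            eqtl_df = eqtl_mod.stats_to_frame(stats_e, variants)
        if gwas_df is not None:
            io_mod.write_summary_stats(out / "gwas_stats.tsv", gwas_df)
        if eqtl_df is not None:
            io_mod.write_summary_stats(out / "eqtl_stats.tsv", eqtl_df)

        stage = "ld"
        lead = config.lead
        if lead is None and gwas_df is not None and len(gwas_df):
            lead = gwas_df.loc[gwas_df["p"].idxmin(), "variant"]
        if lead is None:
            raise ConfigError("no lead variant given and no GWAS stats to derive one")
        ld_results = ld_mod.ld_with_lead(dosages, list(variants["variant"]), lead)
        log.info("stage ld: lead=%s, %d variants", lead, len(ld_results))

        stage = "candidates"
        candidates = ld_mod.select_candidates(
            ld_results,
            gwas_df,
            eqtl_df,
            r2_min=thr.r2_min,
            p_gwas=thr.p_gwas,
            p_eqtl=thr.p_eqtl,
            locus_window_bp=int(thr.window_kb * 1000),
            gene_anchor_pos=anchor,
        )
        log.info("stage candidates: retained %d variants", len(candidates))

        stage = "coloc"
        coloc_json = {}
        if gwas_df is not None and eqtl_df is not None:
            result = coloc_mod.coloc_posteriors(gwas_df, eqtl_df, thr.priors())
            labels = coloc_mod.classify(result, threshold=thr.coloc_threshold)
            coloc_json = {
                "pp": result.pp,
                "n_variants": result.n_variants,
                "priors": dataclasses.asdict(result.priors),
                "labels": labels,
            }
            (out / "coloc.json").write_text(json.dumps(coloc_json, indent=1))

        stage = "annotate"
        matrix = annot.build_annotation_matrix(variants, intervals, near_bp=thr.near_bp)
        matrix.to_table().to_csv(out / "annotation_matrix.tsv", sep="\t")
        summary_status = matrix.summary_status()

        stage = "faire"
        imbalance_df = pd.DataFrame(columns=["variant", "enrichment_pct", "t_stat", "p"])
        if baf is not None and len(baf):
            from .faire import scan_imbalance

            imbalance_df = scan_imbalance(baf, delta=thr.het_delta)
            imbalance_df.to_csv(out / "imbalance.tsv", sep="\t", index=False)

        stage = "report"
        r2_by_id = {r.variant_id: r.r2 for r in ld_results}
        imb_by_id = imbalance_df.set_index("variant") if len(imbalance_df) else None
        rows = []
        for vid in candidates.variant_ids:
            status = summary_status.get(vid, "none")
            imb_p = imb_enr = np.nan
            if imb_by_id is not None and vid in imb_by_id.index:
                imb_p = float(imb_by_id.loc[vid, "p"])
                imb_enr = float(imb_by_id.loc[vid, "enrichment_pct"])
            tier = "candidate"
            if status in ("within", "near"):
                tier = "regulatory"
                if np.isfinite(imb_p) and imb_p < 0.05:
                    tier = "functional_evidence"
            gp = gwas_df.set_index("variant")["p"].get(vid, np.nan) if gwas_df is not None else np.nan
            ep = eqtl_df.set_index("variant")["p"].get(vid, np.nan) if eqtl_df is not None else np.nan
            rows.append(
                {
                    "variant": vid,
                    "flags": ",".join(sorted(candidates.flags[vid])),
                    "r2": r2_by_id.get(vid),
                    "gwas_p": gp,
                    "eqtl_p": ep,
                    "annotation": status,
                    "imbalance_p": imb_p,
                    "enrichment_pct": imb_enr,
                    "tier": tier,
                }
            )
        report = pd.DataFrame(rows, columns=[
            "variant", "flags", "r2", "gwas_p", "eqtl_p", "annotation",
            "imbalance_p", "enrichment_pct", "tier",
        ])
        report.to_csv(out / "report.tsv", sep="\t", index=False)
        tier_counts = report["tier"].value_counts().to_dict() if len(report) else {}
        summary = {
            "lead": lead,
            "n_candidates": len(report),
            "tiers": tier_counts,
            "coloc": coloc_json,
            "seed": config.seed,
            "thresholds": dataclasses.asdict(thr),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        return report
    except Exception as exc:
        if isinstance(exc, ConfigError):
            raise
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
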