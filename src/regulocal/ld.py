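"""Pairwise LD with a lead SNP and candidate-pool construction.

LD is the squared Pearson correlation of genotype dosages over
pairwise-complete samples (composite LD) — the standard surrogate for
haplotype-based r-squared when phase is unknown.  The candidate pool is the
union of three evidence rules: strong LD with the lead SNP, genome-wide
GWAS significance within a window of the target gene, and eQTL significance
(the latter intersected with the LD rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1  # dosage code for a missing genotype


class UndefinedLdError(ValueError):
    """LD is undefined: a site is monomorphic among informative samples."""


@dataclass(frozen=True)
class LdResult:
    variant_id: str
    lead_id: str
    r2: float | None  # None when LD is undefined at this pair
    n_informative: int

    @property
    def defined(self) -> bool:
        return self.r2 is not None


@dataclass
class CandidateSet:
    """Variant ids retained with per-variant provenance flags."""

    flags: dict[str, set[str]] = field(default_factory=dict)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.flags)

    def __len__(self) -> int:
        return len(self.flags)

    def __contains__(self, vid: str) -> bool:
        return vid in self.flags

    def add(self, vid: str, flag: str) -> None:
        self.flags.setdefault(vid, set()).add(flag)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant": list(self.flags),
                "flags": [",".join(sorted(f)) for f in self.flags.values()],
            }
        )


def r2(dosage_a, dosage_b) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing genotypes (coded -1 or NaN) are handled pairwise-complete.
    Raises :class:`UndefinedLdError` if fewer than two informative samples
    remain or either site is monomorphic among them (distinct from r2 = 0).
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    keep = ~(np.isnan(a) | np.isnan(b) | (a == MISSING) | (b == MISSING))
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise UndefinedLdError(f"only {a.size} informative samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedLdError("monomorphic site among informative samples")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_with_lead(dosages: np.ndarray, variant_ids: list[str], lead_id: str) -> list[LdResult]:
    """LD of every variant with the lead SNP; undefined pairs are flagged."""
    if lead_id not in variant_ids:
        raise KeyError(f"lead variant {lead_id!r} not present in genotypes")
    lead_ix = variant_ids.index(lead_id)
    lead = dosages[:, lead_ix]
    out = []
    for j, vid in enumerate(variant_ids):
        a, b = np.asarray(lead, float), np.asarray(dosages[:, j], float)
        keep = ~(np.isnan(a) | np.isnan(b) | (a == MISSING) | (b == MISSING))
        n_inf = int(keep.sum())
        try:
            val = r2(lead, dosages[:, j])
        except UndefinedLdError:
            val = None
        out.append(LdResult(variant_id=vid, lead_id=lead_id, r2=val, n_informative=n_inf))
    return out


def select_candidates(
    ld: list[LdResult],
    gwas: pd.DataFrame | None,
    eqtl: pd.DataFrame | None,
    r2_min: float = 0.8,
    p_gwas: float = 5e-8,
    p_eqtl: float = 5e-8,
    locus_window_bp: int = 500_000,
    gene_anchor_pos: int | None = None,
    window_applies_to_eqtl: bool = False,
) -> CandidateSet:
    """Union rule for the candidate pool.

    retained = {r2 >= r2_min with lead}
             | {GWAS p < p_gwas and |pos - gene_anchor_pos| <= locus_window_bp}
             | {eQTL p < p_eqtl and r2 >= r2_min}

    The r2 threshold is inclusive; p thresholds are strict.  The eQTL
    significance cut-off defaults to the genome-wide threshold and is
    configurable; ``window_applies_to_eqtl`` optionally also restricts eQTL
    hits to the gene window.
    """
    cand = CandidateSet()
    r2_by_id = {res.variant_id: res.r2 for res in ld}
    for res in ld:
        if res.defined and res.r2 >= r2_min:
            cand.add(res.variant_id, "ld_with_lead")

    def in_window(row) -> bool:
        if gene_anchor_pos is None or "pos" not in row or pd.isna(row.get("pos")):
            return True
        return abs(int(row["pos"]) - gene_anchor_pos) <= locus_window_bp

    if gwas is not None and len(gwas):
        for _, row in gwas.iterrows():
            if row["p"] < p_gwas and in_window(row):
                cand.add(row["variant"], "gwas_significant")
    if eqtl is not None and len(eqtl):
        for _, row in eqtl.iterrows():
            vid = row["variant"]
            ld_ok = r2_by_id.get(vid) is not None and r2_by_id[vid] >= r2_min
            win_ok = in_window(row) if window_applies_to_eqtl else True
            if row["p"] < p_eqtl and ld_ok and win_ok:
                cand.add(vid, "eqtl_significant")
    if not len(cand):
        log.warning("candidate selection produced an empty set")
    return cand
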