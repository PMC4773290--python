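"""Allele-specific chromatin accessibility from B-allele fractions.

Heterozygotes are called from the non-enriched (control) array channel; a
paired t-test then compares each heterozygote's B-allele fraction between
FAIRE-enriched and control chromatin.  A shift of the FAIRE BAF away from
0.5 means one allele sits in open chromatin more often than the other.
The same module provides the two-sample t-test used to compare normalised
reporter-assay ratios between allele groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class PairingError(ValueError):
    """A heterozygote lacks a matched control/FAIRE record pair."""


@dataclass(frozen=True)
class ImbalanceResult:
    variant_id: str
    n_het: int
    mean_baf_control: float
    mean_baf_faire: float
    enriched_allele: str  # "A" or "B"
    enrichment_pct: float
    t_stat: float
    p: float
    df: int
    degenerate: bool = False


@dataclass(frozen=True)
class ReporterAssayResult:
    groups: tuple[str, str]
    n: tuple[int, int]
    mean_ratio: tuple[float, float]
    t_stat: float
    p: float


def call_heterozygotes(control: pd.DataFrame, delta: float = 0.15) -> list[str]:
    """Samples whose control BAF falls in [0.5 - delta, 0.5 + delta] (inclusive).

    ``control`` holds control-treatment records for one variant with columns
    sample/baf.  Samples below the band are hom-A, above it hom-B.
    """
    baf = control["baf"].to_numpy(float)
    het = (baf >= 0.5 - delta) & (baf <= 0.5 + delta)
    return control.loc[het, "sample"].tolist()


def allelic_imbalance(records: pd.DataFrame, het_samples: list[str]) -> ImbalanceResult:
    """Paired FAIRE-vs-control t-test on heterozygote B-allele fractions.

    Differences d_i = baf_faire,i - baf_control,i; t = mean(d) / (sd(d)/sqrt(n));
    two-sided p from Student-t with n - 1 df.  The enriched allele is B when
    mean(d) > 0 else A, and enrichment_pct is the relative change of the
    enriched allele's mean fraction between control and FAIRE.
    """
    vid = str(records["variant"].iloc[0]) if len(records) else ""
    if len(het_samples) < 2:
        raise ValueError(f"{vid}: need >= 2 heterozygotes for a paired test")
    sub = records[records["sample"].isin(het_samples)]
    wide = sub.pivot_table(index="sample", columns="treatment", values="baf", aggfunc="first")
    bad = [
        s for s in het_samples
        if s not in wide.index or wide.loc[s][["control", "faire"]].isna().any()
    ]
    if bad or not {"control", "faire"} <= set(wide.columns):
        raise PairingError(f"{vid}: unpaired control/faire records for samples {bad or het_samples}")
    wide = wide.loc[het_samples]
    control = wide["control"].to_numpy(float)
    faire = wide["faire"].to_numpy(float)
    d = faire - control
    n = d.size
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    degenerate = False
    if sd_d == 0.0:
        if mean_d == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = math_inf_sign(mean_d)
            p = 0.0
            degenerate = True
    else:
        t_stat = mean_d / (sd_d / np.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(t_stat), n - 1))
    if mean_d > 0:
        allele, frac_c, frac_f = "B", control.mean(), faire.mean()
    else:
        allele, frac_c, frac_f = "A", 1.0 - control.mean(), 1.0 - faire.mean()
    enrichment = 100.0 * abs(frac_f - frac_c) / frac_c if frac_c > 0 else np.inf
    return ImbalanceResult(
        variant_id=vid,
        n_het=n,
        mean_baf_control=float(control.mean()),
        mean_baf_faire=float(faire.mean()),
        enriched_allele=allele,
        enrichment_pct=float(enrichment),
        t_stat=float(t_stat),
        p=float(p),
        df=n - 1,
        degenerate=degenerate,
    )


def math_inf_sign(x: float) -> float:
    return float(np.inf) if x > 0 else float(-np.inf)


def scan_imbalance(baf: pd.DataFrame, delta: float = 0.15, min_het: int = 2) -> pd.DataFrame:
    """Heterozygote calling + paired test for every variant in a BAF table."""
    rows = []
    for vid, grp in baf.groupby("variant", sort=True):
        hets = call_heterozygotes(grp[grp["treatment"] == "control"], delta=delta)
        if len(hets) < min_het:
            continue
        res = allelic_imbalance(grp, hets)
        rows.append(
            {
                "variant": vid,
                "n_het": res.n_het,
                "mean_baf_control": res.mean_baf_control,
                "mean_baf_faire": res.mean_baf_faire,
                "enriched_allele": res.enriched_allele,
                "enrichment_pct": res.enrichment_pct,
                "t_stat": res.t_stat,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)


def reporter_ratio_test(wells: pd.DataFrame) -> ReporterAssayResult:
    """Two-sample t-test on reporter/control ratios between allele groups.

    ``wells`` has columns well/group/reporter/control with exactly two group
    labels and one matched reporter + control reading per well.
    """
    bad = wells[wells["control"] <= 0]
    if len(bad):
        raise ValueError(f"non-positive control readings in wells {bad['well'].tolist()}")
    groups = sorted(wells["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 allele groups, got {groups}")
    ratios = wells["reporter"] / wells["control"]
    a = ratios[wells["group"] == groups[0]].to_numpy(float)
    b = ratios[wells["group"] == groups[1]].to_numpy(float)
    if min(a.size, b.size) < 2:
        raise ValueError("each group needs >= 2 wells for a t-test")
    t_stat, p = stats.ttest_ind(a, b)
    return ReporterAssayResult(
        groups=(groups[0], groups[1]),
        n=(a.size, b.size),
        mean_ratio=(float(a.mean()), float(b.mean())),
        t_stat=float(t_stat),
        p=float(p),
    )
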