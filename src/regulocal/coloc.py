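"""Bayesian colocalisation of two association signals at one locus.

Given per-variant summary statistics for two traits (e.g. a lipid trait and
liver expression of the candidate gene), each variant receives a Wakefield
asymptotic Bayes factor per trait,

    log ABF = 1/2 [ log(1 - r) + r z^2 ],   r = w / (V + w),

with z = beta/se, V = se^2 and w the prior variance of the true effect.
Assuming at most one causal variant per trait, the evidence for five
hypotheses is accumulated over single-variant configurations:

    H0 neither trait associated; H1 trait 1 only; H2 trait 2 only;
    H3 both, two distinct causal variants; H4 one shared causal variant.

All accumulation happens in log space (log-sum-exp); no raw Bayes-factor
products are ever materialised.  A posterior above the strong-evidence
threshold (default 75%, strict) is labelled "strong".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

log = logging.getLogger(__name__)

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant causal priors and effect-size prior variances.

    p1/p2: prior that a variant is causal for trait 1/2 only; p12: prior it
    is causal for both.  w1/w2: prior variance of the true effect per trait
    in squared phenotype-SD units (0.15 SD prior effect -> w = 0.0225, the
    conventional quantitative-trait choice).
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w1: float = 0.0225
    w2: float = 0.0225

    def __post_init__(self):
        if not (0 < self.p12 <= min(self.p1, self.p2) and max(self.p1, self.p2) < 1):
            raise ValueError("require 0 < p12 <= p1, p2 < 1")
        if self.w1 <= 0 or self.w2 <= 0:
            raise ValueError("prior effect variances must be > 0")


@dataclass
class ColocResult:
    pp: dict[str, float]
    n_variants: int
    priors: ColocPriors
    log_abf_1: np.ndarray = field(repr=False, default=None)
    log_abf_2: np.ndarray = field(repr=False, default=None)
    variant_ids: list[str] = field(default_factory=list)

    def __getitem__(self, h: str) -> float:
        return self.pp[h]

    @property
    def best(self) -> str:
        return max(self.pp, key=self.pp.get)


def log_abf(beta: float, se: float, w: float) -> float:
    """Wakefield log asymptotic Bayes factor in favour of association."""
    if se <= 0:
        raise ValueError(f"se must be > 0, got {se}")
    if w <= 0:
        raise ValueError(f"prior variance must be > 0, got {w}")
    V = se * se
    r = w / (V + w)
    z = beta / se
    return 0.5 * (math.log1p(-r) + r * z * z)


def zscore_from_p(p: float, sign: float = 1.0) -> float:
    """Signed standard-normal quantile recovering z from a two-sided p."""
    if not 0 < p <= 1:
        raise ValueError(
            "p must be in (0, 1]; for p = 0 supply beta/se directly" if p == 0 else f"invalid p {p}"
        )
    return math.copysign(stats.norm.isf(p / 2.0), sign)


def var_from_freq(maf: float, n: int) -> float:
    """Approximate sampling variance of beta for a standardized trait."""
    if not 0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    return 1.0 / (2.0 * n * maf * (1.0 - maf))


def _log_abf_table(df: pd.DataFrame, w: float) -> np.ndarray:
    """Per-variant log ABFs from (beta, se) where available, else (p, maf, n)."""
    out = np.empty(len(df))
    for i, row in enumerate(df.itertuples(index=False)):
        beta = getattr(row, "beta", np.nan)
        se = getattr(row, "se", np.nan)
        if np.isfinite(beta) and np.isfinite(se) and se > 0:
            out[i] = log_abf(float(beta), float(se), w)
            continue
        p = getattr(row, "p", np.nan)
        maf = getattr(row, "maf", np.nan)
        n = getattr(row, "n", np.nan)
        if not (np.isfinite(p) and np.isfinite(maf) and np.isfinite(n)):
            raise ValueError(
                f"variant {getattr(row, 'variant', i)}: need (beta, se) or (p, maf, n)"
            )
        z = zscore_from_p(float(p), math.copysign(1.0, beta) if np.isfinite(beta) else 1.0)
        V = var_from_freq(float(maf), int(n))
        se_eff = math.sqrt(V)
        out[i] = log_abf(z * se_eff, se_eff, w)
    return out


def coloc_posteriors(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    priors: ColocPriors = ColocPriors(),
) -> ColocResult:
    """Five-hypothesis posteriors from two joined summary-stat tables.

    Tables are joined on ``variant`` (intersection; singletons dropped with a
    logged count).  With per-variant log Bayes factors l1, l2 the
    unnormalised log hypothesis weights are::

        L0 = 0
        L1 = log p1  + logsum(l1)
        L2 = log p2  + logsum(l2)
        L3 = log p1 + log p2 + logdiff(logsum(l1) + logsum(l2), logsum(l1 + l2))
        L4 = log p12 + logsum(l1 + l2)

    and pp = softmax(L0..L4).  With a single shared variant H3 is impossible
    and pp[H3] is exactly 0.
    """
    merged = stats1.merge(stats2, on="variant", suffixes=("_1", "_2"))
    n_dropped = (len(stats1) - len(merged)) + (len(stats2) - len(merged))
    if n_dropped:
        log.info("coloc: dropped %d variant rows present in only one table", n_dropped)
    if merged.empty:
        raise ValueError("no shared variants between the two summary-stat tables")

    def side(suffix: str) -> pd.DataFrame:
        cols = {c: c[: -len(suffix)] for c in merged.columns if c.endswith(suffix)}
        return merged[["variant", *cols]].rename(columns=cols)

    l1 = _log_abf_table(side("_1"), priors.w1)
    l2 = _log_abf_table(side("_2"), priors.w2)
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # log( sum_{i != j} BF1_i BF2_j ) = logdiff(s1 + s2, s12)
    if len(merged) == 1 or s1 + s2 <= s12:
        if len(merged) > 1 and s1 + s2 < s12:
            log.warning("coloc: cross-configuration sum numerically negative; H3 weight set to 0")
        l3_cross = -np.inf
    else:
        l3_cross = s1 + s2 + math.log1p(-math.exp(s12 - (s1 + s2)))
    weights = np.array(
        [
            0.0,
            math.log(priors.p1) + s1,
            math.log(priors.p2) + s2,
            math.log(priors.p1) + math.log(priors.p2) + l3_cross,
            math.log(priors.p12) + s12,
        ]
    )
    pp = np.exp(weights - logsumexp(weights))
    pp = pp / pp.sum()
    return ColocResult(
        pp=dict(zip(HYPOTHESES, pp.tolist())),
        n_variants=len(merged),
        priors=priors,
        log_abf_1=l1,
        log_abf_2=l2,
        variant_ids=merged["variant"].tolist(),
    )


def classify(result: ColocResult, threshold: float = 0.75) -> dict[str, str]:
    """Label each hypothesis "strong" if its posterior strictly exceeds the
    threshold, else "inconclusive"."""
    return {
        h: "strong" if p > threshold else "inconclusive" for h, p in result.pp.items()
    }
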