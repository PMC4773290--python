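"""Marginal cis-window association scan.

Each variant in a window around the expression probe (or gene anchor) is
regressed one at a time against the phenotype by ordinary least squares with
an intercept; the slope's two-sided p-value comes from a Student-t reference
with n - 2 degrees of freedom.  The same code path serves lipid traits and
expression phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ld import MISSING


class NoTestError(ValueError):
    """The regression cannot be run (monomorphic dosage or too few samples)."""


@dataclass(frozen=True)
class AssociationStat:
    """Per-variant marginal regression summary for one trait."""

    variant_id: str
    trait_id: str
    beta: float
    se: float
    z: float
    p: float
    n: int
    maf: float
    degenerate: bool = False  # zero residual variance (perfect fit)


@dataclass(frozen=True)
class CisWindow:
    """1-based inclusive window centred on a probe/gene anchor."""

    chrom: str
    anchor_pos: int
    half_width_bp: int = 200_000

    @property
    def start(self) -> int:
        return max(1, self.anchor_pos - self.half_width_bp)

    @property
    def end(self) -> int:
        return self.anchor_pos + self.half_width_bp

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def cis_window(anchor_pos: int, chrom: str = "1", half_width_bp: int = 200_000) -> CisWindow:
    if anchor_pos < 1:
        raise ValueError("anchor_pos is 1-based and must be >= 1")
    return CisWindow(chrom=chrom, anchor_pos=anchor_pos, half_width_bp=half_width_bp)


def marginal_regression(
    dosage,
    phenotype,
    variant_id: str = "",
    trait_id: str = "",
    covariates: np.ndarray | None = None,
) -> AssociationStat:
    """OLS of phenotype on intercept + dosage (+ optional covariates).

    Missing dosages (-1 or NaN) are dropped pairwise.  A perfect fit (zero
    residual variance) returns se = 0, p = 0 with the degenerate flag set.
    """
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    keep = ~(np.isnan(g) | np.isnan(y) | (g == MISSING))
    g, y = g[keep], y[keep]
    n = g.size
    if n < 3:
        raise NoTestError(f"{variant_id or 'variant'}: need >= 3 complete samples, got {n}")
    if np.ptp(g) == 0:
        raise NoTestError(f"{variant_id or 'variant'}: monomorphic dosage")
    X = np.column_stack([np.ones(n), g])
    if covariates is not None:
        X = np.column_stack([X, np.asarray(covariates, float)[keep]])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - X.shape[1]
    if df < 1:
        raise NoTestError("no residual degrees of freedom")
    rss = float(resid @ resid)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = float(coef[1])
    freq = g.mean() / 2.0
    maf = float(min(freq, 1.0 - freq))
    if rss <= 1e-30 * max(1.0, float(y @ y)):
        return AssociationStat(variant_id, trait_id, beta, 0.0, np.inf, 0.0, n, maf, degenerate=True)
    sigma2 = rss / df
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    z = beta / se
    p = float(2.0 * stats.t.sf(abs(z), df))
    p = max(p, np.finfo(float).tiny)
    return AssociationStat(variant_id, trait_id, beta, se, float(z), p, n, maf)


def scan(
    dosages: np.ndarray,
    variants: pd.DataFrame,
    phenotype,
    window: CisWindow | None = None,
    trait_id: str = "trait",
) -> tuple[list[AssociationStat], list[str]]:
    """One marginal regression per polymorphic variant inside the window.

    ``variants`` needs columns variant/chrom/pos.  Returns stats ordered by
    position plus a skip report of variants failing preconditions.
    """
    stats_out: list[AssociationStat] = []
    skipped: list[str] = []
    order = variants["pos"].to_numpy().argsort(kind="stable")
    for j in order:
        row = variants.iloc[j]
        if window is not None and not window.contains(int(row["pos"])):
            continue
        try:
            stats_out.append(
                marginal_regression(dosages[:, j], phenotype, variant_id=row["variant"], trait_id=trait_id)
            )
        except NoTestError as exc:
            skipped.append(f"{row['variant']}: {exc}")
    return stats_out, skipped


def stats_to_frame(stats_list: list[AssociationStat], variants: pd.DataFrame | None = None) -> pd.DataFrame:
    """Summary-stat table in the pipeline's TSV schema."""
    df = pd.DataFrame(
        {
            "variant": [s.variant_id for s in stats_list],
            "beta": [s.beta for s in stats_list],
            "se": [s.se for s in stats_list],
            "p": [s.p for s in stats_list],
            "n": [s.n for s in stats_list],
            "maf": [s.maf for s in stats_list],
            "trait": [s.trait_id for s in stats_list],
        }
    )
    if variants is not None:
        df = df.merge(variants[["variant", "chrom", "pos", "ref", "alt"]], on="variant", how="left")
    return df
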