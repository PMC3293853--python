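"""Factorial contrast analysis of the four-condition design.

The design is a 2x2 factorial: strain (wild type vs regulator deletion)
crossed with supplementation (control vs arginine), conditions labelled

* A — wild type, control
* B — wild type, +arginine
* C — deletion mutant, control
* D — deletion mutant, +arginine

Five contrasts of the condition means are tested per gene ("second minus
first" along each comparison arrow):

* c1 = C - A   strain effect under control conditions
* c2 = B - A   arginine effect in the wild type
* c3 = D - C   arginine effect in the mutant
* c4 = D - B   strain effect under arginine
* c5 = c3 - c2 interaction (differential arginine response)

Condition means are the per-gene OLS estimates of a one-way layout on the
replicate M_g values; t statistics use the variance pooled over the four
conditions.  p-values are two-sided; Benjamini-Hochberg adjustment is
applied within each contrast across genes.  Each contrast is then
discretized into the ternary H_r code: 0 if not significant at the
uncorrected level alpha, otherwise the sign of the contrast estimate M_c.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CONDITIONS", "CONTRAST_VECTORS", "CONTRAST_NAMES",
    "ExpressionSet", "ContrastResult", "fit_contrasts", "classify_hr",
]

logger = logging.getLogger(__name__)

CONDITIONS = ("A", "B", "C", "D")
CONTRAST_NAMES = ("c1", "c2", "c3", "c4", "c5")

#: coefficient vectors over the condition means (A, B, C, D)
CONTRAST_VECTORS = {
    "c1": np.array([-1.0, 0.0, 1.0, 0.0]),   # C - A
    "c2": np.array([-1.0, 1.0, 0.0, 0.0]),   # B - A
    "c3": np.array([0.0, 0.0, -1.0, 1.0]),   # D - C
    "c4": np.array([0.0, -1.0, 0.0, 1.0]),   # D - B
    "c5": np.array([1.0, -1.0, -1.0, 1.0]),  # (D - C) - (B - A)
}

VARIANCE_FLOOR = 1e-12


@dataclass
class ExpressionSet:
    """Normalized M_g matrix (genes x arrays) plus array metadata.

    ``conditions`` maps each array (column of ``mg``) to one of A-D.
    Missing values are allowed; model fitting requires each involved
    condition to retain at least 2 replicates per gene.
    """

    mg: pd.DataFrame
    conditions: pd.Series
    replicates: pd.Series | None = None

    def __post_init__(self):
        self.conditions = self.conditions.reindex(self.mg.columns)
        if self.conditions.isna().any():
            missing = list(self.mg.columns[self.conditions.isna()])
            raise ValueError(f"arrays without condition labels: {missing}")
        bad = set(self.conditions) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        counts = self.conditions.value_counts()
        thin = [c for c in CONDITIONS if counts.get(c, 0) < 2]
        if thin:
            raise ValueError(
                f"conditions with fewer than 2 replicate arrays: {thin}")
        if self.mg.index.has_duplicates:
            raise ValueError("gene ids must be unique")

    @property
    def genes(self) -> pd.Index:
        return self.mg.index


@dataclass
class ContrastResult:
    """Per-gene, per-contrast estimates: M_c, t, p and BH-adjusted p."""

    mc: pd.DataFrame
    t: pd.DataFrame
    p: pd.DataFrame
    p_fdr: pd.DataFrame
    df: pd.Series = field(repr=False, default=None)

    @property
    def genes(self) -> pd.Index:
        return self.mc.index


def fit_contrasts(
    eset: ExpressionSet,
    *,
    alpha: float = 0.05,
    moderate: bool = False,
    prior_df: float = 4.0,
) -> ContrastResult:
    """Estimate the five contrasts for every gene.

    With ``moderate=True`` each gene's pooled variance is shrunk toward
    the median gene variance with ``prior_df`` pseudo-degrees of freedom
    (a simple stabilizer for designs with few replicates; off by default).
    A gene is dropped from a contrast (M_c = 0, p = 1) when any condition
    the contrast involves has fewer than 2 surviving replicates.
    """
    X = eset.mg.to_numpy(float)
    cond = eset.conditions.to_numpy()
    n_genes = X.shape[0]

    means = np.zeros((n_genes, 4))
    counts = np.zeros((n_genes, 4))
    rss = np.zeros(n_genes)
    for k, c in enumerate(CONDITIONS):
        cols = cond == c
        block = X[:, cols]
        ok = ~np.isnan(block)
        counts[:, k] = ok.sum(axis=1)
        with np.errstate(invalid="ignore"):
            s = np.where(ok, block, 0.0).sum(axis=1)
            means[:, k] = np.where(counts[:, k] > 0, s / np.maximum(counts[:, k], 1), np.nan)
            resid = np.where(ok, block - means[:, k][:, None], 0.0)
        rss += (resid ** 2).sum(axis=1)

    df = (np.maximum(counts - 1, 0)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(df > 0, rss / np.maximum(df, 1), np.nan)
    if moderate:
        s2_med = np.nanmedian(s2)
        s2 = (prior_df * s2_med + df * s2) / (prior_df + df)
        df = df + prior_df
    floored = s2 < VARIANCE_FLOOR
    if np.any(floored):
        logger.info("residual variance floored at %g for %d genes",
                    VARIANCE_FLOOR, int(floored.sum()))
        s2 = np.maximum(s2, VARIANCE_FLOOR)

    mc = {}
    tstat = {}
    pval = {}
    for name in CONTRAST_NAMES:
        v = CONTRAST_VECTORS[name]
        involved = v != 0
        ok = (counts[:, involved] >= 2).all(axis=1) & (df > 0)
        if name == "c5":
            # computed literally as c3 - c2 so the identity is exact
            est = mc["c3"] - mc["c2"]
        else:
            est = means @ v
        est = np.where(ok, est, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(s2 * (v[involved] ** 2 / counts[:, involved]).sum(axis=1))
            t = np.where(ok & (se > 0), est / np.where(se > 0, se, 1.0), 0.0)
        p = np.where(ok, 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1)), 1.0)
        n_drop = int((~ok).sum())
        if n_drop:
            logger.info("contrast %s: %d genes dropped "
                        "(insufficient replicates)", name, n_drop)
        mc[name] = est
        tstat[name] = t
        pval[name] = p

    genes = eset.genes
    p_df = pd.DataFrame(pval, index=genes, columns=list(CONTRAST_NAMES))
    fdr = p_df.apply(
        lambda col: multipletests(col.to_numpy(), method="fdr_bh")[1], axis=0)
    return ContrastResult(
        mc=pd.DataFrame(mc, index=genes, columns=list(CONTRAST_NAMES)),
        t=pd.DataFrame(tstat, index=genes, columns=list(CONTRAST_NAMES)),
        p=p_df,
        p_fdr=pd.DataFrame(fdr, index=genes, columns=list(CONTRAST_NAMES)),
        df=pd.Series(df, index=genes, name="df"),
    )


def classify_hr(res: ContrastResult, alpha: float = 0.05) -> pd.DataFrame:
    """Ternary H_r codes per gene and contrast, plus the significance gate.

    H_r = 0 when the uncorrected p >= alpha (or M_c is exactly 0);
    otherwise sign(M_c).  The ``significant`` column is the FDR gate:
    BH-adjusted p < alpha in at least one contrast.
    """
    hr = np.where(
        (res.p.to_numpy() < alpha) & (res.mc.to_numpy() != 0),
        np.sign(res.mc.to_numpy()).astype(int), 0)
    out = pd.DataFrame(hr, index=res.genes,
                       columns=[f"h{i}" for i in range(1, 6)], dtype=int)
    out["significant"] = res.p_fdr.min(axis=1) < alpha
    return out
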