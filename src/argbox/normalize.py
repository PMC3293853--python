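"""Two-channel reference-design array normalization.

Each array carries a cDNA channel (Cy3) against a common genomic-DNA
reference channel (Cy5).  Per spot, M = log2(Cy3/Cy5) measures relative
transcript abundance and A = 0.5*log2(Cy3*Cy5) overall intensity.
Normalization is two-step:

1. print-tip correction — subtract each print-tip group's weighted median
   of M (unit weights for unmasked spots; a group with fewer than 10
   usable spots falls back to the global median);
2. global loess — fit a smooth trend of M on A over all unmasked spots
   (lowess, span 0.3, 2 robustness iterations) and subtract it.

Within-array duplicate spots are then averaged into one M_g value per gene.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = ["spot_mvalues", "normalize_array", "collapse_duplicates"]

logger = logging.getLogger(__name__)

MIN_TIP_SPOTS = 10


def spot_mvalues(cy3: np.ndarray, cy5: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (M, A) per spot from the two channel intensities."""
    cy3 = np.asarray(cy3, float)
    cy5 = np.asarray(cy5, float)
    m = np.log2(cy3 / cy5)
    a = 0.5 * np.log2(cy3 * cy5)
    return m, a


def normalize_array(
    spots: pd.DataFrame,
    *,
    span: float = 0.3,
    iterations: int = 2,
    cy3: str = "cy3",
    cy5: str = "cy5",
    tip: str = "tip",
    mask: str = "mask",
) -> pd.Series:
    """Normalize one array's spot table to corrected M values.

    ``spots`` needs the two channel columns, a print-tip group column and
    optionally a boolean/int ``mask`` column (nonzero = excluded spot).
    Masked spots come back as NaN.  Unmasked spots must have strictly
    positive intensities in both channels.
    """
    masked = (spots[mask].to_numpy().astype(bool)
              if mask in spots.columns else np.zeros(len(spots), bool))
    c3 = spots[cy3].to_numpy(float)
    c5 = spots[cy5].to_numpy(float)
    bad = (~masked) & ((c3 <= 0) | (c5 <= 0))
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} unmasked spots with nonpositive intensities; "
            "mask them before normalizing")

    m = np.full(len(spots), np.nan)
    a = np.full(len(spots), np.nan)
    use = ~masked
    m[use], a[use] = spot_mvalues(c3[use], c5[use])

    # step 1: per print-tip weighted median centering
    tips = spots[tip].to_numpy()
    global_median = float(np.median(m[use]))
    for t in pd.unique(tips):
        sel = use & (tips == t)
        if sel.sum() < MIN_TIP_SPOTS:
            logger.info("print-tip group %r has %d usable spots; "
                        "using global median", t, int(sel.sum()))
            m[sel] -= global_median
        else:
            m[sel] -= float(np.median(m[sel]))

    # step 2: global loess of M on A
    if use.sum() >= 3:
        trend = lowess(m[use], a[use], frac=span, it=iterations,
                       return_sorted=False)
        m[use] -= trend
    return pd.Series(m, index=spots.index, name="M")


def collapse_duplicates(spots: pd.DataFrame, *, gene: str = "gene_id",
                        m: str = "M") -> pd.Series:
    """Average within-array duplicate spots into one M_g value per gene.

    NaN (masked) spots are skipped; a gene whose spots are all masked
    comes back NaN.
    """
    return spots.groupby(gene, sort=True)[m].mean()
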