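"""Paralog screening from heterozygote proportions and read-ratio deviation.

Loci assembled from two collapsed gene copies ("merged paralogs") show two
sequencing signatures: an excess of apparently heterozygous samples, and
pooled heterozygote read counts that deviate from the 1:1 ratio a true
single-copy heterozygote produces.  For each locus we pool reads across
its heterozygous samples (a = ref reads, b = alt reads) and compute

    ratio = a / (a + b)
    D     = (a - b) / sqrt(a + b)

D is the normal approximation to the z-score of a Binomial(a+b, 1/2)
count, so true single-copy loci scatter around D ~ N(0, 1) while merged
loci drift far out; the conventional keep rule is |D| <= 7.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def compute_hdplot(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus H, pooled read ratio and deviation D.

    Requires allele depths.  Columns: locus_id, H (het calls / called
    samples), n_het, total_reads, ratio, D; ratio and D are NaN for loci
    with no heterozygous reads (insufficient evidence, not a paralog
    signal).
    """
    if gm.ad is None:
        raise ValueError("allele depths (AD) required for HDplot")
    called = gm.dosage != MISSING
    het = gm.dosage == 1
    n_called = called.sum(axis=1)
    n_het = het.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        H = np.where(n_called > 0, n_het / n_called, np.nan)
    a = np.where(het, gm.ad[:, :, 0], 0).sum(axis=1).astype(float)
    b = np.where(het, gm.ad[:, :, 1], 0).sum(axis=1).astype(float)
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, a / total, np.nan)
        D = np.where(total > 0, (a - b) / np.sqrt(total), np.nan)
    return pd.DataFrame(
        {
            "locus_id": gm.snp_ids,
            "H": H,
            "n_het": n_het,
            "total_reads": total.astype(np.int64),
            "ratio": ratio,
            "D": D,
        }
    )


def filter_paralogs(
    stats: pd.DataFrame, d_max: float = 7.0, h_max: float | None = None
) -> list[str]:
    """Locus ids retained under |D| <= d_max (and H <= h_max if given).

    Loci with undefined D (no heterozygote reads) are retained: absence of
    evidence is not treated as a paralog signal, but they are logged.
    """
    if d_max < 0 or (h_max is not None and h_max < 0):
        raise ValueError("thresholds must be non-negative")
    D = stats["D"].to_numpy()
    undefined = ~np.isfinite(D)
    keep = undefined | (np.abs(D) <= d_max)
    if h_max is not None:
        keep &= ~(stats["H"].to_numpy() > h_max)
    if undefined.any():
        logger.info("%d loci with undefined D retained", int(undefined.sum()))
    return [lid for lid, k in zip(stats["locus_id"], keep) if k]
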