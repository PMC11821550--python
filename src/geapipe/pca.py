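"""Population-structure covariates via PCA of the genotype matrix.

Dosages are centered by twice the allele frequency and scaled by the
binomial standard deviation sqrt(2*p*(1-p)) (Patterson-style SNP scaling);
missing calls are mean-imputed before the singular value decomposition.
The leading score columns serve as structure covariates in the
genotype-environment regressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genio import MISSING, GenotypeMatrix


@dataclass
class PcaResult:
    """Scores (samples x components), per-component variance proportions
    (relative to the standardized matrix's total variance, non-increasing)
    and SNP loadings."""

    scores: np.ndarray
    variance_proportions: np.ndarray
    loadings: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]
    total_variance: float


def fit_pca(
    gm: GenotypeMatrix, n_components: int = 10, scaling: str = "patterson"
) -> PcaResult:
    """PCA of the standardized dosage matrix.

    ``scaling='patterson'`` divides each centered SNP column by
    sqrt(2*p*(1-p)); ``'unit'`` divides by the empirical standard
    deviation, making the total variance equal the number of retained
    SNPs.  SNPs fixed after filtering (p in {0, 1}) have zero scale and
    are dropped with a warning.  The component sign is fixed by forcing
    the largest-magnitude loading positive, so results are reproducible.
    """
    if gm.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if scaling not in ("patterson", "unit"):
        raise ValueError(f"unknown scaling {scaling!r}")
    D = gm.dosage.T.astype(float)  # samples x snps
    D[gm.dosage.T == MISSING] = np.nan
    p_hat = np.nanmean(D, axis=0) / 2.0
    keep = (p_hat > 0) & (p_hat < 1) & np.isfinite(p_hat)
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} zero-variance SNPs before PCA")
    D = D[:, keep]
    p_hat = p_hat[keep]
    Z = D - 2.0 * p_hat
    Z[np.isnan(Z)] = 0.0  # mean imputation: missing -> column mean
    n = Z.shape[0]
    if scaling == "patterson":
        scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    else:
        scale = np.sqrt((Z**2).sum(axis=0) / (n - 1))
    ok = scale > 0
    Z = Z[:, ok] / scale[ok]
    snp_ids = [s for s, k1 in zip(gm.snp_ids, keep) if k1]
    snp_ids = [s for s, k2 in zip(snp_ids, ok) if k2]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = S**2 / (n - 1)
    total = float(eigvals.sum())
    k = min(n_components, len(S))
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # deterministic sign: largest-|loading| entry of each component positive
    for c in range(k):
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    return PcaResult(
        scores=U * S,
        variance_proportions=eigvals[:k] / total,
        loadings=Vt.T,
        snp_ids=snp_ids,
        sample_ids=list(gm.sample_ids),
        total_variance=total,
    )


def select_covariates(pca: PcaResult, k: int = 1) -> np.ndarray:
    """First k score columns, standardized to zero mean / unit variance.

    ``k=0`` returns an empty (n, 0) matrix: the bivariate, structure-free
    association mode.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k > pca.scores.shape[1]:
        raise ValueError(f"only {pca.scores.shape[1]} components available")
    S = pca.scores[:, :k].copy()
    if k:
        S = (S - S.mean(axis=0)) / S.std(axis=0)
    return S


def suggest_k(variance_proportions: np.ndarray, max_k: int | None = None) -> int:
    """Knee heuristic: number of leading components before the largest
    successive eigenvalue-ratio drop.

    E.g. proportions (0.075, 0.019, 0.012) give ratios (3.9, 1.6) and
    suggest k=1: the first component stands clear of the noise floor.
    """
    v = np.asarray(variance_proportions, dtype=float)
    if len(v) < 2:
        return len(v)
    ratios = v[:-1] / v[1:]
    if max_k is not None:
        ratios = ratios[:max_k]
    return int(np.argmax(ratios)) + 1
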