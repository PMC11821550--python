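"""Logistic genotype-environment association with G and Wald scoring.

For every binary genotype indicator y and environmental variable e, two
nested logistic models are fitted on the identical sample subset:

    null:  logit P(y=1) = b0 + c'k          (structure covariates k)
    full:  logit P(y=1) = b0 + b1*z(e) + c'k

The G score is the likelihood-ratio statistic 2*(LL_full - LL_null),
chi-square with 1 df under the null; the Wald score is b1^2 / Var(b1),
also chi-square 1 df.  An association is called significant when its
Storey q-value on the G-score p-value is below ``q_thresh`` AND the Wald
p-value is below ``p_thresh`` -- both criteria are required.

The maximum-likelihood fit is Newton-Raphson / iteratively reweighted
least squares with the observed-information covariance; quasi-complete
separation (coefficients diverging on standardized predictors) and
non-convergence are detected and flagged, never reported as significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

STATUS_OK = "ok"
STATUS_CONSTANT = "skipped_constant"
STATUS_SEPARATION = "separation"
STATUS_NO_CONVERGE = "no_converge"


@dataclass
class LogisticFit:
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    status: str
    n_iter: int
    n: int


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
    beta_max: float = 15.0,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton-Raphson.

    ``X`` must already contain the intercept column.  Convergence when
    max |delta beta| < ``tol``; coefficients exceeding ``beta_max`` in
    absolute value (on standardized predictors) are treated as separation.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.min() == y.max():
        return LogisticFit(np.full(p, np.nan), np.full((p, p), np.nan),
                           np.nan, STATUS_CONSTANT, 0, n)
    beta = np.zeros(p)
    status = STATUS_NO_CONVERGE
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        w = mu * (1.0 - mu)
        info = (X * w[:, None]).T @ X
        score = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return LogisticFit(beta, np.full((p, p), np.nan), np.nan,
                               STATUS_SEPARATION, it, n)
        beta = beta + delta
        if np.max(np.abs(beta)) > beta_max:
            return LogisticFit(beta, np.full((p, p), np.nan), np.nan,
                               STATUS_SEPARATION, it, n)
        if np.max(np.abs(delta)) < tol:
            status = STATUS_OK
            break
    eta = X @ beta
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    loglik = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        status = STATUS_SEPARATION if status == STATUS_OK else status
    return LogisticFit(beta, cov, loglik, status, it, n)


def score_association(
    y: np.ndarray,
    env: np.ndarray,
    covariates: np.ndarray | None = None,
    null_fit: LogisticFit | None = None,
) -> dict:
    """Score one indicator against one environmental variable.

    Rows with a missing value in y, env or any covariate are dropped
    pairwise; the null (intercept + covariates) and full (adds the
    standardized variable) models are fitted on that same subset so the
    likelihood-ratio comparison is valid.  Returns a plain dict of the
    GeaRecord fields (without q-values, which are a run-level quantity).
    """
    y = np.asarray(y, dtype=float)
    env = np.asarray(env, dtype=float)
    C = None
    if covariates is not None and covariates.size:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != y.shape[0]:
            C = C.T
    mask = np.isfinite(y) & np.isfinite(env)
    if C is not None:
        mask &= np.all(np.isfinite(C), axis=1)
    yy, ee = y[mask], env[mask]
    n_used = int(mask.sum())
    rec = {
        "n_used": n_used, "beta0": np.nan, "beta1": np.nan, "beta1_raw": np.nan,
        "G": np.nan, "p_G": np.nan, "W": np.nan, "p_W": np.nan,
        "status": STATUS_OK,
    }
    if n_used == 0 or yy.min() == yy.max():
        rec["status"] = STATUS_CONSTANT
        return rec
    sd = ee.std()
    if sd == 0:
        rec["status"] = STATUS_CONSTANT
        return rec
    z = (ee - ee.mean()) / sd
    ones = np.ones((n_used, 1))
    Cm = C[mask] if C is not None else np.empty((n_used, 0))
    X_null = np.hstack([ones, Cm])
    X_full = np.hstack([ones, z[:, None], Cm])
    if null_fit is None:
        null_fit = fit_logistic(yy, X_null)
    full = fit_logistic(yy, X_full)
    for f in (null_fit, full):
        if f.status != STATUS_OK:
            rec["status"] = f.status
            return rec
    G = max(0.0, 2.0 * (full.loglik - null_fit.loglik))
    b1 = full.beta[1]
    var_b1 = full.cov[1, 1]
    W = b1 * b1 / var_b1 if var_b1 > 0 else np.nan
    rec.update(
        beta0=full.beta[0], beta1=b1, beta1_raw=b1 / sd,
        G=G, p_G=float(chi2.sf(G, 1)),
        W=W, p_W=float(chi2.sf(W, 1)) if np.isfinite(W) else np.nan,
    )
    if not np.isfinite(W):
        rec["status"] = STATUS_SEPARATION
    return rec


def qvalues(p: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values.

    pi0 is estimated by the median of pi0(lambda) = #{p > lambda} /
    (m * (1 - lambda)) over lambda in {0.05, 0.10, ..., 0.95}, capped at
    1; pass ``pi0=1`` to recover Benjamini-Hochberg adjusted p-values.
    q(p_(i)) = min_{j >= i} pi0 * m * p_(j) / j, monotone in p.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        lams = np.arange(0.05, 0.96, 0.05)
        ests = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lams])
        pi0 = float(min(1.0, np.median(ests)))
        pi0 = max(pi0, 1.0 / m)  # guard degenerate all-small-p input
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_gea(
    indicators,
    env_table: pd.DataFrame,
    covariates: np.ndarray | None = None,
    variables: list[str] | None = None,
    q_thresh: float = 0.05,
    p_thresh: float = 0.05,
    q_mode: str = "pooled",
) -> pd.DataFrame:
    """Score every indicator x variable pair; one GeaRecord row each.

    ``indicators`` is a :class:`~geapipe.genio.GenotypeIndicators` whose
    sample order matches ``env_table``'s rows.  q-values on the G-score
    p-values are computed across all ok-status records of the run
    (``q_mode='pooled'``) or within each variable (``'per_variable'``);
    ``significant = (q_G < q_thresh) & (p_W < p_thresh)``.
    """
    if variables is None:
        variables = list(env_table.columns)
    if not variables:
        raise ValueError("empty variable list")
    if q_mode not in ("pooled", "per_variable"):
        raise ValueError(f"unknown q_mode {q_mode!r}")
    env = env_table[variables]
    if list(env.index) and hasattr(indicators, "sample_ids") and indicators.sample_ids:
        if list(env.index) != list(indicators.sample_ids):
            env = env.reindex(indicators.sample_ids)
    env_arr = {v: env[v].to_numpy(dtype=float) for v in variables}
    C = None
    cov_ok = None
    if covariates is not None and np.asarray(covariates).size:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cov_ok = np.all(np.isfinite(C), axis=1)
    rows = []
    null_cache: dict[bytes, LogisticFit] = {}
    for i in range(indicators.n_indicators):
        y = indicators.values[i].astype(float)
        meta = indicators.meta.iloc[i]
        null_cache.clear()
        for v in variables:
            e = env_arr[v]
            mask = np.isfinite(y) & np.isfinite(e)
            if cov_ok is not None:
                mask &= cov_ok
            key = mask.tobytes()
            null_fit = null_cache.get(key)
            if null_fit is None and mask.any():
                yy = y[mask]
                if yy.min() != yy.max():
                    ones = np.ones((int(mask.sum()), 1))
                    Cm = C[mask] if C is not None else np.empty((int(mask.sum()), 0))
                    null_fit = fit_logistic(yy, np.hstack([ones, Cm]))
                    null_cache[key] = null_fit
            rec = score_association(y, e, C, null_fit=null_fit)
            rec["snp_id"] = meta["snp_id"]
            rec["genotype_class"] = meta["genotype_class"]
            rec["env_var"] = v
            rows.append(rec)
    df = pd.DataFrame(rows)
    df["q_G"] = np.nan
    ok = (df["status"] == STATUS_OK) & np.isfinite(df["p_G"])
    if q_mode == "pooled":
        if ok.any():
            df.loc[ok, "q_G"] = qvalues(df.loc[ok, "p_G"].to_numpy())
    else:
        for v in variables:
            sel = ok & (df["env_var"] == v)
            if sel.any():
                df.loc[sel, "q_G"] = qvalues(df.loc[sel, "p_G"].to_numpy())
    df["significant"] = ok & (df["q_G"] < q_thresh) & (df["p_W"] < p_thresh)
    cols = [
        "snp_id", "genotype_class", "env_var", "n_used", "beta0", "beta1",
        "beta1_raw", "G", "p_G", "q_G", "W", "p_W", "status", "significant",
    ]
    return df[cols]
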