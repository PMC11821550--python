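"""Logistic engine, G/Wald scoring, q-values: oracle and invariance checks."""

import numpy as np
import pytest
from scipy.special import expit

from geapipe.gea import (
    STATUS_CONSTANT,
    STATUS_OK,
    STATUS_SEPARATION,
    fit_logistic,
    qvalues,
    run_gea,
    score_association,
)


def grid_loglik(y, X):
    """Independent oracle: maximize the Bernoulli log-likelihood over the
    coefficient space by coarse-to-fine exhaustive grid refinement."""
    p = X.shape[1]

    def ll(beta):
        mu = np.clip(expit(X @ beta), 1e-12, 1 - 1e-12)
        return np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))

    center = np.zeros(p)
    width = 8.0
    for _ in range(14):
        axes = [np.linspace(c - width, c + width, 9) for c in center]
        grids = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([g.ravel() for g in grids], axis=1)
        vals = np.array([ll(b) for b in pts])
        center = pts[int(np.argmax(vals))]
        width /= 3.0
    return ll(center)


def random_dataset(rng, n, n_cov):
    x = rng.standard_normal(n)
    C = rng.standard_normal((n, n_cov)) if n_cov else np.empty((n, 0))
    eta = 0.3 + 0.8 * x + (C @ rng.uniform(-0.5, 0.5, n_cov) if n_cov else 0)
    y = (rng.random(n) < expit(eta)).astype(float)
    return y, x, C


class TestFitLogistic:
    def test_matches_grid_oracle_on_small_data(self, rng):
        checked = 0
        while checked < 12:
            n = int(rng.integers(20, 31))
            y, x, C = random_dataset(rng, n, int(rng.integers(0, 3)))
            X = np.hstack([np.ones((n, 1)), x[:, None], C])
            fit = fit_logistic(y, X)
            if fit.status != STATUS_OK:
                continue
            assert fit.loglik == pytest.approx(grid_loglik(y, X), abs=1e-6)
            checked += 1

    def test_null_limit_beta_small(self, rng):
        n = 4000
        y = (rng.random(n) < 0.4).astype(float)
        x = rng.standard_normal(n)
        fit = fit_logistic(y, np.column_stack([np.ones(n), x]))
        assert fit.status == STATUS_OK
        assert abs(fit.beta[1]) < 0.1

    def test_constant_response_flagged(self):
        y = np.ones(20)
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        assert fit_logistic(y, X).status == STATUS_CONSTANT

    def test_perfect_separation_flagged(self):
        x = np.linspace(-2, 2, 30)
        y = (x > 0).astype(float)
        fit = fit_logistic(y, np.column_stack([np.ones(30), x]))
        assert fit.status == STATUS_SEPARATION

    def test_agrees_with_statsmodels(self, rng):
        import statsmodels.api as sm

        y, x, C = random_dataset(rng, 200, 1)
        X = np.hstack([np.ones((200, 1)), x[:, None], C])
        fit = fit_logistic(y, X)
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(fit.beta, ref.params, atol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-8)


class TestScoreAssociation:
    def test_G_invariant_under_affine_env(self, rng):
        y, x, _ = random_dataset(rng, 150, 0)
        r1 = score_association(y, x)
        r2 = score_association(y, 3.0 - 2.5 * x)
        assert r1["G"] == pytest.approx(r2["G"], abs=1e-8)
        assert r1["p_G"] == pytest.approx(r2["p_G"], abs=1e-10)

    def test_null_model_saturating_covariate(self, rng):
        y, x, _ = random_dataset(rng, 100, 0)
        # covariate equal to (centered) y saturates the null model
        r = score_association(y, x, covariates=(y - y.mean())[:, None] * 50)
        assert r["status"] != STATUS_OK or r["G"] < 0.5

    def test_missing_rows_dropped_pairwise(self, rng):
        y, x, _ = random_dataset(rng, 120, 0)
        y2 = y.copy()
        y2[:20] = np.nan
        r = score_association(y2, x)
        assert r["n_used"] == 100
        r_ref = score_association(y[20:], x[20:])
        assert r["G"] == pytest.approx(r_ref["G"], abs=1e-10)

    def test_separation_never_significant(self):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(float)
        r = score_association(y, x)
        assert r["status"] == STATUS_SEPARATION
        assert np.isnan(r["G"]) or r["status"] != STATUS_OK


class TestQvalues:
    def test_bh_special_case(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(500)
        q = qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, bh, atol=1e-12)

    def test_ties_all_equal(self):
        p = np.full(100, 0.01)
        q = qvalues(p)
        assert len(set(np.round(q, 15))) == 1

    def test_uniform_pi0_near_one(self, rng):
        p = rng.random(1000)
        q = qvalues(p)
        bh = qvalues(p, pi0=1.0)
        # pi0-hat in [0.8, 1]: q within that factor of BH
        ratio = q / bh
        assert 0.8 <= ratio[0] <= 1.0 + 1e-12
        assert np.allclose(ratio, ratio[0])

    def test_monotone_in_p(self, rng):
        p = rng.random(300)
        q = qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            qvalues(np.array([]))


@pytest.fixture(scope="module")
def tiny_run():
    from geapipe.genio import encode_genotypes
    from geapipe.simdata import SimConfig, simulate_dataset

    cfg = SimConfig(n_samples=100, n_snps=10, prop_adaptive=0.0,
                    n_env=19, seed=2)
    gm, env, samples, truth = simulate_dataset(cfg, with_reads=False)
    return run_gea(encode_genotypes(gm), env)


class TestRunGea:
    def test_cartesian_record_count(self, tiny_run):
        # 10 SNPs x 3 classes x 19 variables
        assert len(tiny_run) == 570

    def test_dual_rule_requires_both(self, tiny_run):
        # a record with q_G below threshold but p_W above it (or the
        # reverse) must never be flagged significant
        rec = tiny_run
        assert not ((rec["significant"]) & (rec["p_W"] >= 0.05)).any()
        assert not ((rec["significant"]) & (rec["q_G"] >= 0.05)).any()

    def test_empty_variable_list_rejected(self):
        from geapipe.genio import encode_genotypes
        from geapipe.simdata import SimConfig, simulate_dataset

        cfg = SimConfig(n_samples=50, n_snps=2, seed=1)
        gm, env, samples, _ = simulate_dataset(cfg, with_reads=False)
        with pytest.raises(ValueError):
            run_gea(encode_genotypes(gm), env, variables=[])

    def test_threshold_saturation_marks_all_ok(self):
        from geapipe.genio import encode_genotypes
        from geapipe.simdata import SimConfig, simulate_dataset

        cfg = SimConfig(n_samples=60, n_snps=5, seed=6)
        gm, env, samples, _ = simulate_dataset(cfg, with_reads=False)
        rec = run_gea(encode_genotypes(gm), env, q_thresh=1.0 + 1e-9,
                      p_thresh=1.0 + 1e-9)
        ok = rec["status"] == STATUS_OK
        assert rec.loc[ok, "significant"].all()
        assert not rec.loc[~ok, "significant"].any()
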