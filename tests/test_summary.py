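"""Variable grouping and sign-based genotype classification."""

import numpy as np
import pandas as pd
import pytest

from geapipe.summary import (
    classify_by_sign,
    correlate_variables,
    count_significant_by_variable,
    per_individual_counts,
)


def record(snp, cls, var, beta1, q, sig=True, pw=0.01):
    return dict(
        snp_id=snp, genotype_class=cls, env_var=var, beta1=beta1,
        q_G=q, p_W=pw, status="ok", significant=sig,
    )


@pytest.fixture()
def freq_table():
    return pd.DataFrame(
        {
            "snp_id": ["s1", "s2", "s3", "s4"],
            "alt_freq": [0.3, 0.7, 0.5, 0.1],
            "maf": [0.3, 0.3, 0.5, 0.1],
            "missingness": [0.0] * 4,
        }
    )


class TestCorrelateVariables:
    def test_self_correlation_unity(self, rng):
        env = pd.DataFrame(rng.standard_normal((80, 3)), columns=list("abc"))
        g = correlate_variables(env)
        assert np.allclose(np.diag(g.correlation), 1.0)

    def test_affine_copies_grouped(self, rng):
        x = rng.standard_normal(100)
        env = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": rng.standard_normal(100)})
        g = correlate_variables(env)
        assert g.correlation.loc["a", "b"] == pytest.approx(1.0)
        grouped = [set(v) for v in g.groups.values()]
        assert {"a", "b"} in grouped
        assert {"c"} in grouped

    def test_winter_block_recovered(self):
        from geapipe.simdata import SimConfig, env_blocks, simulate_environment

        cfg = SimConfig(n_samples=400, n_env=12, n_env_blocks=3,
                        env_block_corr=0.8, seed=19)
        env, _ = simulate_environment(cfg)
        winter = set(env_blocks(cfg)[0])
        g = correlate_variables(env)
        assert any(winter == set(v) for v in g.groups.values())

    def test_groups_satisfy_pairwise_bound(self, rng):
        env = pd.DataFrame(rng.standard_normal((60, 6)),
                           columns=[f"v{i}" for i in range(6)])
        g = correlate_variables(env, r_min=0.6)
        for members in g.groups.values():
            if len(members) > 1:
                sub = g.correlation.loc[members, members].abs().to_numpy()
                assert sub[~np.eye(len(members), dtype=bool)].min() > 0.6

    def test_constant_variable_excluded(self, rng):
        env = pd.DataFrame(
            {"a": rng.standard_normal(50), "b": np.ones(50),
             "c": rng.standard_normal(50)}
        )
        g = correlate_variables(env)
        assert "b" not in g.correlation.columns

    def test_single_variable_rejected(self, rng):
        with pytest.raises(ValueError):
            correlate_variables(pd.DataFrame({"a": rng.standard_normal(10)}))


class TestCounting:
    def test_pairs_vs_distinct(self):
        recs = pd.DataFrame(
            [
                record("s1", "het", "Bio1", 1.0, 0.01),
                record("s1", "het", "Bio2", 1.0, 0.02),
                record("s1", "het", "Bio3", 1.0, 0.03),
            ]
        )
        out = count_significant_by_variable(recs)
        assert out.attrs["total_pairs"] == 3
        assert out.attrs["distinct_indicators"] == 1

    def test_empty_records(self):
        out = count_significant_by_variable(pd.DataFrame(columns=["significant"]))
        assert out.attrs["total_pairs"] == 0
        assert out.attrs["distinct_indicators"] == 0

    def test_distinct_equals_brute_force_on_simulated_run(self, small_dataset):
        from geapipe.gea import run_gea
        from geapipe.genio import encode_genotypes, filter_snps

        gm, env, samples, truth = small_dataset
        rec = run_gea(encode_genotypes(filter_snps(gm)), env)
        out = count_significant_by_variable(rec)
        sig = rec[rec["significant"]]
        brute = len({(r.snp_id, r.genotype_class) for r in sig.itertuples()})
        assert out.attrs["distinct_indicators"] == brute
        assert out.attrs["total_pairs"] == len(sig)


class TestClassifyBySign:
    def test_percentages_of_union(self, freq_table):
        recs = pd.DataFrame(
            [record(f"p{i}", "hom_ref", "Bio1", 1.0, 0.01) for i in range(1334)]
            + [record(f"n{i}", "het", "Bio1", -1.0, 0.01) for i in range(1288)]
        )
        ft = pd.DataFrame(
            {
                "snp_id": [f"p{i}" for i in range(1334)] + [f"n{i}" for i in range(1288)],
                "alt_freq": 0.3,
                "maf": 0.3,
            }
        )
        groups = classify_by_sign(recs, ["Bio1"], ft)
        assert groups["positive"].n_genotypes == 1334
        assert groups["negative"].n_genotypes == 1288
        assert groups["positive"].pct_of_total == pytest.approx(50.88, abs=0.01)
        assert groups["negative"].pct_of_total == pytest.approx(49.12, abs=0.01)

    def test_het_only_group_fully_heterozygous(self, freq_table):
        recs = pd.DataFrame(
            [record("s1", "het", "Bio1", -0.5, 0.01),
             record("s3", "het", "Bio2", -1.0, 0.02)]
        )
        groups = classify_by_sign(recs, ["Bio1", "Bio2"], freq_table)
        g = groups["negative"]
        assert g.pct_heterozygous == 100.0
        assert g.pct_homozygous == 0.0
        # median of the two minor-allele frequencies
        assert g.median_allele_frequency == pytest.approx(np.median([0.3, 0.5]))

    def test_percentages_sum_to_hundred(self, freq_table):
        recs = pd.DataFrame(
            [record("s1", "hom_ref", "Bio1", 1.0, 0.01),
             record("s2", "het", "Bio1", 0.5, 0.02),
             record("s4", "hom_alt", "Bio1", 0.2, 0.03)]
        )
        g = classify_by_sign(recs, ["Bio1"], freq_table)["positive"]
        assert g.pct_homozygous + g.pct_heterozygous == pytest.approx(100.0, abs=1e-9)

    def test_conflicting_signs_lowest_q_wins(self, freq_table):
        recs = pd.DataFrame(
            [record("s1", "het", "Bio1", 1.0, 0.04),
             record("s1", "het", "Bio2", -1.0, 0.001)]
        )
        groups = classify_by_sign(recs, ["Bio1", "Bio2"], freq_table)
        assert groups["negative"].n_genotypes == 1
        assert groups["positive"].n_genotypes == 0

    def test_homozygote_allele_frequency_per_class(self, freq_table):
        recs = pd.DataFrame(
            [record("s1", "hom_ref", "Bio1", 1.0, 0.01),  # ref freq 0.7
             record("s2", "hom_alt", "Bio1", 0.5, 0.02)]  # alt freq 0.7
        )
        g = classify_by_sign(recs, ["Bio1"], freq_table)["positive"]
        assert g.median_allele_frequency == pytest.approx(0.7)

    def test_deterministic(self, freq_table):
        recs = pd.DataFrame(
            [record("s1", "het", "Bio1", 1.0, 0.01),
             record("s2", "het", "Bio1", -1.0, 0.01)]
        )
        a = classify_by_sign(recs, ["Bio1"], freq_table)
        b = classify_by_sign(recs, ["Bio1"], freq_table)
        assert a["positive"].n_genotypes == b["positive"].n_genotypes
        assert a["positive"].members.equals(b["positive"].members)


class TestPerIndividualCounts:
    def test_matches_brute_force(self, small_dataset):
        from geapipe.gea import run_gea
        from geapipe.genio import encode_genotypes, filter_snps, summarize_frequencies

        gm, env, samples, truth = small_dataset
        gmf = filter_snps(gm)
        ind = encode_genotypes(gmf)
        rec = run_gea(ind, env)
        vset = list(env.columns[:5])
        ft = summarize_frequencies(gmf)["snp"]
        for sign in ("positive", "negative"):
            counts = per_individual_counts(rec, ind, vset, sign)
            groups = classify_by_sign(rec, vset, ft)
            members = groups[sign].members
            keys = (
                set(zip(members["snp_id"], members["genotype_class"]))
                if members is not None and len(members)
                else set()
            )
            brute = np.zeros(gmf.n_samples)
            for i in range(ind.n_indicators):
                mk = (ind.meta["snp_id"][i], ind.meta["genotype_class"][i])
                if mk in keys:
                    v = ind.values[i].copy()
                    v[np.isnan(v)] = 0  # missing contributes 0
                    brute += v
            assert np.array_equal(counts.to_numpy(), brute.astype(int))

    def test_no_group_members_zero(self, freq_table, small_dataset):
        from geapipe.genio import encode_genotypes

        gm = small_dataset[0]
        ind = encode_genotypes(gm)
        recs = pd.DataFrame(
            [record("s1", "het", "Bio1", 1.0, 0.01, sig=False)]
        )
        counts = per_individual_counts(recs, ind, ["Bio1"], "positive")
        assert (counts == 0).all()
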