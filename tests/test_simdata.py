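"""Generator contracts: correlation structure, planted effects, determinism."""

import hashlib

import numpy as np
import pandas as pd
import pytest

from geapipe.genio import MISSING, read_vcf
from geapipe.simdata import (
    SimConfig,
    env_blocks,
    simulate_dataset,
    simulate_environment,
    simulate_genotypes,
    simulate_reads,
    write_fixture,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(env_block_corr=1.5),
            dict(missing_rate=-0.1),
            dict(fst=0.0),
            dict(fst=1.0),
            dict(n_samples=5),
            dict(beta1_range=(0.0, np.inf)),
            dict(n_env=1, n_env_blocks=2),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)

    def test_nonpositive_depth_rejected(self, small_dataset):
        gm = small_dataset[0]
        with pytest.raises(ValueError):
            simulate_reads(SimConfig(mean_depth=0.0), gm)


class TestEnvironment:
    def test_perfect_block_correlation_gives_affine_copies(self):
        cfg = SimConfig(n_samples=60, n_env=6, n_env_blocks=2, env_block_corr=1.0)
        env, _ = simulate_environment(cfg)
        for block in env_blocks(cfg):
            base = env[block[0]]
            for other in block[1:]:
                r = np.corrcoef(base, env[other])[0, 1]
                assert r == pytest.approx(1.0, abs=1e-12)

    def test_within_block_correlation_exceeds_cut(self):
        cfg = SimConfig(n_samples=500, n_env=8, n_env_blocks=2,
                        env_block_corr=0.8, seed=5)
        env, _ = simulate_environment(cfg)
        for block in env_blocks(cfg):
            sub = env[block].corr().to_numpy()
            off = sub[~np.eye(len(block), dtype=bool)]
            assert np.all(np.abs(off) > 0.6)

    def test_winter_block_decreases_with_longitude(self):
        cfg = SimConfig(n_samples=400, seed=2)
        env, samples = simulate_environment(cfg)
        winter = env_blocks(cfg)[0]
        r = np.corrcoef(samples["lon"], env[winter[0]])[0, 1]
        assert r < -0.3

    def test_coordinates_inside_rectangle(self, small_dataset, small_config):
        _, _, samples, _ = small_dataset
        assert samples["lon"].between(*small_config.lon_range).all()
        assert samples["lat"].between(*small_config.lat_range).all()


class TestGenotypes:
    def test_missingness_matches_rate(self):
        cfg = SimConfig(n_samples=300, n_snps=300, missing_rate=0.25, seed=4)
        env, samples = simulate_environment(cfg)
        gm, _ = simulate_genotypes(cfg, env, samples)
        rate = (gm.dosage == MISSING).mean()
        assert rate == pytest.approx(0.25, abs=0.01)

    def test_adaptive_count_exact(self):
        cfg = SimConfig(n_samples=50, n_snps=137, prop_adaptive=0.1, seed=0)
        env, samples = simulate_environment(cfg)
        _, truth = simulate_genotypes(cfg, env, samples)
        assert truth.snps["is_adaptive"].sum() == round(0.1 * 137)

    def test_admixture_monotone_in_longitude(self, small_dataset):
        _, _, samples, truth = small_dataset
        order = np.argsort(samples["lon"].to_numpy())
        q = truth.samples["q"].to_numpy()[order]
        assert np.all(np.diff(q) >= 0)
        assert np.all((q >= 0) & (q <= 1))

    def test_panmixia_limit_pop_frequencies_close(self):
        cfg = SimConfig(n_samples=60, n_snps=400, fst=1e-4, seed=9)
        env, samples = simulate_environment(cfg)
        _, truth = simulate_genotypes(cfg, env, samples)
        neutral = truth.snps[~truth.snps.is_adaptive]
        assert np.allclose(neutral["p_pop1"], neutral["p_anc"], atol=0.05)
        assert np.allclose(neutral["p_pop1"], neutral["p_pop2"], atol=0.05)


class TestReads:
    def test_heterozygote_pooled_ratio_near_half(self):
        cfg = SimConfig(n_samples=400, n_snps=60, prop_paralog=0.0,
                        missing_rate=0.0, seed=6)
        gm, env, samples, truth = simulate_dataset(cfg)
        het = gm.dosage == 1
        a = np.where(het, gm.ad[:, :, 0], 0).sum()
        b = np.where(het, gm.ad[:, :, 1], 0).sum()
        assert a / (a + b) == pytest.approx(0.5, abs=0.01)

    def test_zero_depth_call_is_missing(self):
        cfg = SimConfig(n_samples=200, n_snps=50, mean_depth=1.0,
                        missing_rate=0.0, prop_paralog=0.0, seed=8)
        env, samples = simulate_environment(cfg)
        gm, truth = simulate_genotypes(cfg, env, samples)
        gm2 = simulate_reads(cfg, gm, truth)
        zero = gm2.ad.sum(axis=2) == 0
        assert zero.any()  # Poisson(1) produces zero-depth calls
        assert np.all(gm2.dosage[zero] == MISSING)

    def test_homozygotes_single_allele_reads(self):
        cfg = SimConfig(n_samples=100, n_snps=40, prop_paralog=0.0, seed=3)
        gm, env, samples, truth = simulate_dataset(cfg)
        hom_ref = gm.dosage == 0
        hom_alt = gm.dosage == 2
        assert np.all(gm.ad[:, :, 1][hom_ref] == 0)
        assert np.all(gm.ad[:, :, 0][hom_alt] == 0)

    def test_paralog_loci_show_excess_heterozygosity(self):
        cfg = SimConfig(n_samples=240, n_snps=400, prop_paralog=0.10, seed=12)
        gm, env, samples, truth = simulate_dataset(cfg)
        het_prop = (gm.dosage == 1).mean(axis=1)
        is_par = truth.snps["is_paralog"].to_numpy()
        assert het_prop[is_par].mean() > het_prop[~is_par].mean() + 0.1


class TestFixtureRoundTrip:
    def test_same_seed_byte_identical(self, tmp_path):
        def checksums(d):
            cfg = SimConfig(n_samples=30, n_snps=40, seed=21)
            out = write_fixture(*simulate_dataset(cfg), str(d))
            return {
                k: hashlib.sha256(open(p, "rb").read()).hexdigest()
                for k, p in out.items()
            }

        assert checksums(tmp_path / "a") == checksums(tmp_path / "b")

    def test_vcf_roundtrip_preserves_matrix(self, tmp_path, small_dataset):
        gm, env, samples, truth = small_dataset
        paths = write_fixture(gm, env, samples, truth, str(tmp_path))
        gm2 = read_vcf(paths["vcf"])
        assert gm2.sample_ids == gm.sample_ids
        assert np.array_equal(gm2.dosage, gm.dosage)
        assert np.array_equal(gm2.ad, gm.ad)
        assert np.array_equal(gm2.pos, gm.pos)

    def test_zero_snps_writes_header_only_vcf(self, tmp_path):
        cfg = SimConfig(n_samples=12, n_snps=0, prop_paralog=0.0, seed=1)
        gm, env, samples, truth = simulate_dataset(cfg, with_reads=False)
        paths = write_fixture(gm, env, samples, truth, str(tmp_path))
        gm2 = read_vcf(paths["vcf"])
        assert gm2.n_snps == 0
        assert gm2.n_samples == 12
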