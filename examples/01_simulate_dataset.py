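"""Generate a synthetic landscape-genomics dataset and inspect the truth.

Builds 240 virtual trees along a west-east hybrid zone, 19 block-correlated
bioclimatic variables, 2000 GBS-like SNP loci (5% with a planted
genotype-environment effect, 5% merged paralogs) and writes the VCF + CSV
fixture files.
"""

from geapipe import SimConfig, simulate_dataset, write_fixture

cfg = SimConfig(seed=7)
gm, env, samples, truth = simulate_dataset(cfg)
paths = write_fixture(gm, env, samples, truth, "scratch/example_fixture")

print(f"samples: {gm.n_samples}, SNPs: {gm.n_snps}")
print(f"environment variables: {list(env.columns)}")
print(f"planted adaptive SNPs: {int(truth.snps['is_adaptive'].sum())}")
print(f"merged-paralog loci:   {int(truth.snps['is_paralog'].sum())}")
print(f"missing call fraction: {(gm.dosage == -1).mean():.3f}")
print("files:", ", ".join(paths.values()))
# The truth table records, per locus, the linked variable and effect size
# beta1 on the standardized-environment scale, and per sample the true
# admixture proportion q -- the quantities recovery is scored against.
print(truth.snps[truth.snps.is_adaptive].head()[["snp_id", "env_var", "beta1"]])
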