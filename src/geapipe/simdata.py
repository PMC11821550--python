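"""Synthetic landscape, population and genotype generator.

Emulates the statistical structure a reduced-representation (GBS)
landscape-genomics dataset carries: two diverged populations meeting in a
longitudinal hybrid zone, block-correlated bioclimatic gradients, a small
set of loci whose genotype-class probabilities follow a logistic model in
one environmental variable, missing calls, and per-call read depths in
which a fraction of loci are merged paralogs.  Every planted feature is
recorded in a truth table so recovery can be scored downstream.

Population divergence uses the Balding-Nichols model: population allele
frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F) around an ancestral frequency
p, with F the divergence parameter.  Per-sample admixture follows a
logistic cline in longitude, q = expit((lon - center)/width).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .genio import MISSING, GenotypeMatrix, write_vcf

__all__ = [
    "SimConfig",
    "TruthTable",
    "simulate_environment",
    "simulate_genotypes",
    "simulate_reads",
    "simulate_dataset",
    "write_fixture",
    "write_synthetic_ontology",
    "write_synthetic_annotation",
]


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study design.

    Defaults describe the benchmark conditions: 240 trees sampled across a
    west-east gradient, 19 bioclimatic variables in four correlated blocks,
    moderate divergence between the two parental populations, and GBS-like
    depths around 40 reads per call.
    """

    n_samples: int = 240
    n_snps: int = 2000
    prop_adaptive: float = 0.05
    beta1_range: tuple[float, float] = (0.5, 1.5)
    fst: float = 0.15
    hybrid_zone_center: float = 130.0
    hybrid_zone_width: float = 8.0
    n_env: int = 19
    n_env_blocks: int = 4
    env_block_corr: float = 0.8
    env_gradient_strength: float = 0.4
    missing_rate: float = 0.10
    mean_depth: float = 40.0
    prop_paralog: float = 0.05
    seed: int = 0
    lon_range: tuple[float, float] = (95.0, 165.0)
    lat_range: tuple[float, float] = (58.0, 72.0)

    def __post_init__(self) -> None:
        for name in ("prop_adaptive", "env_block_corr", "missing_rate", "prop_paralog"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if not np.all(np.isfinite(self.beta1_range)):
            raise ValueError("beta1_range must be finite")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        if self.n_env < 1 or self.n_env_blocks < 1:
            raise ValueError("n_env and n_env_blocks must be positive")
        if self.n_env < self.n_env_blocks:
            raise ValueError(
                f"cannot split {self.n_env} variables into {self.n_env_blocks} blocks"
            )

def _stage_rng(config: SimConfig, stage_index: int) -> np.random.Generator:
    # sub-streams derived deterministically from the single global seed
    return np.random.default_rng([config.seed, stage_index])


@dataclass
class TruthTable:
    """Simulator's record of what was planted.

    ``snps`` has one row per locus (is_adaptive, env_var, beta1, ancestral
    and population frequencies, is_paralog); ``samples`` carries the true
    admixture proportion q per individual.
    """

    snps: pd.DataFrame
    samples: pd.DataFrame


def _env_names(n_env: int) -> list[str]:
    return [f"Bio{i + 1}" for i in range(n_env)]


def env_blocks(config: SimConfig) -> list[list[str]]:
    """Contiguous assignment of variables to blocks; block 0 is 'winter'."""
    names = _env_names(config.n_env)
    splits = np.array_split(np.arange(config.n_env), config.n_env_blocks)
    return [[names[i] for i in idx] for idx in splits]


def simulate_environment(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample coordinates and block-correlated environmental variables.

    Returns ``(env_table, sample_table)``.  Each block shares a latent
    factor; a variable is sqrt(rho) * factor + sqrt(1-rho) * noise so that
    within-block pairwise correlation is rho in expectation (affine copies
    at rho = 1).  Block 0 is the winter-like block: its factor decreases
    with longitude, mimicking increasingly cold/dry conditions eastward.
    """
    rng = _stage_rng(config, 0)
    n = config.n_samples
    lon = rng.uniform(*config.lon_range, size=n)
    lat = rng.uniform(*config.lat_range, size=n)
    z_lon = (lon - lon.mean()) / lon.std()
    z_lat = (lat - lat.mean()) / lat.std()

    blocks = env_blocks(config)
    # Geographic gradients carry only part of each factor's variance:
    # climate tracks the west-east cline without being collinear with it,
    # so a structure covariate does not absorb the whole signal.
    w = config.env_gradient_strength
    factors = []
    for b in range(len(blocks)):
        if b == 0:  # winter severity grows eastward
            factors.append(-(np.sqrt(w) * z_lon + np.sqrt(1 - w) * rng.standard_normal(n)))
        elif b == 1:
            factors.append(-(np.sqrt(w) * z_lat + np.sqrt(1 - w) * rng.standard_normal(n)))
        else:
            factors.append(rng.standard_normal(n))
    rho = config.env_block_corr
    data = {}
    for b, names in enumerate(blocks):
        for j, name in enumerate(names):
            noise = rng.standard_normal(n) if rho < 1.0 else 0.0
            latent = np.sqrt(rho) * factors[b] + np.sqrt(1.0 - rho) * noise
            # arbitrary per-variable location/scale, as raw bioclim units would have
            data[name] = 10.0 * (b + 1) + (1.0 + 0.2 * j) * latent
    env = pd.DataFrame(data, index=[f"S{i:04d}" for i in range(n)])
    env.index.name = "sample_id"
    q = expit((lon - config.hybrid_zone_center) / config.hybrid_zone_width)
    species = np.where(q > 0.8, "east", np.where(q < 0.2, "west", "hybrid"))
    samples = pd.DataFrame(
        {
            "sample_id": env.index,
            "lon": lon,
            "lat": lat,
            "species": species,
        }
    ).reset_index(drop=True)
    return env, samples


def simulate_genotypes(
    config: SimConfig, env: pd.DataFrame, samples: pd.DataFrame
) -> tuple[GenotypeMatrix, TruthTable]:
    """Draw genotypes for neutral and planted-adaptive loci.

    Neutral loci: Balding-Nichols population frequencies p1, p2 around an
    ancestral p ~ U(0.05, 0.95); a sample with admixture q draws its
    genotype Binomial(2, q*p1 + (1-q)*p2).  Adaptive loci: the probability
    of carrying the alt allele (het or hom_alt) follows
    expit(beta0 + beta1 * z_env) with z_env the standardized linked
    variable and beta0 matching the locus' baseline carrier frequency;
    carriers split het vs hom_alt by the Hardy-Weinberg conditional odds.
    Adaptive ancestral frequencies are drawn U(0.15, 0.5): planted
    effects load on minor alleles at MAF-viable frequencies, keeping the
    carrier class informative.  Missing calls are MCAR at
    ``missing_rate``.
    """
    rng = _stage_rng(config, 1)
    n, m = config.n_samples, config.n_snps
    lon = samples["lon"].to_numpy()
    q = expit((lon - config.hybrid_zone_center) / config.hybrid_zone_width)

    n_adaptive = int(round(config.prop_adaptive * m))
    adaptive_idx = rng.choice(m, size=n_adaptive, replace=False) if m else np.array([], int)
    is_adaptive = np.zeros(m, dtype=bool)
    is_adaptive[adaptive_idx] = True

    # adaptive effects load on minor alleles at MAF-viable frequencies,
    # so the carrier class is informative rather than saturated
    p_anc = rng.uniform(0.05, 0.95, size=m)
    p_anc[is_adaptive] = rng.uniform(0.15, 0.5, size=n_adaptive)
    F = config.fst
    a, b = p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F
    p1 = rng.beta(a, b)
    p2 = rng.beta(a, b)

    env_names = list(env.columns)
    winter = env_blocks(config)[0]
    linked = np.array([""] * m, dtype=object)
    beta1 = np.zeros(m)
    lo, hi = config.beta1_range
    dosage = np.empty((m, n), dtype=np.int8)

    env_z = (env - env.mean()) / env.std(ddof=0)
    for j in range(m):
        if is_adaptive[j]:
            var = winter[rng.integers(len(winter))] if winter else env_names[0]
            linked[j] = var
            mag = rng.uniform(lo, hi)
            beta1[j] = mag if rng.random() < 0.5 else -mag
            z = env_z[var].to_numpy()
            p = p_anc[j]
            carrier0 = 1.0 - (1.0 - p) ** 2
            eta = logit(carrier0) + beta1[j] * z
            carrier = rng.random(n) < expit(eta)
            het_given_carrier = 2 * p * (1 - p) / (2 * p * (1 - p) + p * p)
            het = rng.random(n) < het_given_carrier
            dosage[j] = np.where(carrier, np.where(het, 1, 2), 0)
        else:
            p_mix = np.clip(q * p1[j] + (1 - q) * p2[j], 1e-9, 1 - 1e-9)
            dosage[j] = rng.binomial(2, p_mix)

    miss = rng.random((m, n)) < config.missing_rate
    dosage[miss] = MISSING

    snp_ids = [f"snp{j:05d}" for j in range(m)]
    gm = GenotypeMatrix(
        sample_ids=list(env.index),
        snp_ids=snp_ids,
        chrom=np.array([f"chr{(j % 12) + 1}" for j in range(m)], dtype=object),
        pos=np.array([10_000 + 500 * j for j in range(m)], dtype=np.int64),
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array(["T"] * m, dtype=object),
        dosage=dosage,
    )
    truth = TruthTable(
        snps=pd.DataFrame(
            {
                "snp_id": snp_ids,
                "is_adaptive": is_adaptive,
                "env_var": linked,
                "beta1": beta1,
                "p_anc": p_anc,
                "p_pop1": p1,
                "p_pop2": p2,
                "is_paralog": np.zeros(m, dtype=bool),
            }
        ),
        samples=pd.DataFrame({"sample_id": list(env.index), "q": q}),
    )
    return gm, truth


def _reads_for(
    rng: np.random.Generator, dosage: np.ndarray, mean_depth: float
) -> np.ndarray:
    """(n, 2) ref/alt read counts for one locus' dosage vector."""
    n = dosage.shape[0]
    depth = rng.poisson(mean_depth, size=n)
    ad = np.zeros((n, 2), dtype=np.int32)
    hom_ref = dosage == 0
    hom_alt = dosage == 2
    het = dosage == 1
    ad[hom_ref, 0] = depth[hom_ref]
    ad[hom_alt, 1] = depth[hom_alt]
    alt_reads = rng.binomial(depth[het], 0.5)
    ad[het, 1] = alt_reads
    ad[het, 0] = depth[het] - alt_reads
    missing = dosage == MISSING
    ad[missing] = 0
    return ad


def simulate_reads(
    config: SimConfig, gm: GenotypeMatrix, truth: TruthTable | None = None
) -> GenotypeMatrix:
    """Attach GBS-like allele read depths; inject merged-paralog loci.

    Depth is Poisson(``mean_depth``) per call; heterozygotes draw alt reads
    Binomial(depth, 0.5); homozygotes put all reads on one allele.  A
    fraction ``prop_paralog`` of loci are replaced by the merge of the
    locus with an independent hidden duplicate: reads of both are summed
    and the genotype re-called from the pooled signal (any mixed evidence
    calls a heterozygote), which produces the excess apparent
    heterozygosity and skewed pooled read ratios paralogs show.  Calls
    with zero total depth become missing.  Returns a new matrix; marks
    ``is_paralog`` in ``truth`` when given.
    """
    if config.mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = _stage_rng(config, 2)
    m, n = gm.n_snps, gm.n_samples
    n_paralog = int(round(config.prop_paralog * m))
    paralog_idx = set(
        rng.choice(m, size=n_paralog, replace=False).tolist() if m else []
    )

    dosage = gm.dosage.copy()
    ad = np.zeros((m, n, 2), dtype=np.int32)
    for j in range(m):
        ad_j = _reads_for(rng, gm.dosage[j], config.mean_depth)
        if j in paralog_idx:
            p_hidden = rng.uniform(0.1, 0.9)
            hidden = rng.binomial(2, p_hidden, size=n).astype(np.int8)
            hidden[gm.dosage[j] == MISSING] = MISSING
            ad_j = ad_j + _reads_for(rng, hidden, config.mean_depth)
            # re-call from the merged signal
            total = ad_j.sum(axis=1)
            called = np.where(
                (ad_j[:, 0] > 0) & (ad_j[:, 1] > 0),
                1,
                np.where(ad_j[:, 1] > 0, 2, 0),
            ).astype(np.int8)
            called[total == 0] = MISSING
            dosage[j] = called
        else:
            dosage[j, ad_j.sum(axis=1) == 0] = MISSING
        ad[j] = ad_j

    if truth is not None:
        flags = np.zeros(m, dtype=bool)
        flags[list(paralog_idx)] = True
        truth.snps["is_paralog"] = flags

    return GenotypeMatrix(
        sample_ids=list(gm.sample_ids),
        snp_ids=list(gm.snp_ids),
        chrom=gm.chrom.copy(),
        pos=gm.pos.copy(),
        ref=gm.ref.copy(),
        alt=gm.alt.copy(),
        dosage=dosage,
        ad=ad,
    )


def simulate_dataset(
    config: SimConfig, with_reads: bool = True
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, TruthTable]:
    """Convenience wrapper running all stages with one seed."""
    env, samples = simulate_environment(config)
    gm, truth = simulate_genotypes(config, env, samples)
    if with_reads:
        gm = simulate_reads(config, gm, truth)
    return gm, env, samples, truth


def write_fixture(
    gm: GenotypeMatrix,
    env: pd.DataFrame,
    samples: pd.DataFrame,
    truth: TruthTable,
    out_dir: str,
) -> dict[str, str]:
    """Write VCF + CSV tables; byte-identical for identical inputs."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "env": os.path.join(out_dir, "env.csv"),
        "samples": os.path.join(out_dir, "samples.csv"),
        "truth_snps": os.path.join(out_dir, "truth_snps.csv"),
        "truth_samples": os.path.join(out_dir, "truth_samples.csv"),
    }
    write_vcf(gm, paths["vcf"])
    env.to_csv(paths["env"], lineterminator="\n", float_format="%.10g")
    samples.to_csv(paths["samples"], index=False, lineterminator="\n", float_format="%.10g")
    truth.snps.to_csv(paths["truth_snps"], index=False, lineterminator="\n", float_format="%.10g")
    truth.samples.to_csv(paths["truth_samples"], index=False, lineterminator="\n", float_format="%.10g")
    return paths


# ---------------------------------------------------------------------------
# synthetic annotation resources (gene models + ontology) for the
# annotation/enrichment stages

SYNTHETIC_BP_TERMS = [
    ("GO:0008150", "biological_process", None),
    ("GO:0008152", "metabolic process", "GO:0008150"),
    ("GO:0009987", "cellular process", "GO:0008150"),
    ("GO:0006810", "transport", "GO:0008150"),
    ("GO:0055085", "transmembrane transport", "GO:0006810"),
    ("GO:0044237", "cellular metabolic process", "GO:0008152"),
    ("GO:0019538", "protein metabolic process", "GO:0008152"),
    ("GO:0006629", "lipid metabolic process", "GO:0008152"),
    ("GO:0016043", "cellular component organization", "GO:0009987"),
    ("GO:0007049", "cell cycle", "GO:0009987"),
    ("GO:0042592", "homeostatic process", "GO:0008150"),
    ("GO:0050801", "ion homeostasis", "GO:0042592"),
    ("GO:0032502", "developmental process", "GO:0008150"),
    ("GO:0009653", "anatomical structure morphogenesis", "GO:0032502"),
    ("GO:0006811", "ion transport", "GO:0006810"),
    ("GO:0098660", "inorganic ion transmembrane transport", "GO:0055085"),
    ("GO:0098655", "cation transmembrane transport", "GO:0098660"),
    ("GO:0071805", "potassium ion transmembrane transport", "GO:0098655"),
    ("GO:0006814", "sodium ion transport", "GO:0006811"),
    ("GO:0055065", "metal ion homeostasis", "GO:0050801"),
]

# specific sibling/descendant terms the planted candidate genes share
SYNTHETIC_SIGNAL_TERMS = [
    "GO:0098660", "GO:0098655", "GO:0071805", "GO:0006814", "GO:0055065",
]


def write_synthetic_ontology(path: str) -> None:
    """Write the small synthetic biological_process ontology (OBO 1.2)."""
    chunks = ["format-version: 1.2", "ontology: synthetic-go", ""]
    for tid, name, parent in SYNTHETIC_BP_TERMS:
        chunks.append("[Term]")
        chunks.append(f"id: {tid}")
        chunks.append(f"name: {name}")
        chunks.append("namespace: biological_process")
        if parent:
            chunks.append(f"is_a: {parent}")
        chunks.append("")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(chunks))


def write_synthetic_annotation(
    gm: GenotypeMatrix,
    truth: TruthTable,
    gff_path: str,
    ann_path: str,
    seed: int = 0,
) -> None:
    """Tile the simulated chromosomes with 2 kb exonic gene models and a
    gene-to-term annotation table.

    Genes harboring a planted adaptive SNP are annotated to a coherent
    set of specific transport/homeostasis terms, emulating candidate
    adaptive genes sharing biological processes; background genes draw
    from the generic terms, so the signal leaves stay rare in the corpus
    and the enrichment stage has a real overrepresentation to detect.
    """
    rng = np.random.default_rng([seed, 104])
    generic = [
        t
        for t, _, parent in SYNTHETIC_BP_TERMS
        if parent is not None and t not in SYNTHETIC_SIGNAL_TERMS
    ]
    adaptive_pos = {
        (str(c), int(p))
        for c, p, a in zip(gm.chrom, gm.pos, truth.snps["is_adaptive"])
        if a
    }
    lines = ["##gff-version 3"]
    ann = []
    g = 0
    for chrom in sorted(set(map(str, gm.chrom))):
        pos = sorted(int(p) for c, p in zip(gm.chrom, gm.pos) if str(c) == chrom)
        start, hi = pos[0] - 100, pos[-1] + 100
        while start < hi:
            end = min(start + 1999, hi)
            name = f"gene{g:04d}"
            lines.append(
                f"{chrom}\tsim\tgene\t{start}\t{end}\t.\t+\t.\tID={name};Name={name}"
            )
            lines.append(
                f"{chrom}\tsim\texon\t{start}\t{end}\t.\t+\t.\tID={name}.e;Parent={name}"
            )
            has_adaptive = any(
                (chrom, p) in adaptive_pos for p in pos if start <= p <= end
            )
            if has_adaptive:
                chosen = list(rng.choice(SYNTHETIC_SIGNAL_TERMS, size=2, replace=False))
            else:
                chosen = list(rng.choice(generic, size=rng.integers(1, 4), replace=False))
            ann.extend((name, t) for t in chosen)
            g += 1
            start = end + 1
    with open(gff_path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
    pd.DataFrame(ann, columns=["gene", "term"]).to_csv(
        ann_path, sep="\t", index=False, lineterminator="\n"
    )
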