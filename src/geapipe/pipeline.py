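"""End-to-end orchestration of the association pipeline.

Stage order: read -> HDplot paralog screen (when depths are present) ->
MD/MAF pruning -> genotype encoding -> structure PCA -> logistic GEA ->
sign-group summaries -> Moran's I diagnostics (optional) -> gene
annotation -> GO enrichment -> semantic reduction.  Every stage writes
its table under the output directory and contributes its before/after
counts to a JSON run manifest, so a run is auditable stage by stage.  All
randomness (permutations) flows from the single config seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotate as annotate_mod
from . import enrich as enrich_mod
from . import semsim as semsim_mod
from .gea import run_gea
from .genio import (
    encode_genotypes,
    filter_snps,
    read_env_table,
    read_sample_table,
    read_vcf,
    summarize_frequencies,
)
from .hdplot import compute_hdplot, filter_paralogs
from .pca import fit_pca, select_covariates
from .spatial import build_weights, global_moran
from .summary import (
    WINTER_CORE_VARIABLES,
    classify_by_sign,
    count_significant_by_variable,
    per_individual_counts,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and knobs of one pipeline run."""

    vcf: str
    env: str
    samples: str
    outdir: str
    gff3: str | None = None
    obo: str | None = None
    annotations: str | None = None  # gene -> GO term TSV/CSV
    md_max: float = 0.20
    maf_min: float = 0.05
    use_hdplot: bool = True
    d_max: float = 7.0
    q_thresh: float = 0.05
    p_thresh: float = 0.05
    simrel_C: float = 0.7
    variables: list[str] | None = None
    variable_set: list[str] = field(default_factory=lambda: list(WINTER_CORE_VARIABLES))
    k_neighbors: int = 20
    n_perm: int = 999
    run_moran: bool = False
    moran_max_vectors: int = 20
    pca_components: int = 1
    namespace: str = "biological_process"
    snp_mode: str = "multi"
    seed: int = 0

    def validate(self) -> None:
        for name in ("md_max", "maf_min", "q_thresh", "p_thresh", "simrel_C"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("vcf", "env", "samples"):
            p = getattr(self, name)
            if not os.path.exists(p):
                raise FileNotFoundError(f"{name} file not found: {p}")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dict (also written as JSON)."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def out(name: str) -> str:
        return os.path.join(config.outdir, name)

    def stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        s = stage("read")
        gm = read_vcf(config.vcf)
        env = read_env_table(config.env)
        samples = read_sample_table(config.samples)
        env = env.loc[gm.sample_ids]
        samples = samples.set_index("sample_id").loc[gm.sample_ids].reset_index()
        manifest["stages"][s] = {"n_snps": gm.n_snps, "n_samples": gm.n_samples,
                                 "n_env": env.shape[1]}
    except Exception as e:  # noqa: BLE001
        raise StageError("read", e) from e

    if config.use_hdplot and gm.ad is not None:
        try:
            s = stage("hdplot")
            stats = compute_hdplot(gm)
            keep = set(filter_paralogs(stats, d_max=config.d_max))
            idx = [i for i, sid in enumerate(gm.snp_ids) if sid in keep]
            stats.to_csv(out("hdplot.csv"), index=False)
            manifest["stages"][s] = {"n_before": gm.n_snps, "n_after": len(idx)}
            gm = gm.take_snps(np.array(idx, dtype=int))
        except Exception as e:  # noqa: BLE001
            raise StageError("hdplot", e) from e

    try:
        s = stage("filter")
        n_before = gm.n_snps
        gm = filter_snps(gm, md_max=config.md_max, maf_min=config.maf_min)
        manifest["stages"][s] = {"n_before": n_before, "n_after": gm.n_snps}
    except Exception as e:  # noqa: BLE001
        raise StageError("filter", e) from e

    try:
        s = stage("encode")
        indicators = encode_genotypes(gm)
        freqs = summarize_frequencies(gm)
        freqs["snp"].to_csv(out("snp_frequencies.csv"), index=False)
        freqs["sample"].to_csv(out("sample_heterozygosity.csv"), index=False)
        manifest["stages"][s] = {"n_indicators": indicators.n_indicators}
    except Exception as e:  # noqa: BLE001
        raise StageError("encode", e) from e

    try:
        s = stage("pca")
        pca = fit_pca(gm, n_components=max(config.pca_components, 2))
        cov = select_covariates(pca, k=config.pca_components)
        pd.DataFrame(
            pca.scores,
            index=pca.sample_ids,
            columns=[f"PC{i + 1}" for i in range(pca.scores.shape[1])],
        ).to_csv(out("pca_scores.csv"))
        manifest["stages"][s] = {
            "variance_proportions": [float(x) for x in pca.variance_proportions[:5]],
            "k": config.pca_components,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("pca", e) from e

    try:
        s = stage("gea")
        records = run_gea(
            indicators,
            env,
            covariates=cov,
            variables=config.variables,
            q_thresh=config.q_thresh,
            p_thresh=config.p_thresh,
        )
        records.to_csv(out("gea_records.csv"), index=False)
        manifest["stages"][s] = {
            "n_records": len(records),
            "n_significant_pairs": int(records["significant"].sum()),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("gea", e) from e

    try:
        s = stage("summary")
        by_var = count_significant_by_variable(records)
        by_var.to_csv(out("significant_by_variable.csv"), index=False)
        vset = [v for v in config.variable_set if v in env.columns]
        groups = classify_by_sign(records, vset, freqs["snp"]) if vset else {}
        rows = []
        for sign, g in groups.items():
            rows.append(
                dict(sign=sign, n_genotypes=g.n_genotypes,
                     pct_of_total=g.pct_of_total,
                     pct_homozygous=g.pct_homozygous,
                     pct_heterozygous=g.pct_heterozygous,
                     median_allele_frequency=g.median_allele_frequency)
            )
            if g.n_genotypes:
                per_individual_counts(records, indicators, vset, sign).to_csv(
                    out(f"per_individual_{sign}.csv")
                )
        pd.DataFrame(rows).to_csv(out("sign_groups.csv"), index=False)
        manifest["stages"][s] = {
            "distinct_significant": by_var.attrs.get("distinct_indicators", 0),
            "total_pairs": by_var.attrs.get("total_pairs", 0),
            "sign_groups": {r["sign"]: r["n_genotypes"] for r in rows},
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("summary", e) from e

    if config.run_moran:
        try:
            s = stage("moran")
            w = build_weights(samples, k=config.k_neighbors)
            rng = np.random.default_rng([config.seed, 77])
            rows = []
            for name in env.columns:
                r = global_moran(env[name].to_numpy(), w,
                                 n_perm=config.n_perm, seed=rng)
                rows.append(dict(vector=name, kind="env", I=r.I,
                                 expected=r.expected, pseudo_p=r.pseudo_p))
            sig_snps = records.loc[records["significant"], "snp_id"].unique()
            chosen = list(sig_snps[: config.moran_max_vectors])
            snp_pos = {sid: i for i, sid in enumerate(gm.snp_ids)}
            for sid in chosen:
                y = gm.dosage[snp_pos[sid]].astype(float)
                y[y < 0] = np.nan
                y = np.where(np.isnan(y), np.nanmean(y), y)
                if y.min() == y.max():
                    continue
                r = global_moran(y, w, n_perm=config.n_perm, seed=rng)
                rows.append(dict(vector=sid, kind="genotype", I=r.I,
                                 expected=r.expected, pseudo_p=r.pseudo_p))
            moran_df = pd.DataFrame(rows)
            moran_df.to_csv(out("moran.csv"), index=False)
            manifest["stages"][s] = {"n_vectors": len(rows)}
        except Exception as e:  # noqa: BLE001
            raise StageError("moran", e) from e

    hits = None
    if config.gff3:
        try:
            s = stage("annotate")
            vset = [v for v in config.variable_set if v in env.columns]
            sig = records[records["significant"] & records["env_var"].isin(vset)]
            cand = sorted(sig["snp_id"].unique())
            pos = {sid: i for i, sid in enumerate(gm.snp_ids)}
            snp_df = pd.DataFrame(
                {
                    "snp_id": cand,
                    "chrom": [gm.chrom[pos[sid]] for sid in cand],
                    "pos": [int(gm.pos[pos[sid]]) for sid in cand],
                }
            )
            index = annotate_mod.read_gff3(config.gff3)
            hits = annotate_mod.intersect_snps(snp_df, index)
            hits.to_csv(out("annotation_hits.csv"), index=False)
            genic = hits[hits["gene_id"].notna()]
            manifest["stages"][s] = {
                "n_candidate_snps": len(cand),
                "n_genic_hits": len(genic),
                "by_class": genic["feature_class"].value_counts().to_dict(),
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("annotate", e) from e

    enr = None
    dag = None
    closure = None
    if config.obo and config.annotations and hits is not None:
        try:
            s = stage("enrich")
            dag = enrich_mod.load_obo(config.obo)
            ann = pd.read_csv(config.annotations, sep=None, engine="python")
            closure = enrich_mod.propagate_annotations(ann, dag)
            genic = hits[hits["gene_name"].notna()]
            counts = genic.groupby("gene_name")["snp_id"].nunique()
            cluster_hits = pd.DataFrame(
                {"gene": counts.index, "n_snps": counts.to_numpy()}
            )
            cluster = enrich_mod.multi_snp_expansion(cluster_hits, config.snp_mode)
            background = sorted(closure)
            # suffixed SNP entries inherit the parent gene's annotations
            for name in cluster:
                base = name.rsplit("_", 1)[0] if "_" in name else name
                if name not in closure and base in closure:
                    closure[name] = closure[base]
            background = sorted(set(background) | set(cluster))
            cluster = [g for g in cluster if g in closure]
            enr = enrich_mod.hypergeometric_enrichment(
                cluster, background, closure,
                namespace=config.namespace, dag=dag,
            )
            enr.to_csv(out("enrichment.csv"), index=False)
            manifest["stages"][s] = {
                "n_cluster_genes": len(cluster),
                "n_terms_tested": len(enr),
                "n_significant_terms": int(enr["significant"].sum()) if len(enr) else 0,
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("enrich", e) from e

    if enr is not None and len(enr):
        try:
            s = stage("semsim")
            term_ic = semsim_mod.information_content(
                closure, dag, namespace=config.namespace
            )
            sig_terms = enr[enr["significant"]][["term_id", "p"]]
            red = semsim_mod.reduce_terms(sig_terms, term_ic, dag, C=config.simrel_C)
            red.to_csv(out("semsim_reduction.csv"), index=False)
            manifest["stages"][s] = {
                "n_terms": len(red),
                "n_representatives": int(red["representative"].nunique()) if len(red) else 0,
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("semsim", e) from e

    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
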