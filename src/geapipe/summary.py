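"""Variable correlation grouping and adaptive-genotype classification.

Two post-association summaries: (1) hierarchical grouping of
environmental variables by absolute Pearson correlation, used to pick a
representative set of tightly linked gradients (e.g. winter temperature
and precipitation variables); (2) classification of the significantly
associated genotype indicators by the sign of their environment
coefficient beta1 -- a positive-coefficient group (genotypes enriched
where the variable is high) and a negative one (enriched in the cold/dry
extreme when the variable is a winter gradient) -- with homozygote /
heterozygote composition, median allele frequencies and per-individual
carrier counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import beta as beta_dist

logger = logging.getLogger(__name__)

# Default six-variable seasonal sets (bioclim codes). These are this
# package's assumption for "winter" (cold/dry season) and "summer"
# (warm/wet season) variables, configurable per analysis.
WINTER_VARIABLES = ["Bio6", "Bio9", "Bio11", "Bio14", "Bio17", "Bio19"]
SUMMER_VARIABLES = ["Bio5", "Bio8", "Bio10", "Bio13", "Bio16", "Bio18"]
# Four-variable core winter set: coldest-period temperature and
# driest-period precipitation.
WINTER_CORE_VARIABLES = ["Bio6", "Bio11", "Bio14", "Bio17"]


@dataclass
class VariableGrouping:
    groups: dict[str, list[str]]
    correlation: pd.DataFrame
    pvalues: pd.DataFrame
    linkage_tree: np.ndarray


@dataclass
class SignGroupSummary:
    """Composition of one beta1-sign group of associated genotypes."""

    sign: str
    n_genotypes: int
    pct_of_total: float
    pct_homozygous: float
    pct_heterozygous: float
    median_allele_frequency: float
    members: pd.DataFrame = field(repr=False, default=None)


def _pearson_with_p(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, m = X.shape
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    r = Z.T @ Z / n
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    # two-sided p via the exact beta distribution of r under the null
    ab = (n - 2) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 2 * beta_dist.cdf(-np.abs(r) / 2 + 0.5, ab, ab)
    np.fill_diagonal(p, 0.0)
    return r, p


def correlate_variables(
    env_table: pd.DataFrame, sig_level: float = 0.01, r_min: float = 0.6
) -> VariableGrouping:
    """Group variables by |Pearson r| with average-linkage clustering.

    Distance is 1 - |r|, with non-significant correlations (two-sided
    p >= ``sig_level``) treated as zero.  The average-linkage tree is cut
    at distance 1 - ``r_min`` and any resulting group whose weakest
    internal pair has |r| <= ``r_min`` is split at its top merge until all
    groups satisfy the pairwise bound.  Constant variables are excluded
    with a warning.
    """
    if env_table.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    X = env_table.to_numpy(dtype=float)
    const = X.std(axis=0) == 0
    if const.any():
        dropped = [c for c, f in zip(env_table.columns, const) if f]
        logger.warning("excluding constant variables: %s", dropped)
        env_table = env_table.loc[:, ~const]
        X = X[:, ~const]
    names = list(env_table.columns)
    r, p = _pearson_with_p(X)
    r_eff = np.where(p < sig_level, r, 0.0)
    np.fill_diagonal(r_eff, 1.0)
    dist = 1.0 - np.abs(r_eff)
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")

    # members per linkage node
    m = len(names)
    node_members: dict[int, list[int]] = {i: [i] for i in range(m)}
    for i, row in enumerate(Z):
        node_members[m + i] = node_members[int(row[0])] + node_members[int(row[1])]

    def ok(mem: list[int]) -> bool:
        if len(mem) == 1:
            return True
        sub = np.abs(r_eff[np.ix_(mem, mem)])
        return float(sub[~np.eye(len(mem), dtype=bool)].min()) > r_min

    # start from the cut at 1 - r_min, then split violating groups
    def collect(node: int, height_limit: float) -> list[int]:
        if node < m:
            return [node]
        row = Z[node - m]
        if row[2] <= height_limit:
            return [node]
        return collect(int(row[0]), height_limit) + collect(int(row[1]), height_limit)

    frontier = collect(2 * m - 2, 1.0 - r_min)
    final: list[list[int]] = []
    while frontier:
        node = frontier.pop()
        mem = node_members[node]
        if ok(mem):
            final.append(mem)
        else:
            row = Z[node - m]
            frontier.extend([int(row[0]), int(row[1])])
    final.sort(key=lambda mem: min(mem))
    groups = {
        f"group{g + 1}": [names[i] for i in sorted(mem)]
        for g, mem in enumerate(final)
    }
    rdf = pd.DataFrame(r, index=names, columns=names)
    pdf = pd.DataFrame(p, index=names, columns=names)
    return VariableGrouping(groups=groups, correlation=rdf, pvalues=pdf, linkage_tree=Z)


def count_significant_by_variable(records: pd.DataFrame) -> pd.DataFrame:
    """Per-variable significant pair counts and distinct-indicator counts.

    A row per variable: ``n_pairs`` significant (indicator, variable)
    associations and ``pct`` of all significant pairs.  The attached
    ``.attrs['total_pairs']`` and ``.attrs['distinct_indicators']`` give
    run totals (an indicator significant for several variables counts
    once in the distinct total).
    """
    sig = records[records.get("significant", pd.Series(dtype=bool)) == True]  # noqa: E712
    if len(sig) == 0:
        out = pd.DataFrame(columns=["env_var", "n_pairs", "pct"])
        out.attrs["total_pairs"] = 0
        out.attrs["distinct_indicators"] = 0
        return out
    counts = (
        sig.groupby("env_var", sort=True).size().rename("n_pairs").reset_index()
    )
    total = int(counts["n_pairs"].sum())
    counts["pct"] = 100.0 * counts["n_pairs"] / total
    out = counts
    out.attrs["total_pairs"] = total
    out.attrs["distinct_indicators"] = int(
        sig.drop_duplicates(["snp_id", "genotype_class"]).shape[0]
    )
    return out


def _assign_signs(records: pd.DataFrame, variable_set: list[str]) -> pd.DataFrame:
    sig = records[
        records["significant"] & records["env_var"].isin(variable_set)
    ].copy()
    if len(sig) == 0:
        return sig.assign(sign=pd.Series(dtype=str))
    # most significant association wins; ties by larger |beta1|, then order
    sig["_abs_b1"] = -sig["beta1"].abs()
    sig = sig.sort_values(
        ["q_G", "_abs_b1"], kind="stable"
    ).drop_duplicates(["snp_id", "genotype_class"], keep="first")
    multi = records[
        records["significant"] & records["env_var"].isin(variable_set)
    ].groupby(["snp_id", "genotype_class"])["beta1"].agg(
        lambda s: len(set(np.sign(s))) > 1
    )
    n_conflict = int(multi.sum())
    if n_conflict:
        logger.info(
            "%d indicators had conflicting beta1 signs across variables; "
            "assigned by lowest q_G",
            n_conflict,
        )
    sig["sign"] = np.where(sig["beta1"] > 0, "positive", "negative")
    return sig.drop(columns="_abs_b1")


def classify_by_sign(
    records: pd.DataFrame,
    variable_set: list[str],
    freq_table: pd.DataFrame,
) -> dict[str, SignGroupSummary]:
    """Split associated genotypes by the sign of beta1 and summarize.

    Each distinct indicator significant for at least one variable of
    ``variable_set`` is assigned the sign of the beta1 of its most
    significant (lowest q_G) association in the set.  ``freq_table`` is
    the per-SNP frequency frame from
    :func:`geapipe.genio.summarize_frequencies` (``['snp']``); the median
    allele frequency uses the composing allele for homozygote indicators
    and the minor allele for heterozygote indicators.
    """
    assigned = _assign_signs(records, variable_set)
    total = len(assigned)
    freq = freq_table.set_index("snp_id")
    out = {}
    for sign in ("positive", "negative"):
        grp = assigned[assigned["sign"] == sign]
        n = len(grp)
        if n == 0:
            out[sign] = SignGroupSummary(sign, 0, 0.0, np.nan, np.nan, np.nan, grp)
            continue
        is_het = grp["genotype_class"] == "het"
        alt_f = freq.loc[grp["snp_id"], "alt_freq"].to_numpy()
        maf = freq.loc[grp["snp_id"], "maf"].to_numpy()
        af = np.where(
            grp["genotype_class"] == "hom_ref",
            1.0 - alt_f,
            np.where(grp["genotype_class"] == "hom_alt", alt_f, maf),
        )
        out[sign] = SignGroupSummary(
            sign=sign,
            n_genotypes=n,
            pct_of_total=100.0 * n / total,
            pct_homozygous=100.0 * float((~is_het).mean()),
            pct_heterozygous=100.0 * float(is_het.mean()),
            median_allele_frequency=float(np.median(af)),
            members=grp.reset_index(drop=True),
        )
    return out


def per_individual_counts(
    records: pd.DataFrame,
    indicators,
    variable_set: list[str],
    sign: str,
) -> pd.Series:
    """Number of sign-group genotypes each individual carries.

    For every sample, counts the group's indicators whose value is 1;
    missing indicator values contribute 0.
    """
    assigned = _assign_signs(records, variable_set)
    grp = assigned[assigned["sign"] == sign]
    key = indicators.meta["snp_id"] + "|" + indicators.meta["genotype_class"]
    wanted = set(grp["snp_id"] + "|" + grp["genotype_class"])
    rows = np.array([k in wanted for k in key])
    vals = indicators.values[rows]
    counts = np.nansum(vals, axis=0) if rows.any() else np.zeros(
        indicators.values.shape[1]
    )
    return pd.Series(
        counts.astype(int), index=indicators.sample_ids, name=f"n_{sign}"
    )
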