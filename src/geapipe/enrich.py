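"""GO-term overrepresentation by the hypergeometric test.

Annotations are propagated up the ontology (a gene annotated to a term is
annotated to all its is_a/part_of ancestors -- the true-path rule), then
each term is scored by the upper-tail hypergeometric probability of
seeing k cluster genes annotated to it given K of the N background genes
are: p = P(X >= k), X ~ Hypergeometric(N, K, n).  The background is the
custom annotation universe (genes with at least one propagated
annotation), mirroring a "whole annotation as reference set" analysis;
Benjamini-Hochberg adjusted p-values are reported alongside the raw
p < 0.05 significance gate.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_RELATIONS = ("is_a", "part_of")


def load_obo(path: str, relations=DEFAULT_RELATIONS) -> nx.DiGraph:
    """Read an OBO ontology into a child -> parent DiGraph.

    Keeps only the given relationship types as edges; obsolete terms are
    excluded.  Node attributes carry ``name`` and ``namespace``.
    """
    import obonet

    multi = obonet.read_obo(str(path))  # skips obsolete terms
    dag = nx.DiGraph()
    dag.add_nodes_from(multi.nodes(data=True))
    for u, v, key in multi.edges(keys=True):
        if key in relations:
            dag.add_edge(u, v, relation=key)
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("ontology graph contains a cycle")
    return dag


def ancestors(dag: nx.DiGraph, term: str) -> set[str]:
    """All is_a/part_of ancestors of ``term`` (edges point child->parent)."""
    return nx.descendants(dag, term)


def namespace_root(dag: nx.DiGraph, namespace: str) -> str:
    roots = [
        t
        for t, d in dag.nodes(data=True)
        if d.get("namespace") == namespace and dag.out_degree(t) == 0
    ]
    if len(roots) != 1:
        raise ValueError(
            f"expected one root for namespace {namespace!r}, found {roots}"
        )
    return roots[0]


def propagate_annotations(
    annotations: pd.DataFrame | dict,
    dag: nx.DiGraph,
) -> dict[str, frozenset[str]]:
    """Gene -> annotated-term closure under the true-path rule.

    ``annotations`` is a two-column frame (gene, term) or a mapping of
    gene to an iterable of term ids.  Terms absent from the ontology
    (including obsolete ones, which the loader drops) are skipped with a
    warning count.
    """
    if isinstance(annotations, pd.DataFrame):
        pairs = [
            (str(g), str(t)) for g, t in annotations.iloc[:, :2].itertuples(index=False)
        ]
    else:
        pairs = [(g, t) for g, terms in annotations.items() for t in terms]
    anc_cache: dict[str, frozenset[str]] = {}
    closure: dict[str, set[str]] = {}
    n_unknown = 0
    for gene, term in pairs:
        if term not in dag:
            n_unknown += 1
            continue
        if term not in anc_cache:
            anc_cache[term] = frozenset(ancestors(dag, term) | {term})
        closure.setdefault(gene, set()).update(anc_cache[term])
    if n_unknown:
        logger.warning("dropped %d annotations to unknown/obsolete terms", n_unknown)
    return {g: frozenset(ts) for g, ts in closure.items()}


def hypergeometric_enrichment(
    cluster: list[str],
    background: list[str],
    closure: dict[str, frozenset[str]],
    namespace: str | None = None,
    dag: nx.DiGraph | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per term.

    ``cluster`` must be a subset of ``background``; genes without any
    propagated annotation do not count toward N (reference-set
    semantics).  With ``namespace`` (and ``dag``), terms and the
    annotated-gene universe are restricted to that sub-ontology.  Returns
    term_id, k, n, K, N, p, p_adj (BH) and ``significant`` at raw
    p < 0.05, sorted by p.
    """
    cluster = list(dict.fromkeys(cluster))
    background = list(dict.fromkeys(background))
    if not cluster or not background:
        raise ValueError("cluster and background must be nonempty")
    missing = set(cluster) - set(background)
    if missing:
        raise ValueError(f"cluster genes absent from background: {sorted(missing)[:5]}")

    def terms_of(gene: str) -> frozenset[str]:
        ts = closure.get(gene, frozenset())
        if namespace is not None:
            if dag is None:
                raise ValueError("namespace filtering requires the dag")
            ts = frozenset(
                t for t in ts if dag.nodes[t].get("namespace") == namespace
            )
        return ts

    bg_annot = {g: terms_of(g) for g in background}
    bg_annotated = [g for g, ts in bg_annot.items() if ts]
    N = len(bg_annotated)
    cl_annotated = [g for g in cluster if bg_annot.get(g)]
    n = len(cl_annotated)
    term_K: dict[str, int] = {}
    for g in bg_annotated:
        for t in bg_annot[g]:
            term_K[t] = term_K.get(t, 0) + 1
    term_k: dict[str, int] = {}
    for g in cl_annotated:
        for t in bg_annot[g]:
            term_k[t] = term_k.get(t, 0) + 1
    rows = []
    for t in sorted(term_k):
        k, K = term_k[t], term_K[t]
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(dict(term_id=t, k=k, n=n, K=K, N=N, p=min(p, 1.0)))
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["p"] < 0.05
        df = df.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
    else:
        df = pd.DataFrame(
            columns=["term_id", "k", "n", "K", "N", "p", "p_adj", "significant"]
        )
    return df


def multi_snp_expansion(hits: pd.DataFrame, mode: str = "multi") -> list[str]:
    """Expand gene hits by SNP multiplicity.

    ``hits`` has columns gene and n_snps.  mode='multi' emits one entry
    per SNP, suffixing duplicates (gene, gene_1, gene_2, ...) so each
    entry represents a single SNP; mode='single' emits one entry per
    gene.
    """
    if mode not in ("multi", "single"):
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    for rec in hits.itertuples(index=False):
        gene, n = str(rec.gene), int(rec.n_snps)
        if mode == "single" or n <= 1:
            out.append(gene)
        else:
            out.append(gene)
            out.extend(f"{gene}_{i}" for i in range(1, n))
    return out
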