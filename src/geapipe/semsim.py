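"""Semantic-similarity reduction of enriched ontology terms.

Redundant GO terms are collapsed with the SimRel measure.  Each term's
information content is IC(t) = -ln p(t), where p(t) is the fraction of
the annotation corpus annotated to t (after true-path propagation)
relative to the namespace root.  For two terms, the most informative
common ancestor (MICA) is the shared ancestor with maximal IC and

    SimRel(t1, t2) = (2 * IC(MICA) / (IC(t1) + IC(t2))) * (1 - p(MICA))

which is 0 when the only common ancestor is the root and approaches
1 - p(t) for identical rare terms.  Reduction is greedy, REVIGO-like:
terms are visited in ascending enrichment p-value; a term joins the first
existing representative it resembles (SimRel >= C, its dispensability),
otherwise it founds a new cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .enrich import ancestors, namespace_root


@dataclass
class TermIC:
    """Annotation probability and information content per term (nats)."""

    p: dict[str, float]
    ic: dict[str, float]
    namespace: str
    root: str


def information_content(
    closure: dict[str, frozenset[str]],
    dag: nx.DiGraph,
    namespace: str = "biological_process",
) -> TermIC:
    """p(t) and IC(t) from an annotation corpus.

    p(t) = genes annotated (directly or via descendants, i.e. through the
    propagated closure) to t, divided by genes annotated to the namespace
    root; IC = -ln p.  Terms with zero annotations are excluded (their IC
    is undefined on this corpus).
    """
    root = namespace_root(dag, namespace)
    counts: dict[str, int] = {}
    for terms in closure.values():
        for t in terms:
            if dag.nodes[t].get("namespace") == namespace:
                counts[t] = counts.get(t, 0) + 1
    n_root = counts.get(root, 0)
    if n_root == 0:
        raise ValueError(f"no genes annotated to {namespace} root")
    p = {t: c / n_root for t, c in counts.items()}
    ic = {t: float(-np.log(v)) for t, v in p.items()}
    return TermIC(p=p, ic=ic, namespace=namespace, root=root)


def simrel(t1: str, t2: str, term_ic: TermIC, dag: nx.DiGraph) -> float:
    """SimRel similarity between two terms, in [0, 1].

    Terms without defined IC raise; disjoint terms (no common ancestor
    with defined IC in the namespace) score 0.
    """
    for t in (t1, t2):
        if t not in term_ic.ic:
            raise ValueError(f"term {t} has no defined IC on this corpus")
    anc1 = (ancestors(dag, t1) | {t1}) & set(term_ic.ic)
    anc2 = (ancestors(dag, t2) | {t2}) & set(term_ic.ic)
    common = anc1 & anc2
    if not common:
        return 0.0
    mica = max(common, key=lambda t: (term_ic.ic[t], t))
    ic_sum = term_ic.ic[t1] + term_ic.ic[t2]
    if ic_sum == 0.0:
        return 0.0  # both are the root
    return float(2.0 * term_ic.ic[mica] / ic_sum * (1.0 - term_ic.p[mica]))


def reduce_terms(
    terms: pd.DataFrame,
    term_ic: TermIC,
    dag: nx.DiGraph,
    C: float = 0.7,
) -> pd.DataFrame:
    """Greedy dispensability clustering of enriched terms.

    ``terms`` has columns term_id and p (enrichment p-value).  Terms are
    processed by ascending p (ties by term id); each joins the earliest
    representative with SimRel >= ``C`` -- recording that similarity as
    its dispensability -- or becomes a representative itself
    (dispensability 0).  Terms without IC on the corpus are dropped.
    Returns term_id, p, ic, representative, dispensability.
    """
    if len(terms) == 0:
        return pd.DataFrame(
            columns=["term_id", "p", "ic", "representative", "dispensability"]
        )
    df = terms[["term_id", "p"]].copy()
    df = df[df["term_id"].isin(term_ic.ic)]
    df = df.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
    reps: list[str] = []
    rows = []
    for rec in df.itertuples(index=False):
        t = rec.term_id
        assigned = None
        disp = 0.0
        for r in reps:
            s = simrel(t, r, term_ic, dag)
            if s >= C:
                assigned, disp = r, s
                break
        if assigned is None:
            reps.append(t)
            assigned = t
        rows.append(
            dict(
                term_id=t,
                p=rec.p,
                ic=term_ic.ic[t],
                representative=assigned,
                dispensability=disp,
            )
        )
    return pd.DataFrame(rows)
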