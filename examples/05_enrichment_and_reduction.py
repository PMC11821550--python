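"""GO enrichment of candidate genes and SimRel redundancy reduction.

A toy ontology and annotation corpus are built inline; a cluster of
candidate genes biased toward transport terms is tested against the full
background with the upper-tail hypergeometric test, and the significant
terms are collapsed by SimRel similarity (terms joining a representative
they resemble at >= 0.7).
"""

import numpy as np
import pandas as pd

from geapipe.enrich import hypergeometric_enrichment, load_obo, propagate_annotations
from geapipe.semsim import information_content, reduce_terms

import os
import tempfile

from geapipe.simdata import (
    SYNTHETIC_BP_TERMS,
    SYNTHETIC_SIGNAL_TERMS,
    write_synthetic_ontology,
)

tmp = tempfile.mkdtemp()
obo = os.path.join(tmp, "synthetic.obo")
write_synthetic_ontology(obo)
dag = load_obo(obo)

rng = np.random.default_rng(0)
generic = [t for t, _, p in SYNTHETIC_BP_TERMS
           if p and t not in SYNTHETIC_SIGNAL_TERMS]
rows = []
for g in range(400):
    pool = SYNTHETIC_SIGNAL_TERMS if g < 40 else generic  # 40 candidate-like genes
    for t in rng.choice(pool, size=2, replace=False):
        rows.append((f"g{g}", t))
closure = propagate_annotations(pd.DataFrame(rows, columns=["gene", "term"]), dag)

cluster = [f"g{i}" for i in range(40)]
res = hypergeometric_enrichment(cluster, sorted(closure), closure,
                                namespace="biological_process", dag=dag)
sig = res[res.significant]
print(f"{len(sig)} of {len(res)} terms significant (raw p < 0.05):")
print(sig[["term_id", "k", "K", "p", "p_adj"]].to_string(index=False))

ic = information_content(closure, dag, "biological_process")
red = reduce_terms(sig[["term_id", "p"]], ic, dag, C=0.7)
n_rep = red["representative"].nunique()
print(f"\nSimRel reduction: {len(red)} terms -> {n_rep} representatives")
print(red[["term_id", "representative", "dispensability"]].to_string(index=False))
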