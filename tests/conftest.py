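import numpy as np
import pandas as pd
import pytest

from geapipe.simdata import SimConfig, simulate_dataset

MINI_OBO = """format-version: 1.2
ontology: go

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0008152
name: metabolic process
namespace: biological_process
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0009987
name: cellular process
namespace: biological_process
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0044237
name: cellular metabolic process
namespace: biological_process
is_a: GO:0008152 ! metabolic process
is_a: GO:0009987 ! cellular process

[Term]
id: GO:0006810
name: transport
namespace: biological_process
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0055085
name: transmembrane transport
namespace: biological_process
is_a: GO:0006810 ! transport

[Term]
id: GO:0016043
name: cellular component organization
namespace: biological_process
is_a: GO:0009987 ! cellular process
relationship: part_of GO:0044237 ! cellular metabolic process

[Term]
id: GO:0000001
name: long gone process
namespace: biological_process
is_obsolete: true

[Term]
id: GO:0003674
name: molecular_function
namespace: molecular_function

[Term]
id: GO:0005215
name: transporter activity
namespace: molecular_function
is_a: GO:0003674 ! molecular_function

[Typedef]
id: part_of
name: part of
"""

MINI_GFF3 = """##gff-version 3
chr1\ttest\tgene\t100\t500\t.\t+\t.\tID=geneA;Name=GA
chr1\ttest\tfive_prime_UTR\t100\t149\t.\t+\t.\tID=geneA.utr5;Parent=geneA
chr1\ttest\texon\t100\t260\t.\t+\t.\tID=geneA.e1;Parent=geneA
chr1\ttest\texon\t380\t500\t.\t+\t.\tID=geneA.e2;Parent=geneA
chr1\ttest\tthree_prime_UTR\t460\t500\t.\t+\t.\tID=geneA.utr3;Parent=geneA
chr1\ttest\tgene\t450\t900\t.\t-\t.\tID=geneB;Name=GB
chr1\ttest\texon\t450\t620\t.\t-\t.\tID=geneB.e1;Parent=geneB
chr1\ttest\texon\t800\t900\t.\t-\t.\tID=geneB.e2;Parent=geneB
chr2\ttest\tgene\t1000\t1400\t.\t+\t.\tID=geneC
chr2\ttest\texon\t1000\t1400\t.\t+\t.\tID=geneC.e1;Parent=geneC
"""


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_samples=120, n_snps=200, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(gm, env, samples, truth) with allele depths, 120 x 200."""
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def mini_dag(tmp_path_factory):
    from geapipe.enrich import load_obo

    path = tmp_path_factory.mktemp("obo") / "mini.obo"
    path.write_text(MINI_OBO)
    return load_obo(str(path))


@pytest.fixture(scope="session")
def mini_annotations():
    """gene -> direct GO annotations on the mini ontology."""
    return pd.DataFrame(
        [
            ("g1", "GO:0044237"),
            ("g2", "GO:0044237"),
            ("g3", "GO:0008152"),
            ("g4", "GO:0055085"),
            ("g5", "GO:0055085"),
            ("g6", "GO:0006810"),
            ("g7", "GO:0009987"),
            ("g8", "GO:0008150"),
            ("g9", "GO:0016043"),
            ("g10", "GO:0005215"),
        ],
        columns=["gene", "term"],
    )


@pytest.fixture(scope="session")
def mini_gff3(tmp_path_factory):
    path = tmp_path_factory.mktemp("gff") / "mini.gff3"
    path.write_text(MINI_GFF3)
    return str(path)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
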