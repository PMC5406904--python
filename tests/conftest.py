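import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from netpathad.io import load_disease_gene_fixture, load_enrichment_table


@pytest.fixture(scope="session")
def pathway_table():
    return load_enrichment_table()


@pytest.fixture(scope="session")
def disease_genes():
    return load_disease_gene_fixture()
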