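import io

import pytest

from gofuse.pipeline import RunConfig, run_pipeline
from gofuse.synthetic import SimConfig, make_worked_fixture, simulate

CHAIN_OBO = """format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: middle
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: leaf
namespace: biological_process
is_a: GO:0000002 ! middle

[Term]
id: GO:0000004
name: gone
namespace: biological_process
is_a: GO:0000001 ! root
is_obsolete: true
"""

# diamond: leaf has two paths to the root, one via part_of
DIAMOND_OBO = """format-version: 1.2
ontology: toy

[Term]
id: GO:0000010
name: root
namespace: molecular_function

[Term]
id: GO:0000011
name: left
namespace: molecular_function
is_a: GO:0000010 ! root

[Term]
id: GO:0000012
name: right
namespace: molecular_function
relationship: part_of GO:0000010 ! root

[Term]
id: GO:0000013
name: leaf
namespace: molecular_function
is_a: GO:0000011 ! left
is_a: GO:0000012 ! right
"""


@pytest.fixture
def chain_obo():
    return io.StringIO(CHAIN_OBO)


@pytest.fixture
def diamond_obo():
    return io.StringIO(DIAMOND_OBO)


@pytest.fixture(scope="session")
def worked():
    """Tiny fixed hand-verifiable bundle (10 genes, 3 planted modules)."""
    return make_worked_fixture()


@pytest.fixture(scope="session")
def planted_bundle():
    """Moderate planted-signal bundle shared by integration tests."""
    return simulate(
        SimConfig(
            seed=11,
            n_genes=60,
            module_sizes={"BP": [5, 12], "MF": [6]},
            n_samples=20,
            n_interactions=30,
        )
    )


@pytest.fixture(scope="session")
def pipeline_result(planted_bundle):
    b = planted_bundle
    return run_pipeline(
        b.ontology, b.ann_old, b.feature_tables, b.expression, b.ppi_edges,
        RunConfig(seed=11),
    )
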