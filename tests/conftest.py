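import pytest

from mirtfnet.fixtures import load_paper_fixtures
from mirtfnet.network import (
    build_tf_edges,
    find_core_nodes,
    find_ffls,
    merge_network,
    merge_tfbs_groups,
)
from mirtfnet.synthetic import SimConfig, generate_bundle, table2_edge_bundle
from mirtfnet.types import Config


@pytest.fixture(scope="session")
def fixtures():
    return load_paper_fixtures()


@pytest.fixture(scope="session")
def cfg():
    return Config()


@pytest.fixture(scope="session")
def reference_network(fixtures):
    """Network rebuilt from the bundled FFL table via the full machinery."""
    bundle = table2_edge_bundle(fixtures.ffl_table)
    groups, matrix_to_group = merge_tfbs_groups(bundle.mapped_hits)
    tf_gene, tf_mirna = build_tf_edges(bundle.mapped_hits, matrix_to_group)
    ffls = find_ffls(tf_gene, tf_mirna, bundle.mirna_gene_edges, groups)
    net = merge_network(ffls)
    return {
        "bundle": bundle,
        "groups": groups,
        "tf_gene": tf_gene,
        "tf_mirna": tf_mirna,
        "ffls": ffls,
        "net": net,
    }


@pytest.fixture(scope="session")
def synthetic_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    return generate_bundle(SimConfig(rng_seed=7), out)
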