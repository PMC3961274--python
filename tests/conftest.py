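import random

import numpy as np
import pytest

import miregnet as m


@pytest.fixture(scope="session")
def fixture_net():
    """The literature fixture (records + annotations)."""
    return m.paper_fixture()


@pytest.fixture(scope="session")
def global_net(fixture_net):
    return m.build_global_network(fixture_net.base_records,
                                  fixture_net.annotations)


@pytest.fixture(scope="session")
def differential_net(global_net, fixture_net):
    return m.extract_level_network(global_net, "differential",
                                   annotations=fixture_net.annotations)


@pytest.fixture(scope="session")
def related_net(global_net, fixture_net):
    return m.extract_level_network(global_net, "related",
                                   annotations=fixture_net.annotations)


@pytest.fixture(scope="session")
def tf1000_net(global_net, fixture_net):
    return m.integrate_predicted_tfs(
        global_net, fixture_net.predicted_tfs,
        fixture_net.tf_regulations, fixture_net.annotations,
    )


@pytest.fixture
def toy_pwm():
    """A sharply informative 8-position matrix (consensus TTGACGTA)."""
    counts = np.array([
        [1, 1, 1, 17],
        [0, 2, 0, 18],
        [1, 0, 19, 0],
        [18, 1, 1, 0],
        [0, 20, 0, 0],
        [0, 0, 20, 0],
        [1, 0, 0, 19],
        [17, 1, 1, 1],
    ])
    return m.PositionWeightMatrix.from_counts("TOYTF", counts)


def random_bipartite_network(rng: random.Random, max_genes: int = 7,
                             max_mirnas: int = 8,
                             edge_prob: float = 0.25) -> m.RegulatoryNetwork:
    """A random role-valid network with <=15 nodes for oracle comparisons."""
    genes = [f"G{i}" for i in range(rng.randint(2, max_genes))]
    mirnas = [f"hsa-miR-{i}" for i in range(rng.randint(2, max_mirnas))]
    net = m.RegulatoryNetwork()
    for g in genes:
        net.add_node(m.NodeRef(g, m.Role.GENE))
    for mi in mirnas:
        net.add_node(m.NodeRef(mi, m.Role.MIRNA))
    for g in genes:
        for mi in mirnas:
            if rng.random() < edge_prob:
                net.add_record(m.InteractionRecord(
                    m.NodeRef(g, m.Role.GENE), m.NodeRef(mi, m.Role.MIRNA),
                    m.EdgeKind.REGULATES))
            if rng.random() < edge_prob:
                net.add_record(m.InteractionRecord(
                    m.NodeRef(mi, m.Role.MIRNA), m.NodeRef(g, m.Role.GENE),
                    m.EdgeKind.TARGETS))
    return net
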