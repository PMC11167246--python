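import numpy as np
import pytest

from ican import chem_io, fixtures


@pytest.fixture(scope="session")
def molecules():
    """name -> (MolGraph, expected formula) for every curated fixture molecule."""
    out = {}
    for name, smiles, formula in fixtures.fixture_molecules():
        out[name] = (chem_io.parse_smiles(smiles), formula)
    return out


@pytest.fixture(scope="session")
def phenol(molecules):
    return molecules["phenol"][0]


def pairwise_distances_minplus(graph):
    """Independent all-pairs shortest-path oracle: min-plus matrix squaring
    on the adjacency matrix, no graph-library traversal involved."""
    nodes = sorted(graph.graph.nodes)
    pos = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    inf = float("inf")
    d = np.full((n, n), inf)
    np.fill_diagonal(d, 0.0)
    for u, v in graph.graph.edges:
        d[pos[u], pos[v]] = 1.0
        d[pos[v], pos[u]] = 1.0
    # repeated min-plus squaring until fixed point
    while True:
        nxt = np.min(d[:, :, None] + d[None, :, :], axis=1)
        if np.array_equal(nxt, d):
            break
        d = nxt
    return nodes, d
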