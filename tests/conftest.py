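import numpy as np
import pytest

from cone import Relationship, SignedLink, SignedNetwork


def make_link(a, b, rel="induce", directed=False):
    from cone.network import parse_relationship

    return SignedLink(a, b, parse_relationship(rel), directed)


@pytest.fixture
def chain3():
    """A -(induce)- B -(inhibit)- C."""
    return SignedNetwork(
        [make_link("A", "B", "induce"), make_link("B", "C", "inhibit")]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


def random_signed_network(rng, n_genes=20, n_links=30, directed=False):
    """Random small signed network for property tests."""
    genes = [f"G{i}" for i in range(n_genes)]
    links = []
    seen = set()
    while len(links) < n_links:
        i, j = rng.choice(n_genes, size=2, replace=False)
        key = (min(i, j), max(i, j)) if not directed else (int(i), int(j))
        if key in seen:
            continue
        seen.add(key)
        rel = Relationship.INHIBITING if rng.uniform() < 0.3 else Relationship.NON_INHIBITING
        links.append(SignedLink(genes[int(i)], genes[int(j)], rel, directed))
    return SignedNetwork(links, genes=genes, directed=directed)
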