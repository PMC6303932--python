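"""Signed molecular interaction networks and link coherence.

A regulatory network is a graph ``G = (V, E)`` whose vertices are genes and
whose links carry a regulatory relationship: *inhibiting* or
*non-inhibiting* (induction, binding, unsigned positive association).  Each
link has weight ``w(j, k) = -1`` if inhibiting and ``+1`` otherwise.

Given per-gene differential-expression estimates ``delta_j``, a link
``(j, k)`` is **coherent** when

    sign(delta_j) * sign(delta_k) * w(j, k) = 1,

i.e. the two genes change together across a non-inhibiting link and in
opposite directions across an inhibiting one.  The coherent subnetwork of a
contrast is obtained by discarding incoherent links and genes left without
any link.  The **boundary** of a subnetwork ``S`` is the union of its
incoherent internal links ``I`` and the links ``B`` crossing between
``V(S)`` and the rest of the network.

This module provides the data model (:class:`SignedLink`,
:class:`SignedNetwork`, :class:`Subnetwork`, :class:`BoundarySet`), the
coherence primitives, and edge-list / SIF / GraphML input-output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Hashable, Iterable, Iterator, List, Mapping, Optional, Sequence, Set, Tuple, Union

import networkx as nx

Gene = Hashable
LinkKey = Tuple[Gene, Gene]

__all__ = [
    "Relationship",
    "SignedLink",
    "SignedNetwork",
    "Subnetwork",
    "BoundarySet",
    "link_weight",
    "is_coherent",
    "coherence_filter",
    "boundary",
    "remove_isolated",
    "connected_components",
    "read_network_tsv",
    "write_network_tsv",
    "write_graphml",
]


class Relationship(str, Enum):
    """Regulatory nature of a link."""

    INHIBITING = "inhibiting"
    NON_INHIBITING = "non_inhibiting"


#: accepted spellings in edge-list files; anything else is rejected so that
#: silently mis-coded relationships cannot slip through.
_RELATIONSHIP_ALIASES: Dict[str, Relationship] = {
    "inhibit": Relationship.INHIBITING,
    "inhibiting": Relationship.INHIBITING,
    "inhibition": Relationship.INHIBITING,
    "repression": Relationship.INHIBITING,
    "induce": Relationship.NON_INHIBITING,
    "inducing": Relationship.NON_INHIBITING,
    "activation": Relationship.NON_INHIBITING,
    "binding": Relationship.NON_INHIBITING,
    "other": Relationship.NON_INHIBITING,
    "unknown": Relationship.NON_INHIBITING,
    "non_inhibiting": Relationship.NON_INHIBITING,
}


def parse_relationship(token: str) -> Relationship:
    """Map an edge-list token to a :class:`Relationship`.

    Unknown-but-possibly-inhibiting labels are not guessed at: only the
    aliases listed in ``_RELATIONSHIP_ALIASES`` are accepted, and every
    non-inhibiting alias maps to weight +1.
    """
    try:
        return _RELATIONSHIP_ALIASES[token.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unrecognised relationship label {token!r}; expected one of "
            f"{sorted(_RELATIONSHIP_ALIASES)}"
        ) from None


@dataclass(frozen=True)
class SignedLink:
    """A single regulatory link between two distinct genes."""

    source: Gene
    target: Gene
    relationship: Relationship = Relationship.NON_INHIBITING
    directed: bool = False

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-loop on gene {self.source!r} is not allowed")
        if not isinstance(self.relationship, Relationship):
            object.__setattr__(self, "relationship", parse_relationship(str(self.relationship)))

    @property
    def weight(self) -> int:
        """``-1`` for inhibiting links, ``+1`` otherwise."""
        return -1 if self.relationship is Relationship.INHIBITING else 1

    @property
    def key(self) -> LinkKey:
        """Canonical identity: ordered pair if directed, sorted pair if not."""
        if self.directed:
            return (self.source, self.target)
        a, b = sorted((self.source, self.target), key=repr)
        return (a, b)

    def endpoints(self) -> Tuple[Gene, Gene]:
        return (self.source, self.target)


def link_weight(link: SignedLink) -> int:
    """Weight ``w(j, k)`` of a link: -1 if inhibiting, +1 otherwise."""
    return link.weight


def _sign(x: float) -> int:
    if not math.isfinite(x):
        raise ValueError(f"non-finite differential-expression estimate: {x!r}")
    return int(x > 0) - int(x < 0)


def is_coherent(delta_j: float, delta_k: float, weight: int) -> bool:
    """Whether a link is coherent for the given endpoint estimates.

    A link is coherent iff ``sign(delta_j) * sign(delta_k) * weight == 1``.
    A zero estimate at either endpoint makes the product 0, hence incoherent.

    Raises
    ------
    ValueError
        If either estimate is NaN/inf or ``weight`` is not in {-1, +1}.
    """
    if weight not in (-1, 1):
        raise ValueError(f"link weight must be -1 or +1, got {weight!r}")
    return _sign(delta_j) * _sign(delta_k) * weight == 1


class SignedNetwork:
    """The universe network ``G = (V, E)``.

    Parameters
    ----------
    links
        Iterable of :class:`SignedLink`.  Links are stored under their
        canonical key; for undirected networks the unordered pair appears
        once, for directed networks ``(j, k)`` and ``(k, j)`` are distinct.
        Exact duplicate links are collapsed with a warning; the same key
        with conflicting relationships is an error.
    genes
        Extra genes to include beyond link endpoints (isolated genes are
        legal in the universe network).
    directed
        Directedness of the network; link ``directed`` flags are coerced to
        match.
    """

    def __init__(
        self,
        links: Iterable[SignedLink] = (),
        genes: Iterable[Gene] = (),
        directed: bool = False,
    ) -> None:
        self.directed = bool(directed)
        self._links: Dict[LinkKey, SignedLink] = {}
        self._adjacency: Dict[Gene, Set[LinkKey]] = {}
        self.genes: Set[Gene] = set(genes)
        for g in self.genes:
            self._adjacency.setdefault(g, set())
        for link in links:
            self.add_link(link)

    # -- construction -----------------------------------------------------

    def add_link(self, link: SignedLink) -> None:
        if link.directed != self.directed:
            link = SignedLink(link.source, link.target, link.relationship, self.directed)
        key = link.key
        existing = self._links.get(key)
        if existing is not None:
            if existing.relationship is link.relationship:
                warnings.warn(f"duplicate link {key} collapsed", stacklevel=2)
                return
            raise ValueError(
                f"conflicting relationships for link {key}: "
                f"{existing.relationship.value} vs {link.relationship.value}"
            )
        self._links[key] = link
        for g in link.endpoints():
            self.genes.add(g)
            self._adjacency.setdefault(g, set()).add(key)

    # -- queries ----------------------------------------------------------

    @property
    def links(self) -> List[SignedLink]:
        return list(self._links.values())

    @property
    def link_keys(self) -> Set[LinkKey]:
        return set(self._links)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_links(self) -> int:
        return len(self._links)

    def __contains__(self, key: LinkKey) -> bool:
        return key in self._links

    def get_link(self, key: LinkKey) -> SignedLink:
        return self._links[key]

    def links_of(self, gene: Gene) -> List[SignedLink]:
        return [self._links[k] for k in self._adjacency.get(gene, ())]

    def neighbors(self, gene: Gene) -> Set[Gene]:
        out: Set[Gene] = set()
        for link in self.links_of(gene):
            j, k = link.endpoints()
            out.add(k if j == gene else j)
        return out

    def degree(self, gene: Gene) -> int:
        return len(self._adjacency.get(gene, ()))

    def canonical_key(self, source: Gene, target: Gene) -> LinkKey:
        if self.directed:
            return (source, target)
        a, b = sorted((source, target), key=repr)
        return (a, b)

    # -- derived structures ----------------------------------------------

    def induced_subnetwork(self, genes: Iterable[Gene]) -> "Subnetwork":
        """Subnetwork on ``genes`` with all parent links among them."""
        gene_set = set(genes)
        keys = {
            k
            for k, link in self._links.items()
            if link.source in gene_set and link.target in gene_set
        }
        return Subnetwork(self, gene_set, keys)

    def restricted_to(self, genes: Iterable[Gene]) -> "SignedNetwork":
        """A new universe network restricted to ``genes`` (isolated kept)."""
        gene_set = set(genes) & self.genes
        links = [
            l for l in self._links.values()
            if l.source in gene_set and l.target in gene_set
        ]
        return SignedNetwork(links, genes=gene_set, directed=self.directed)


class Subnetwork:
    """A subnetwork ``S`` of a parent :class:`SignedNetwork`.

    ``E(S)`` need not contain every parent link among ``V(S)``: the coherent
    subnetwork keeps only coherent links.
    """

    def __init__(
        self,
        parent: SignedNetwork,
        genes: Iterable[Gene],
        link_keys: Iterable[LinkKey],
    ) -> None:
        self.parent = parent
        self.genes: Set[Gene] = set(genes)
        self.link_keys: Set[LinkKey] = set(link_keys)
        missing_genes = self.genes - parent.genes
        if missing_genes:
            raise ValueError(f"genes not in parent network: {sorted(map(repr, missing_genes))[:5]}")
        for key in self.link_keys:
            if key not in parent:
                raise ValueError(f"link {key} not in parent network")
            link = parent.get_link(key)
            if link.source not in self.genes or link.target not in self.genes:
                raise ValueError(f"link {key} has an endpoint outside the subnetwork genes")

    @property
    def links(self) -> List[SignedLink]:
        return [self.parent.get_link(k) for k in self.link_keys]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_links(self) -> int:
        return len(self.link_keys)

    def degree(self, gene: Gene) -> int:
        return sum(1 for k in self.link_keys if gene in k)

    def is_empty(self) -> bool:
        return not self.genes

    @classmethod
    def empty(cls, parent: SignedNetwork) -> "Subnetwork":
        return cls(parent, (), ())


@dataclass(frozen=True)
class BoundarySet:
    """Boundary of a subnetwork: incoherent internal links ``I`` plus
    crossing links ``B``; the boundary is their (disjoint) union."""

    incoherent_internal: frozenset  # of LinkKey
    crossing: frozenset  # of LinkKey

    @property
    def boundary(self) -> frozenset:
        return self.incoherent_internal | self.crossing

    @classmethod
    def empty(cls) -> "BoundarySet":
        return cls(frozenset(), frozenset())


# ---------------------------------------------------------------------------
# coherence operations


def _check_deltas(network: SignedNetwork, deltas: Mapping[Gene, float]) -> None:
    for gene in network.genes:
        if gene not in deltas:
            raise KeyError(f"no differential-expression estimate for gene {gene!r}")


def coherence_filter(network: SignedNetwork, deltas: Mapping[Gene, float]) -> Subnetwork:
    """Keep exactly the coherent links; drop genes left isolated.

    Every network gene must have an estimate in ``deltas`` (KeyError names
    the first missing gene otherwise).
    """
    _check_deltas(network, deltas)
    kept: Set[LinkKey] = set()
    genes: Set[Gene] = set()
    for key, link in ((l.key, l) for l in network.links):
        if is_coherent(deltas[link.source], deltas[link.target], link.weight):
            kept.add(key)
            genes.add(link.source)
            genes.add(link.target)
    return Subnetwork(network, genes, kept)


def boundary(
    network: SignedNetwork,
    sub: Subnetwork,
    deltas: Mapping[Gene, float],
) -> BoundarySet:
    """Boundary ``dS = I | B`` of ``sub`` within ``network``.

    ``I`` is the set of links of ``E(S)`` that are incoherent under
    ``deltas``; ``B`` is the set of links of ``E(G)`` with exactly one
    endpoint in ``V(S)``.
    """
    if sub.parent is not network:
        if not (sub.genes <= network.genes and sub.link_keys <= network.link_keys):
            raise ValueError("subnetwork is not contained in the given network")
    incoherent = frozenset(
        key
        for key in sub.link_keys
        if not is_coherent(
            deltas[network.get_link(key).source],
            deltas[network.get_link(key).target],
            network.get_link(key).weight,
        )
    )
    crossing = frozenset(
        link.key
        for link in network.links
        if (link.source in sub.genes) != (link.target in sub.genes)
    )
    return BoundarySet(incoherent, crossing)


def remove_isolated(sub: Subnetwork) -> Subnetwork:
    """Drop genes with degree 0 within the subnetwork (idempotent)."""
    linked: Set[Gene] = set()
    for key in sub.link_keys:
        link = sub.parent.get_link(key)
        linked.add(link.source)
        linked.add(link.target)
    return Subnetwork(sub.parent, sub.genes & linked, sub.link_keys)


def connected_components(sub: Subnetwork) -> List[Subnetwork]:
    """Maximal connected components of ``sub``, ignoring direction.

    Ordered by decreasing gene count, ties broken by the lexicographically
    smallest gene, so output order is deterministic.
    """
    g = nx.Graph()
    g.add_nodes_from(sub.genes)
    for key in sub.link_keys:
        link = sub.parent.get_link(key)
        g.add_edge(link.source, link.target)
    comps = []
    for nodes in nx.connected_components(g):
        keys = {
            k
            for k in sub.link_keys
            if sub.parent.get_link(k).source in nodes
        }
        comps.append(Subnetwork(sub.parent, nodes, keys))
    comps.sort(key=lambda c: (-c.n_genes, min(map(repr, c.genes))))
    return comps


# ---------------------------------------------------------------------------
# input / output


def read_network_tsv(
    path: Union[str, Path],
    directed: bool = False,
    fmt: Optional[str] = None,
) -> SignedNetwork:
    """Read a signed edge list.

    Two dialects are accepted: plain edge list (``source TAB target TAB
    relationship``) and SIF (``source TAB interaction TAB target``).  When
    ``fmt`` is None the dialect is detected from the first data row: if the
    middle column is a recognised relationship label the file is SIF.
    A header row ``source  target  relationship`` is skipped if present.
    """
    path = Path(path)
    rows: List[List[str]] = []
    with path.open() as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: expected 3 tab-separated columns, got {line!r}")
            rows.append([p.strip() for p in parts[:3]])
    if rows and rows[0][0].lower() == "source":
        rows = rows[1:]
    if not rows:
        return SignedNetwork(directed=directed)
    if fmt is None:
        middle_is_rel = rows[0][1].lower() in _RELATIONSHIP_ALIASES
        third_is_rel = rows[0][2].lower() in _RELATIONSHIP_ALIASES
        fmt = "sif" if (middle_is_rel and not third_is_rel) else "edgelist"
    links = []
    for row in rows:
        if fmt == "sif":
            src, rel, tgt = row
        else:
            src, tgt, rel = row
        links.append(SignedLink(src, tgt, parse_relationship(rel), directed))
    return SignedNetwork(links, directed=directed)


def write_network_tsv(network: Union[SignedNetwork, Subnetwork], path: Union[str, Path]) -> None:
    """Write an edge list TSV (``source  target  relationship``)."""
    links = network.links
    with Path(path).open("w") as fh:
        fh.write("source\ttarget\trelationship\n")
        for link in sorted(links, key=lambda l: repr(l.key)):
            rel = "inhibit" if link.relationship is Relationship.INHIBITING else "induce"
            fh.write(f"{link.source}\t{link.target}\t{rel}\n")


def write_graphml(
    sub: Subnetwork,
    deltas: Mapping[Gene, float],
    path: Union[str, Path],
) -> None:
    """Write a subnetwork to GraphML.

    Nodes carry ``delta_sign`` in {"up", "down"}; edges carry
    ``relationship`` in {"inhibiting", "non_inhibiting"} — the standard
    up/down + inducing/inhibiting rendering of coherent subnetworks.
    """
    g: Union[nx.DiGraph, nx.Graph]
    g = nx.DiGraph() if sub.parent.directed else nx.Graph()
    for gene in sub.genes:
        sign = "up" if deltas.get(gene, 0.0) > 0 else "down"
        g.add_node(str(gene), delta_sign=sign)
    for link in sub.links:
        g.add_edge(str(link.source), str(link.target), relationship=link.relationship.value)
    nx.write_graphml(g, str(path))
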