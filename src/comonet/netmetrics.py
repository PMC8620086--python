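"""Condition-network extraction and per-node metrics.

A *condition network* is the subgraph induced by all genes linked to a
disease or phenotype node in the knowledge base, together with the
interactions among those genes.  Three per-node quantities drive the
downstream hub analysis:

``K_i``
    within-network link count — every parallel typed link incident to gene
    *i* whose other endpoint is inside the network, plus the gene–condition
    links themselves.
``B_i``
    betweenness centrality on the undirected simple projection of the
    gene–gene graph (condition node excluded), unnormalized, unordered node
    pairs counted once, shortest-path credit split equally among ties.
``CTS_i = K_i / M_i``
    cross-talk specificity, where ``M_i`` is the gene's global link count in
    the whole knowledge base.  CTS close to 1 marks genes whose literature
    links are specific to the analyzed condition; promiscuous global hubs
    score low even when their within-network connectivity is high.

Whether a literature tool's "connectivity" counts parallel typed links or
distinct neighbors is generally undocumented, so both are computed: ``K``
counts parallel links, ``neighbor_degree`` counts distinct gene neighbors.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import pandas as pd

from .kb import GENE_LIKE_TYPES, KnowledgeBase

__all__ = [
    "ConditionNetwork",
    "NodeMetrics",
    "ConditionLookupError",
    "extract_condition_network",
    "betweenness_centrality",
    "cross_talk_specificity",
    "compute_node_metrics",
    "rank_nodes",
    "metrics_table",
]


class ConditionLookupError(KeyError):
    """The requested condition id is absent or not a condition entity."""


@dataclass
class ConditionNetwork:
    """Genes linked to one condition plus the interactions among them."""

    condition_id: str
    members: set[str]
    gene_gene_edges: set[tuple[str, str]]
    gene_condition_links: dict[str, int]
    link_multiplicity: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        """True when the condition has no linked genes (warning, not error)."""
        return not self.members

    def gene_set(self) -> frozenset[str]:
        return frozenset(self.members)

    def neighbors(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {g: set() for g in self.members}
        for a, b in self.gene_gene_edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj


@dataclass(frozen=True)
class NodeMetrics:
    """Per-gene metrics within one condition network."""

    K: int
    neighbor_degree: int
    betweenness: float
    M: int
    cts: float


def extract_condition_network(kb: KnowledgeBase, condition_id: str) -> ConditionNetwork:
    """Induce the network of genes linked to ``condition_id``.

    Members are exactly the gene-like entities with at least one interaction
    to the condition (either direction).  Gene–gene edges are the undirected
    simple pairs among members; parallel-link counts are kept separately in
    ``link_multiplicity``.  Self-loops never enter the edge set.

    Raises
    ------
    ConditionLookupError
        If the id is unknown or not a condition entity.
    """
    entity = kb.entities.get(condition_id)
    if entity is None or entity.etype != "condition":
        raise ConditionLookupError(
            f"{condition_id!r} is not a condition entity in this knowledge base"
        )

    gene_condition_links: dict[str, int] = {}
    for link in kb.incident(condition_id):
        other = link.target if link.source == condition_id else link.source
        if kb.entities[other].etype in GENE_LIKE_TYPES:
            gene_condition_links[other] = gene_condition_links.get(other, 0) + 1
    members = set(gene_condition_links)

    edges: set[tuple[str, str]] = set()
    multiplicity: dict[tuple[str, str], int] = {}
    for i in kb.interactions:
        if i.is_self_loop:
            continue
        if i.source in members and i.target in members:
            pair = tuple(sorted((i.source, i.target)))
            edges.add(pair)  # type: ignore[arg-type]
            multiplicity[pair] = multiplicity.get(pair, 0) + 1  # type: ignore[index]

    return ConditionNetwork(
        condition_id=condition_id,
        members=members,
        gene_gene_edges=edges,
        gene_condition_links=gene_condition_links,
        link_multiplicity=multiplicity,
    )


def _brandes(adj: dict[str, set[str]]) -> dict[str, float]:
    # Brandes' accumulation; unweighted BFS variant.  Ordered source loop
    # double-counts unordered pairs on an undirected graph, halved at the end.
    bc = dict.fromkeys(adj, 0.0)
    for s in adj:
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in adj}
        sigma = dict.fromkeys(adj, 0)
        dist = dict.fromkeys(adj, -1)
        sigma[s] = 1
        dist[s] = 0
        queue: deque[str] = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = dict.fromkeys(adj, 0.0)
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return {v: b / 2.0 for v, b in bc.items()}


def betweenness_centrality(net: ConditionNetwork) -> dict[str, float]:
    """Unnormalized betweenness on the simple gene–gene graph.

    Unordered pairs counted once; pairs in different components contribute
    nothing; degree-0 and degree-1 nodes score exactly 0.
    """
    return _brandes(net.neighbors())


def cross_talk_specificity(
    net: ConditionNetwork, kb: KnowledgeBase
) -> dict[str, tuple[int, int, float]]:
    """Per-member (K_i, M_i, CTS_i).

    ``K_i`` counts every parallel link of gene *i* whose other endpoint is a
    network member or the condition itself; ``M_i`` counts all links of *i*
    in the knowledge base (self-loops excluded from both).  A member always
    has at least the condition link, so ``M_i`` is at least 1.
    """
    inside = net.members | {net.condition_id}
    out: dict[str, tuple[int, int, float]] = {}
    for gene in net.members:
        links = kb.incident(gene)
        m = len(links)
        if m == 0:
            raise RuntimeError(
                f"internal inconsistency: member {gene!r} has no links in the "
                "knowledge base, yet membership requires a condition link"
            )
        k = sum(
            1
            for link in links
            if (link.target if link.source == gene else link.source) in inside
        )
        out[gene] = (k, m, k / m)
    return out


def compute_node_metrics(net: ConditionNetwork, kb: KnowledgeBase) -> dict[str, NodeMetrics]:
    """Assemble K, neighbor_degree, betweenness, M and CTS for every member."""
    bc = betweenness_centrality(net)
    cts = cross_talk_specificity(net, kb)
    adj = net.neighbors()
    return {
        g: NodeMetrics(
            K=cts[g][0],
            neighbor_degree=len(adj[g]),
            betweenness=bc[g],
            M=cts[g][1],
            cts=cts[g][2],
        )
        for g in net.members
    }


_RANK_KEYS = {
    "K": lambda m: m.K,
    "B": lambda m: m.betweenness,
    "CTS": lambda m: m.cts,
}


def rank_nodes(metrics: dict[str, NodeMetrics], key: str, n: int) -> list[str]:
    """Top ``n`` genes by ``key`` in {"K", "B", "CTS"}, descending.

    Ties break lexicographically by symbol; returns min(n, #nodes) entries.
    """
    if key not in _RANK_KEYS:
        raise ValueError(f"unknown ranking key {key!r}; expected one of K, B, CTS")
    if not metrics:
        raise ValueError("rank_nodes needs a non-empty metrics map")
    if n < 1:
        raise ValueError("n must be >= 1")
    getter = _RANK_KEYS[key]
    ordered = sorted(metrics, key=lambda g: (-getter(metrics[g]), g))
    return ordered[:n]


def metrics_table(metrics: dict[str, NodeMetrics]) -> pd.DataFrame:
    """Metrics as a DataFrame sorted by CTS descending (symbol breaks ties)."""
    df = pd.DataFrame(
        [
            {
                "gene": g,
                "K": m.K,
                "neighbor_degree": m.neighbor_degree,
                "betweenness": m.betweenness,
                "M": m.M,
                "CTS": m.cts,
            }
            for g, m in metrics.items()
        ],
        columns=["gene", "K", "neighbor_degree", "betweenness", "M", "CTS"],
    )
    return df.sort_values(["CTS", "gene"], ascending=[False, True]).reset_index(drop=True)
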