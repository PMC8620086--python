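"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from collections import Counter

import pytest

from comonet.kb import Entity, Interaction, KnowledgeBase


def build_kb(
    gene_edges=(),
    condition_links=(),
    genes=(),
    rtype="PPI",
):
    """Assemble a small knowledge base from terse edge descriptions.

    ``gene_edges``: iterable of (a, b) or (a, b, rtype) gene pairs.
    ``condition_links``: iterable of (condition, gene, rtype, direction)
    with direction "to_gene" (condition→gene) or "to_condition".
    """
    kb = KnowledgeBase()
    for g in genes:
        kb.add_entity(Entity(g, g, "gene"))
    for edge in gene_edges:
        a, b, *rest = edge
        for g in (a, b):
            if g not in kb:
                kb.add_entity(Entity(g, g, "gene"))
        kb.add_interaction(Interaction(a, b, rest[0] if rest else rtype))
    for cond, gene, r, direction in condition_links:
        if cond not in kb:
            kb.add_entity(Entity(cond, cond, "condition"))
        if gene not in kb:
            kb.add_entity(Entity(gene, gene, "gene"))
        if direction == "to_gene":
            kb.add_interaction(Interaction(cond, gene, r))
        else:
            kb.add_interaction(Interaction(gene, cond, r))
    return kb


def bfs_betweenness_oracle(adj):
    """Brute-force betweenness: enumerate every shortest path per node pair.

    Independent of the production algorithm: BFS layering plus explicit
    path enumeration, crediting each interior node 1/#paths per pair.
    """
    from collections import deque

    nodes = sorted(adj)
    bc = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        dist = {s: 0}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
        if t not in dist:
            continue
        paths = []
        stack = [[t]]
        while stack:
            path = stack.pop()
            head = path[-1]
            if head == s:
                paths.append(path)
                continue
            for w in adj[head]:
                if dist.get(w, -1) == dist[head] - 1:
                    stack.append(path + [w])
        for path in paths:
            for interior in path[1:-1]:
                bc[interior] += 1.0 / len(paths)
    return bc


def hypergeom_tail_oracle(k, K, n, N):
    """Exhaustive-draw tail P(X >= k): count all C(N, n) subsets directly."""
    marked = set(range(K))
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def hypergeom_counts_oracle(K, n, N):
    """Overlap-count distribution over all C(N, n) draws with K marked."""
    marked = set(range(K))
    return Counter(
        len(marked.intersection(draw)) for draw in itertools.combinations(range(N), n)
    )


@pytest.fixture
def path_kb():
    """Condition c linked to g1, g2; chain g1–g2–g3 in the global graph."""
    return build_kb(
        gene_edges=[("g1", "g2"), ("g2", "g3")],
        condition_links=[
            ("c", "g1", "ASSOCIATION", "to_condition"),
            ("c", "g2", "ASSOCIATION", "to_condition"),
        ],
    )
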