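"""Seeded generator of literature-style knowledge bases with planted truth.

Every analysis stage in this package is validated against synthetic
knowledge bases whose relevant structure is known by construction:

* a heavy-tailed global gene–gene graph grown by preferential attachment
  (each new gene attaches ``m`` edges to existing genes with probability
  proportional to current degree), with typed directed multi-edges sampled
  from a relation-type mixture;
* condition modules of configured sizes with a planted core shared by all
  conditions and planted pairwise overlaps, the remaining members drawn
  without replacement with probability proportional to (degree + 1) — the
  hub bias of literature curation that cross-talk specificity exists to
  counteract;
* gene–condition links typed according to a link-class mixture, so the
  rule-based classifier has planted ground truth;
* flat annotation terms with one planted enriched term per condition.

The default parameters are the study conditions this package models: five
disease modules of sizes 141, 494, 424, 685 and 130 genes (hypoglycemia,
cardiovascular disease, diabetic retinopathy, nephropathy and neuropathy), a
14-gene core mutual to all five, pairwise overlaps with the focus module of
47, 50, 62 and 22 genes, and a link-class mixture matching the curated class
frequencies of the focus condition.

All discrete draws go through integer arithmetic on a PCG64 generator
(``rng.integers``), so a seed reproduces the same bundle on any platform —
no floating-point RNG enters any discrete choice.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .kb import Entity, GeneSet, Interaction, KnowledgeBase, write_gmt, write_kb

__all__ = [
    "DEFAULT_CONDITIONS",
    "DEFAULT_RELATION_WEIGHTS",
    "DEFAULT_CLASS_WEIGHTS",
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_global_network",
    "plant_conditions",
    "plant_condition_links",
    "plant_annotations",
    "generate_bundle",
    "write_bundle",
]

DEFAULT_CONDITIONS = (
    "hypoglycemia",
    "cardiovascular_disease",
    "diabetic_retinopathy",
    "diabetic_nephropathy",
    "diabetic_neuropathy",
)

#: Gene–gene relation mixture for the global graph.
DEFAULT_RELATION_WEIGHTS: dict[str, float] = {
    "ASSOCIATION": 0.40,
    "PPI": 0.30,
    "UPREGULATES": 0.15,
    "DOWNREGULATES": 0.15,
}

#: Gene–condition link-class mixture; defaults to the curated class
#: frequencies of the focus condition (43:17:16:22:34:19).
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "UP": 43 / 151,
    "DOWN": 17 / 151,
    "CAUSAL": 16 / 151,
    "PROTECTIVE": 22 / 151,
    "SNP_RISK": 34 / 151,
    "OTHER": 19 / 151,
}

#: How each planted link class materializes as a typed edge.  Direction is
#: relative to the condition node; the classifier's default rulemap inverts
#: this map exactly, which is what makes class recovery a round trip.
_CLASS_EDGE: dict[str, tuple[str, str]] = {
    "UP": ("UPREGULATES", "to_gene"),
    "DOWN": ("DOWNREGULATES", "to_gene"),
    "CAUSAL": ("CAUSES", "to_condition"),
    "PROTECTIVE": ("PROTECTS_AGAINST", "to_condition"),
    "SNP_RISK": ("SNP_RISK", "to_condition"),
    "OTHER": ("ASSOCIATION", "to_condition"),
}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic bundle (see module docstring for defaults)."""

    n_genes: int = 3000
    m: int = 3
    condition_names: tuple[str, ...] = DEFAULT_CONDITIONS
    module_sizes: tuple[int, ...] = (141, 494, 424, 685, 130)
    planted_core_size: int = 14
    planted_pairwise_overlaps: dict[tuple[int, int], int] = field(
        default_factory=lambda: {(0, 1): 47, (0, 2): 50, (0, 3): 62, (0, 4): 22}
    )
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 40)
    planted_term_fraction: float = 0.8
    relation_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RELATION_WEIGHTS)
    )
    class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= self.m or self.m < 1:
            raise ValueError(f"need n_genes > m >= 1 (n_genes={self.n_genes}, m={self.m})")
        if len(self.condition_names) != len(self.module_sizes):
            raise ValueError("one module size per condition name is required")
        if any(s > self.n_genes for s in self.module_sizes):
            raise ValueError("module sizes cannot exceed n_genes")
        if self.module_sizes and self.planted_core_size > min(self.module_sizes):
            raise ValueError("planted core cannot exceed the smallest module")
        if not 0.0 < self.planted_term_fraction <= 1.0:
            raise ValueError(
                f"planted_term_fraction must be in (0, 1], got {self.planted_term_fraction}"
            )
        for weights, what in ((self.relation_weights, "relation"), (self.class_weights, "class")):
            total = sum(weights.values())
            if not math.isclose(total, 1.0, rel_tol=1e-9):
                raise ValueError(f"{what} weights must sum to 1 (got {total})")
        for (i, j), o in self.planted_pairwise_overlaps.items():
            if i == j or not (0 <= i < len(self.module_sizes)) or not (
                0 <= j < len(self.module_sizes)
            ):
                raise ValueError(f"bad overlap pair ({i}, {j})")
            if o < self.planted_core_size:
                raise ValueError(
                    f"overlap {o} of pair ({i}, {j}) smaller than the core "
                    f"({self.planted_core_size}) every module shares"
                )


@dataclass
class SyntheticTruth:
    """Ground truth recorded while a bundle is generated."""

    spec: SyntheticSpec
    modules: dict[str, frozenset[str]] = field(default_factory=dict)
    core: frozenset[str] = frozenset()
    pairwise_overlaps: dict[tuple[str, str], int] = field(default_factory=dict)
    class_assignment: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)
    planted_terms: dict[str, str] = field(default_factory=dict)
    term_genes: dict[str, frozenset[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "spec": {
                **{k: v for k, v in asdict(self.spec).items() if k != "planted_pairwise_overlaps"},
                "planted_pairwise_overlaps": {
                    f"{i},{j}": o for (i, j), o in self.spec.planted_pairwise_overlaps.items()
                },
            },
            "modules": {c: sorted(g) for c, g in self.modules.items()},
            "core": sorted(self.core),
            "pairwise_overlaps": {f"{a}|{b}": o for (a, b), o in self.pairwise_overlaps.items()},
            "class_assignment": {
                c: {g: sorted(cls) for g, cls in sorted(assign.items())}
                for c, assign in self.class_assignment.items()
            },
            "planted_terms": dict(self.planted_terms),
            "term_genes": {t: sorted(g) for t, g in self.term_genes.items()},
        }
        return json.dumps(payload, indent=1, sort_keys=True)


# -- integer-arithmetic sampling primitives --------------------------------

_WEIGHT_SCALE = 1_000_000


def _int_weights(weights: Mapping[str, float]) -> tuple[list[str], list[int]]:
    labels = sorted(weights)
    ints = [max(1, round(weights[l] * _WEIGHT_SCALE)) for l in labels]
    return labels, ints


def _weighted_choice(rng: np.random.Generator, cumulative: list[int]) -> int:
    r = int(rng.integers(0, cumulative[-1]))
    lo, hi = 0, len(cumulative) - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if r < cumulative[mid]:
            hi = mid
        else:
            lo = mid + 1
    return lo


def _sample_weighted_without_replacement(
    rng: np.random.Generator,
    pool: list[str],
    weight_of: Callable[[str], int],
    k: int,
) -> list[str]:
    if k > len(pool):
        raise ValueError(f"cannot draw {k} distinct genes from a pool of {len(pool)}")
    pool = list(pool)
    weights = [weight_of(g) for g in pool]
    chosen: list[str] = []
    for _ in range(k):
        total = sum(weights)
        r = int(rng.integers(0, total))
        acc = 0
        for i, w in enumerate(weights):
            acc += w
            if r < acc:
                break
        chosen.append(pool.pop(i))
        weights.pop(i)
    return chosen


# -- generation stages -----------------------------------------------------

def generate_global_network(
    n_genes: int,
    m: int,
    seed: int,
    relation_weights: Mapping[str, float] | None = None,
) -> KnowledgeBase:
    """Grow a typed preferential-attachment gene network.

    Node ``i`` (for i >= 1) attaches ``min(m, i)`` edges to distinct earlier
    nodes chosen proportionally to current degree; relation types come from
    the mixture.  Deterministic for a fixed seed.
    """
    if n_genes <= m or m < 1:
        raise ValueError(f"need n_genes > m >= 1 (n_genes={n_genes}, m={m})")
    weights = dict(DEFAULT_RELATION_WEIGHTS) if relation_weights is None else dict(relation_weights)
    labels, ints = _int_weights(weights)
    cumulative = list(np.cumsum(ints))
    rng = np.random.default_rng(seed)

    width = len(str(n_genes - 1))
    names = [f"G{i:0{width}d}" for i in range(n_genes)]
    kb = KnowledgeBase()
    for name in names:
        kb.add_entity(Entity(name, name, "gene"))

    # classic repeated-endpoints urn: picking a uniform index is picking a
    # node with probability proportional to its degree
    repeated: list[int] = [0]
    for i in range(1, n_genes):
        k = min(m, i)
        targets: set[int] = set()
        while len(targets) < k:
            targets.add(repeated[int(rng.integers(0, len(repeated)))])
        for t in sorted(targets):
            rtype = labels[_weighted_choice(rng, cumulative)]
            kb.add_interaction(Interaction(names[i], names[t], rtype))
            repeated.append(t)
        repeated.extend([i] * k)
    return kb


def plant_condition_links(
    kb: KnowledgeBase,
    condition_id: str,
    assignment: Mapping[str, Sequence[str] | frozenset[str]],
) -> None:
    """Materialize a (possibly multi-label) class assignment as typed edges.

    Inverse of the default classifier rulemap: classifying the resulting
    knowledge base recovers ``assignment`` exactly.
    """
    if condition_id not in kb.entities:
        kb.add_entity(Entity(condition_id, condition_id, "condition"))
    for gene in sorted(assignment):
        for label in sorted(assignment[gene]):
            rtype, direction = _CLASS_EDGE[label]
            if direction == "to_gene":
                kb.add_interaction(Interaction(condition_id, gene, rtype))
            else:
                kb.add_interaction(Interaction(gene, condition_id, rtype))


def plant_conditions(
    kb: KnowledgeBase, spec: SyntheticSpec, seed: int
) -> tuple[KnowledgeBase, SyntheticTruth]:
    """Plant condition modules with a common core and exact pairwise overlaps.

    Core genes are drawn first and linked to every condition.  Each declared
    pairwise overlap beyond the core is drawn as genes shared by exactly that
    pair; remaining members are unique to their module, so every pairwise
    intersection equals core + declared extra by construction.  All draws are
    without replacement with weight (degree + 1), emulating hub bias.
    """
    rng = np.random.default_rng(seed)
    degree = {g: kb.degree(g) for g in kb.gene_ids()}
    weight_of = lambda g: degree[g] + 1  # noqa: E731
    pool = sorted(degree)

    names = spec.condition_names
    sizes = spec.module_sizes
    extras = {
        (i, j): o - spec.planted_core_size
        for (i, j), o in spec.planted_pairwise_overlaps.items()
    }
    budget = [s - spec.planted_core_size for s in sizes]
    for (i, j), extra in extras.items():
        budget[i] -= extra
        budget[j] -= extra
    if any(b < 0 for b in budget):
        raise ValueError(
            "infeasible module sizes: core plus declared pairwise extras "
            f"exceed a module (remaining budgets {budget})"
        )

    truth = SyntheticTruth(spec=spec)
    modules: dict[str, set[str]] = {c: set() for c in names}

    core = _sample_weighted_without_replacement(rng, pool, weight_of, spec.planted_core_size)
    taken = set(core)
    for c in names:
        modules[c].update(core)
    for (i, j) in sorted(extras):
        shared = _sample_weighted_without_replacement(
            rng, [g for g in pool if g not in taken], weight_of, extras[(i, j)]
        )
        taken.update(shared)
        modules[names[i]].update(shared)
        modules[names[j]].update(shared)
    for idx, c in enumerate(names):
        unique = _sample_weighted_without_replacement(
            rng, [g for g in pool if g not in taken], weight_of, budget[idx]
        )
        taken.update(unique)
        modules[c].update(unique)

    class_labels, class_ints = _int_weights(spec.class_weights)
    class_cumulative = list(np.cumsum(class_ints))
    for c in names:
        assignment = {
            g: frozenset({class_labels[_weighted_choice(rng, class_cumulative)]})
            for g in sorted(modules[c])
        }
        plant_condition_links(kb, c, assignment)
        truth.class_assignment[c] = assignment
        truth.modules[c] = frozenset(modules[c])
    truth.core = frozenset(core)
    for (i, j), o in spec.planted_pairwise_overlaps.items():
        truth.pairwise_overlaps[(names[i], names[j])] = o
    return kb, truth


def plant_annotations(
    kb: KnowledgeBase, spec: SyntheticSpec, seed: int, truth: SyntheticTruth
) -> dict[str, GeneSet]:
    """Generate flat annotation terms with one planted term per condition.

    Background terms draw uniform-size random gene subsets; each condition's
    planted term contains ``planted_term_fraction`` of its module, padded by
    a quarter as many off-module genes so the term is not the module itself.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(kb.gene_ids())
    lo, hi = spec.term_size_range
    annotation: dict[str, GeneSet] = {}
    for t in range(spec.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = _sample_weighted_without_replacement(rng, genes, lambda g: 1, size)
        name = f"TERM{t:04d}"
        annotation[name] = GeneSet(name, frozenset(members))
    for c in truth.modules:
        module = sorted(truth.modules[c])
        n_in = max(1, round(spec.planted_term_fraction * len(module)))
        inside = _sample_weighted_without_replacement(rng, module, lambda g: 1, n_in)
        off_module = [g for g in genes if g not in truth.modules[c]]
        n_pad = min(len(off_module), max(1, n_in // 4))
        pad = _sample_weighted_without_replacement(rng, off_module, lambda g: 1, n_pad)
        name = f"PLANTED_{c.upper()}"
        annotation[name] = GeneSet(name, frozenset(inside) | frozenset(pad))
        truth.planted_terms[c] = name
    truth.term_genes = {t: gs.genes for t, gs in annotation.items()}
    return annotation


def generate_bundle(
    spec: SyntheticSpec,
) -> tuple[KnowledgeBase, dict[str, GeneSet], SyntheticTruth]:
    """Run all three stages off one spec seed; child stages get derived seeds."""
    kb = generate_global_network(spec.n_genes, spec.m, spec.seed, spec.relation_weights)
    kb, truth = plant_conditions(kb, spec, spec.seed + 1)
    annotation = plant_annotations(kb, spec, spec.seed + 2, truth)
    return kb, annotation, truth


def write_bundle(
    spec: SyntheticSpec, outdir: str | Path
) -> tuple[KnowledgeBase, dict[str, GeneSet], SyntheticTruth]:
    """Generate a bundle and emit the TSV/GMT/JSON files of the KB dialect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kb, annotation, truth = generate_bundle(spec)
    write_kb(kb, outdir / "nodes.tsv", outdir / "edges.tsv")
    write_gmt(
        [GeneSet(c, truth.modules[c]) for c in truth.modules],
        outdir / "modules.gmt",
    )
    with open(outdir / "annotation.tsv", "w", encoding="utf-8") as fh:
        fh.write("term_id\tterm_name\tgene\n")
        for term in sorted(annotation):
            for gene in sorted(annotation[term].genes):
                fh.write(f"{term}\t{term}\t{gene}\n")
    (outdir / "truth.json").write_text(truth.to_json(), encoding="utf-8")
    return kb, annotation, truth
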