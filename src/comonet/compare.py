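"""Multi-way comparison of condition gene networks.

Given the gene sets of several condition networks, this module computes the
pairwise overlap-significance matrix against a focus condition, the exact
n-way Venn partition (2–6 sets), the mutual core shared by all networks, and
the annotation terms enriched simultaneously in every condition.

Venn regions are keyed by membership bitmask strings over the declared set
order — ``"10110"`` holds the genes in sets 1, 3 and 4 of five and no other —
which serializes any diagram up to six ways without drawing it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .enrich import EnrichmentResult, overlap_overrepresentation
from .kb import GeneSet

__all__ = [
    "VennPartition",
    "OverlapMatrix",
    "venn_partition",
    "mutual_genes",
    "shared_enriched_terms",
    "overlap_matrix",
    "venn_figure",
]


@dataclass(frozen=True)
class VennPartition:
    """Disjoint decomposition of a union of 2–6 named gene sets."""

    set_names: tuple[str, ...]
    regions: Mapping[str, frozenset[str]]

    def region(self, names: Sequence[str]) -> frozenset[str]:
        """Genes belonging to exactly the given sets and no others."""
        wanted = set(names)
        unknown = wanted - set(self.set_names)
        if unknown:
            raise KeyError(f"unknown set names {sorted(unknown)}")
        mask = "".join("1" if s in wanted else "0" for s in self.set_names)
        return self.regions.get(mask, frozenset())

    @property
    def core(self) -> frozenset[str]:
        """The all-membership region (genes present in every set)."""
        return self.regions.get("1" * len(self.set_names), frozenset())

    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.regions.values():
            out |= genes
        return frozenset(out)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"bitmask": mask, "size": len(genes), "genes": ";".join(sorted(genes))}
            for mask, genes in sorted(self.regions.items())
        ]
        return pd.DataFrame(rows, columns=["bitmask", "size", "genes"])


@dataclass(frozen=True)
class OverlapMatrix:
    """Overlap enrichment of one focus gene set against several comparators."""

    focus_name: str
    cells: Mapping[str, EnrichmentResult]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "comparator": name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "log10_p": r.log10_p,
                "p_raw": r.p_raw,
                "genes": ";".join(sorted(r.genes)),
            }
            for name, r in self.cells.items()
        ]
        return pd.DataFrame(
            rows, columns=["comparator", "k", "K", "n", "N", "log10_p", "p_raw", "genes"]
        )


def venn_partition(sets: Sequence[GeneSet]) -> VennPartition:
    """Partition the union of 2–6 named sets into disjoint bitmask regions.

    Every gene of the union lands in exactly one region; the bitmask's i-th
    character is "1" iff the gene belongs to the i-th declared set.
    """
    if not 2 <= len(sets) <= 6:
        raise ValueError(f"venn_partition takes 2 to 6 sets, got {len(sets)}")
    names = tuple(s.name for s in sets)
    if len(set(names)) != len(names):
        raise ValueError(f"set names must be unique, got {names}")
    regions: dict[str, set[str]] = {}
    union: set[str] = set()
    for s in sets:
        union |= s.genes
    for gene in union:
        mask = "".join("1" if gene in s.genes else "0" for s in sets)
        regions.setdefault(mask, set()).add(gene)
    return VennPartition(names, {m: frozenset(g) for m, g in regions.items()})


def mutual_genes(sets: Sequence[GeneSet]) -> frozenset[str]:
    """Intersection of all sets (equals the all-ones Venn region)."""
    if len(sets) < 2:
        raise ValueError("mutual_genes needs at least 2 sets")
    out = set(sets[0].genes)
    for s in sets[1:]:
        out &= s.genes
    return frozenset(out)


def shared_enriched_terms(
    per_condition_results: Sequence[Sequence[EnrichmentResult]],
    alpha: float = 0.01,
) -> list[str]:
    """Terms significantly enriched (corrected p < alpha) in *every* condition.

    Sorted by the worst (maximum) corrected p across conditions, ascending;
    label breaks ties.
    """
    if not per_condition_results:
        raise ValueError("shared_enriched_terms needs at least one result list")
    shared: dict[str, float] | None = None
    for results in per_condition_results:
        here = {r.label: r.p_corrected for r in results if r.p_corrected < alpha}
        if shared is None:
            shared = here
        else:
            shared = {
                t: max(p, here[t]) for t, p in shared.items() if t in here
            }
    assert shared is not None
    return sorted(shared, key=lambda t: (shared[t], t))


def overlap_matrix(
    focus: GeneSet,
    comparators: Sequence[GeneSet],
    N: int,
    alpha: float = 0.01,
) -> OverlapMatrix:
    """One overlap-overrepresentation cell per comparator, query = focus."""
    cells = {
        comp.name: overlap_overrepresentation(focus, comp, N, alpha=alpha)
        for comp in comparators
    }
    return OverlapMatrix(focus.name, cells)


def venn_figure(partition: VennPartition, path: str) -> None:
    """Draw a 2–3 set Venn diagram with region counts (presentation only).

    Pure matplotlib circles; raises for more than three sets, for which the
    TSV partition table is the supported output.
    """
    n = len(partition.set_names)
    if n > 3:
        raise ValueError("figure export supports at most 3 sets; use the TSV table")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    centers2 = [(-0.5, 0.0), (0.5, 0.0)]
    centers3 = [(-0.5, -0.3), (0.5, -0.3), (0.0, 0.6)]
    centers = centers2 if n == 2 else centers3
    fig, ax = plt.subplots(figsize=(5, 5))
    for (x, y), name in zip(centers, partition.set_names):
        ax.add_patch(Circle((x, y), 1.0, alpha=0.25))
        ax.annotate(name, (x, y + 1.05), ha="center")
    # place each region count at the mean of its member circles
    for mask, genes in sorted(partition.regions.items()):
        members = [centers[i] for i, bit in enumerate(mask) if bit == "1"]
        x = sum(m[0] for m in members) / len(members)
        y = sum(m[1] for m in members) / len(members)
        ax.annotate(str(len(genes)), (x, y), ha="center", va="center")
    ax.set_xlim(-2, 2)
    ax.set_ylim(-2, 2)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
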