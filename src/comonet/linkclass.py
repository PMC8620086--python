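"""Rule-based classification of gene–condition link patterns.

Curated disease networks describe *how* each gene relates to the condition:
its expression may go up or down under the condition, its product may cause
or protect against it, or variants in it may modulate risk.  This module
mechanizes that curation as a declarative rulemap from (relation type,
direction relative to the condition) to one of six classes:

    UP          gene expression up-regulated by the condition
    DOWN        gene expression down-regulated by the condition
    CAUSAL      gene product can induce the condition
    PROTECTIVE  protective effect against / counterregulatory response
    SNP_RISK    variants associated with condition risk
    OTHER       any remaining association (fallback, exclusive)

Classification is multi-label: a gene reported both up- and down-regulated
carries both classes.  OTHER is assigned exactly to genes for which no rule
fires on any of their condition links.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .kb import GENE_LIKE_TYPES, GeneSet, KnowledgeBase, SchemaError
from .netmetrics import ConditionLookupError

__all__ = [
    "LINK_CLASSES",
    "DEFAULT_RULEMAP",
    "LinkClassification",
    "CrossTable",
    "read_rulemap",
    "classify_condition_links",
    "class_counts",
    "cross_classification",
]

logger = logging.getLogger(__name__)

#: The six link-pattern classes, in reporting order.
LINK_CLASSES = ("UP", "DOWN", "CAUSAL", "PROTECTIVE", "SNP_RISK", "OTHER")

#: Direction is relative to the condition: "to_gene" means the condition is
#: the source of the edge, "to_condition" means the gene is.
DEFAULT_RULEMAP: dict[tuple[str, str], str] = {
    ("UPREGULATES", "to_gene"): "UP",
    ("DOWNREGULATES", "to_gene"): "DOWN",
    ("CAUSES", "to_condition"): "CAUSAL",
    ("PROTECTS_AGAINST", "to_condition"): "PROTECTIVE",
    ("SNP_RISK", "to_condition"): "SNP_RISK",
}


@dataclass(frozen=True)
class LinkClassification:
    """Multi-label class assignment for every gene linked to one condition."""

    condition_id: str
    assignment: Mapping[str, frozenset[str]]

    @classmethod
    def from_class_sets(
        cls, condition_id: str, class_sets: Mapping[str, GeneSet]
    ) -> "LinkClassification":
        """Build an assignment from per-class gene sets (e.g. a curated table)."""
        unknown = set(class_sets) - set(LINK_CLASSES)
        if unknown:
            raise ValueError(f"unknown link classes {sorted(unknown)}")
        assignment: dict[str, set[str]] = {}
        for label, gs in class_sets.items():
            for gene in gs.genes:
                assignment.setdefault(gene, set()).add(label)
        return cls(condition_id, {g: frozenset(c) for g, c in assignment.items()})

    def genes_in_class(self, label: str) -> frozenset[str]:
        if label not in LINK_CLASSES:
            raise ValueError(f"unknown link class {label!r}")
        return frozenset(g for g, cs in self.assignment.items() if label in cs)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "classes": ",".join(sorted(cs))}
            for g, cs in sorted(self.assignment.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "classes"])


@dataclass(frozen=True)
class CrossTable:
    """Class-by-class contingency of genes shared by two conditions.

    Cell (i, j) holds the genes carrying class i for condition A and class j
    for condition B; multi-label genes appear in several cells.
    """

    condition_a: str
    condition_b: str
    cells: Mapping[tuple[str, str], frozenset[str]]

    def cell(self, row: str, col: str) -> frozenset[str]:
        return self.cells.get((row, col), frozenset())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "row_class": r,
                "col_class": c,
                "n": len(self.cells.get((r, c), frozenset())),
                "genes": ";".join(sorted(self.cells.get((r, c), frozenset()))),
            }
            for r in LINK_CLASSES
            for c in LINK_CLASSES
        ]
        return pd.DataFrame(rows, columns=["row_class", "col_class", "n", "genes"])


def read_rulemap(path: str | Path) -> dict[tuple[str, str], str]:
    """Read a rulemap TSV with columns (rtype, direction, class)."""
    rules: dict[tuple[str, str], str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        need = {"rtype", "direction", "class"}
        if reader.fieldnames is None or not need <= set(reader.fieldnames):
            raise SchemaError(f"{path}: rulemap needs columns (rtype, direction, class)")
        for lineno, row in enumerate(reader, start=2):
            direction = row["direction"].strip()
            label = row["class"].strip()
            if direction not in ("to_gene", "to_condition"):
                raise SchemaError(f"{path}:{lineno}: bad direction {direction!r}")
            if label not in LINK_CLASSES or label == "OTHER":
                raise SchemaError(f"{path}:{lineno}: bad class {label!r}")
            rules[(row["rtype"].strip(), direction)] = label
    return rules


def classify_condition_links(
    kb: KnowledgeBase,
    condition_id: str,
    rulemap: Mapping[tuple[str, str], str] | None = None,
) -> LinkClassification:
    """Classify every gene linked to ``condition_id`` via the rulemap.

    Each gene–condition link fires at most one rule keyed by its relation
    type and direction; links matching no rule are logged and contribute to
    OTHER, which a gene receives exactly when none of its links fire.
    Deterministic and independent of edge input order.
    """
    entity = kb.entities.get(condition_id)
    if entity is None or entity.etype != "condition":
        raise ConditionLookupError(
            f"{condition_id!r} is not a condition entity in this knowledge base"
        )
    rules = DEFAULT_RULEMAP if rulemap is None else dict(rulemap)
    assignment: dict[str, set[str]] = {}
    for link in kb.incident(condition_id):
        gene = link.target if link.source == condition_id else link.source
        if kb.entities[gene].etype not in GENE_LIKE_TYPES:
            continue
        direction = "to_gene" if link.source == condition_id else "to_condition"
        classes = assignment.setdefault(gene, set())
        label = rules.get((link.rtype, direction))
        if label is not None:
            classes.add(label)
        else:
            logger.debug(
                "link %s (%s) of gene %s matches no rule; OTHER-contributing",
                link.rtype, direction, gene,
            )
    return LinkClassification(
        condition_id,
        {g: frozenset(cs) if cs else frozenset({"OTHER"}) for g, cs in assignment.items()},
    )


def class_counts(cls: LinkClassification) -> dict[str, int]:
    """Gene counts per class; a multi-label gene counts once in each class."""
    counts = dict.fromkeys(LINK_CLASSES, 0)
    for classes in cls.assignment.values():
        for label in classes:
            counts[label] += 1
    return counts


def cross_classification(clsA: LinkClassification, clsB: LinkClassification) -> CrossTable:
    """Cross-tabulate shared genes by (class under A, class under B)."""
    shared = set(clsA.assignment) & set(clsB.assignment)
    cells: dict[tuple[str, str], set[str]] = {}
    for gene in shared:
        for ra in clsA.assignment[gene]:
            for cb in clsB.assignment[gene]:
                cells.setdefault((ra, cb), set()).add(gene)
    return CrossTable(
        clsA.condition_id,
        clsB.condition_id,
        {key: frozenset(genes) for key, genes in cells.items()},
    )
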