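"""Machine-readable transcriptions of the published analysis tables.

The source study prints its results as tables and in-text gene lists: ten
molecule categories making up the 141-gene focus (hypoglycemia) network, six
curated gene–condition link-pattern classes, a class-by-class cross table
against Alzheimer's disease, the 14-gene core mutual to all five condition
networks, the endothelial genes found inside the focus network, and the
top-ranked hub / cross-talk-specificity genes.  These transcriptions are the
ground for every table-level check in this package.

Fixtures are data files, not code; :func:`verify_fixture_invariants` checks
the transcription against the printed category sizes and set containments,
so a transcription typo is distinguishable from an algorithm bug.  Symbols
are normalized through the packaged alias table at load time (the printed
tables themselves mix aliases: the SNP row prints G6PC where the category
table prints G6PC1).
"""

from __future__ import annotations

import csv
import json
from functools import lru_cache
from importlib import resources
from typing import Any

from ..kb import GeneSet, normalize_symbol, read_aliases, read_gmt
from ..linkclass import LINK_CLASSES, CrossTable, LinkClassification

__all__ = ["FIXTURE_NAMES", "load_fixture", "verify_fixture_invariants"]

#: Printed category sizes of the ten molecule groups, in file order.
_TABLE1_SIZES = {
    "hormones": 14,
    "cytokines_growth_factors": 12,
    "receptors": 19,
    "enzymes": 38,
    "transporters": 19,
    "transcription_factors": 12,
    "neuropeptides": 7,
    "structural_proteins": 2,
    "other_proteins": 17,
    "microRNAs": 2,
}

#: Printed link-class sizes (up, down, inducing, protective, SNP, other).
_TABLE2_SIZES = {
    "UP": 43,
    "DOWN": 17,
    "CAUSAL": 16,
    "PROTECTIVE": 22,
    "SNP_RISK": 34,
    "OTHER": 19,
}

FIXTURE_NAMES = (
    "aliases",
    "table1",
    "network",
    "table2",
    "table2_classification",
    "table5",
    "ad_classification",
    "table5_row_classification",
    "mutual14",
    "endothelial",
    "top_cts",
    "hub_genes",
)


def _data_path(filename: str):
    return resources.as_file(resources.files(__name__) / "data" / filename)


@lru_cache(maxsize=1)
def _bundle() -> dict[str, Any]:
    with _data_path("aliases.tsv") as p:
        aliases = read_aliases(p)
    with _data_path("table1.gmt") as p:
        table1 = {gs.name: gs for gs in read_gmt(p, aliases)}
    with _data_path("table2.gmt") as p:
        table2 = {gs.name: gs for gs in read_gmt(p, aliases)}
    with _data_path("gene_lists.gmt") as p:
        lists = {gs.name: gs for gs in read_gmt(p, aliases)}
    with _data_path("rankings.json") as p, open(p, encoding="utf-8") as fh:
        rankings = json.load(fh)
    cells: dict[tuple[str, str], frozenset[str]] = {}
    with _data_path("table5.tsv") as p, open(p, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            genes = frozenset(
                normalize_symbol(g, aliases) for g in row["genes"].split(";") if g
            )
            cells[(row["row_class"], row["col_class"])] = genes

    union: set[str] = set()
    for gs in table1.values():
        union |= gs.genes

    # AD-side classes read off the cross-table columns; the focus-side view
    # of the same table comes from its rows (the curated class table and the
    # cross table disagree on one symbol in the original publication, so the
    # cross table is kept self-contained)
    ad_sets: dict[str, set[str]] = {}
    focus_sets: dict[str, set[str]] = {}
    for (row, col), genes in cells.items():
        ad_sets.setdefault(col, set()).update(genes)
        focus_sets.setdefault(row, set()).update(genes)

    return {
        "aliases": aliases,
        "table1": table1,
        "network": GeneSet("hypoglycemia_network", frozenset(union)),
        "table2": table2,
        "table2_classification": LinkClassification.from_class_sets("hypoglycemia", table2),
        "table5": CrossTable("hypoglycemia", "alzheimers_disease", cells),
        "ad_classification": LinkClassification.from_class_sets(
            "alzheimers_disease",
            {c: GeneSet(c, frozenset(g)) for c, g in ad_sets.items()},
        ),
        "table5_row_classification": LinkClassification.from_class_sets(
            "hypoglycemia",
            {c: GeneSet(c, frozenset(g)) for c, g in focus_sets.items()},
        ),
        "mutual14": lists["mutual14"],
        "endothelial": lists["endothelial_in_network"],
        "top_cts": list(rankings["top_cts"]),
        "hub_genes": list(rankings["hub_genes"]),
    }


def load_fixture(name: str) -> Any:
    """Return a transcribed, normalized fixture object from the registry.

    Raises
    ------
    KeyError
        For a name outside :data:`FIXTURE_NAMES`.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    return _bundle()[name]


def verify_fixture_invariants(
    overrides: dict[str, Any] | None = None,
) -> list[str]:
    """Check the transcription against the printed counts and containments.

    Returns a list of human-readable violations (empty for the shipped
    bundle).  ``overrides`` substitutes registry entries, which lets tests
    confirm that an injected transcription error is actually caught.
    """
    bundle = dict(_bundle())
    if overrides:
        bundle.update(overrides)
    violations: list[str] = []

    table1 = bundle["table1"]
    if set(table1) != set(_TABLE1_SIZES):
        violations.append(
            f"table1 categories {sorted(table1)} != expected {sorted(_TABLE1_SIZES)}"
        )
    for cat, size in _TABLE1_SIZES.items():
        got = len(table1.get(cat, ()))
        if got != size:
            violations.append(f"table1 category {cat!r} has {got} genes, expected {size}")
    union: set[str] = set()
    for gs in table1.values():
        union |= set(gs.genes)
    if len(union) != 141:
        violations.append(f"table1 union has {len(union)} genes, expected 141")

    table2 = bundle["table2"]
    for cls, size in _TABLE2_SIZES.items():
        got = len(table2.get(cls, ()))
        if got != size:
            violations.append(f"table2 class {cls!r} has {got} genes, expected {size}")
    table2_union: set[str] = set()
    for gs in table2.values():
        table2_union |= set(gs.genes)
    stray = table2_union - union
    if stray:
        violations.append(f"table2 genes outside the table1 network: {sorted(stray)}")
    # every network gene carries at least one curated link class, so the two
    # unions coincide; a symbol on either side alone marks a transcription bug
    stray = union - table2_union
    if stray:
        violations.append(f"table1 genes missing from the link-class table: {sorted(stray)}")

    for list_name, expected_size in (("mutual14", 14), ("endothelial", 15)):
        gs = bundle[list_name]
        if len(gs.genes) != expected_size:
            violations.append(
                f"{list_name} has {len(gs.genes)} genes, expected {expected_size}"
            )
    stray = set(bundle["mutual14"].genes) - union
    if stray:
        violations.append(f"mutual14 genes outside the table1 network: {sorted(stray)}")
    stray = set(bundle["endothelial"].genes) - union
    if stray:
        violations.append(f"endothelial genes outside the table1 network: {sorted(stray)}")

    for rank_name, expected_size in (("top_cts", 10), ("hub_genes", 7)):
        ranked = bundle[rank_name]
        if len(ranked) != expected_size:
            violations.append(f"{rank_name} has {len(ranked)} genes, expected {expected_size}")
        stray = set(ranked) - union
        if stray:
            violations.append(f"{rank_name} genes outside the table1 network: {sorted(stray)}")

    table5 = bundle["table5"]
    table5_genes: set[str] = set()
    for genes in table5.cells.values():
        table5_genes |= set(genes)
    stray = table5_genes - union
    if stray:
        violations.append(f"table5 genes outside the table1 network: {sorted(stray)}")
    bad_classes = {
        c
        for pair in table5.cells
        for c in pair
        if c not in LINK_CLASSES
    }
    if bad_classes:
        violations.append(f"table5 uses unknown link classes: {sorted(bad_classes)}")

    return violations
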