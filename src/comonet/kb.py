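"""Typed knowledge-graph data model and file I/O.

The substrate of every analysis in this package is a literature-style
knowledge base: a directed multigraph whose nodes are biological entities
(genes, microRNAs, conditions, annotation terms) and whose edges are typed
interactions, optionally carrying PubMed provenance.  Parallel edges between
the same pair of entities are retained in storage — literature-derived
knowledge bases record one typed link per extracted statement — and collapsed
onto a simple undirected projection only where a metric requires it.

Gene and protein records that share a symbol are merged into a single node,
because the source networks report "genes/proteins" as single members.
Symbols are normalized to uppercase through a small, user-extensible alias
table (the packaged table maps e.g. G6PC to G6PC1 and GLUT2 to SLC2A2).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "ENTITY_TYPES",
    "GENE_LIKE_TYPES",
    "Entity",
    "Interaction",
    "KnowledgeBase",
    "GeneSet",
    "KnowledgeBaseError",
    "SchemaError",
    "ReferentialIntegrityError",
    "InvalidSymbolError",
    "normalize_symbol",
    "default_aliases",
    "read_aliases",
    "read_kb",
    "write_kb",
    "read_gmt",
    "write_gmt",
    "read_annotation",
    "write_sif",
    "read_sif",
]

#: Entity types understood by the schema.  Gene and protein rows are merged
#: on read, so a loaded knowledge base only ever carries "gene" for both.
ENTITY_TYPES = frozenset({"gene", "protein", "microRNA", "condition", "term"})

#: Types counted as network members / enrichment background.
GENE_LIKE_TYPES = frozenset({"gene", "microRNA"})


class KnowledgeBaseError(Exception):
    """Base class for knowledge-base construction and I/O errors."""


class SchemaError(KnowledgeBaseError):
    """A file violates the expected column layout or vocabulary."""


class ReferentialIntegrityError(KnowledgeBaseError):
    """An interaction endpoint does not resolve to a declared entity."""


class InvalidSymbolError(ValueError):
    """A gene symbol is empty or blank after stripping."""


def normalize_symbol(raw: str, aliases: Mapping[str, str] | None = None) -> str:
    """Return the canonical uppercase form of a gene symbol.

    Whitespace is stripped, the symbol is uppercased and, if present in the
    alias table, replaced by its canonical symbol.  Idempotent: canonical
    symbols map to themselves.

    Raises
    ------
    InvalidSymbolError
        If ``raw`` is empty or blank.
    """
    sym = raw.strip().upper()
    if not sym:
        raise InvalidSymbolError(f"empty gene symbol (raw input {raw!r})")
    if aliases:
        sym = aliases.get(sym, sym)
    return sym


def read_aliases(path: str | Path) -> dict[str, str]:
    """Read an alias table TSV with header columns (alias, canonical)."""
    table: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"alias", "canonical"} <= set(reader.fieldnames):
            raise SchemaError(f"{path}: alias table needs columns (alias, canonical)")
        for row in reader:
            table[row["alias"].strip().upper()] = row["canonical"].strip().upper()
    return table


def default_aliases() -> dict[str, str]:
    """The alias table packaged with the fixtures (G6PC→G6PC1, GLUT2→SLC2A2, ...)."""
    ref = resources.files("comonet.fixtures") / "data" / "aliases.tsv"
    with resources.as_file(ref) as path:
        return read_aliases(path)


@dataclass(frozen=True)
class Entity:
    """A node of the knowledge graph."""

    id: str
    name: str
    etype: str

    def __post_init__(self) -> None:
        if self.etype not in ENTITY_TYPES:
            raise SchemaError(
                f"unknown entity type {self.etype!r} for {self.id!r}; "
                f"expected one of {sorted(ENTITY_TYPES)}"
            )


@dataclass(frozen=True)
class Interaction:
    """A typed directed edge; ``pmids`` carries provenance, never interpreted."""

    source: str
    target: str
    rtype: str
    pmids: tuple[str, ...] = ()

    @property
    def is_self_loop(self) -> bool:
        return self.source == self.target


@dataclass(frozen=True)
class GeneSet:
    """A named set of normalized gene symbols."""

    name: str
    genes: frozenset[str]

    @classmethod
    def from_iterable(
        cls,
        name: str,
        genes: Iterable[str],
        aliases: Mapping[str, str] | None = None,
    ) -> "GeneSet":
        return cls(name, frozenset(normalize_symbol(g, aliases) for g in genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, item: object) -> bool:
        return item in self.genes


class KnowledgeBase:
    """A typed directed multigraph of entities and interactions.

    Interactions are stored as a multiset: duplicate (source, target, rtype)
    records stay as parallel edges.  ``simple_projection`` collapses them to
    an undirected simple edge set.  Self-interactions are stored but excluded
    from adjacency-based metrics by the callers that compute them.
    """

    def __init__(self) -> None:
        self.entities: dict[str, Entity] = {}
        self.interactions: list[Interaction] = []
        self._incident: dict[str, list[Interaction]] = {}

    # -- construction ------------------------------------------------------

    def add_entity(self, entity: Entity) -> None:
        existing = self.entities.get(entity.id)
        if existing is not None:
            if existing.etype != entity.etype:
                raise SchemaError(
                    f"entity {entity.id!r} declared twice with conflicting "
                    f"types {existing.etype!r} and {entity.etype!r}"
                )
            return
        self.entities[entity.id] = entity
        self._incident[entity.id] = []

    def add_interaction(self, interaction: Interaction) -> None:
        for endpoint in (interaction.source, interaction.target):
            if endpoint not in self.entities:
                raise ReferentialIntegrityError(
                    f"interaction {interaction.source!r}-[{interaction.rtype}]->"
                    f"{interaction.target!r} references unknown entity {endpoint!r}"
                )
        self.interactions.append(interaction)
        self._incident[interaction.source].append(interaction)
        if not interaction.is_self_loop:
            self._incident[interaction.target].append(interaction)

    # -- queries -----------------------------------------------------------

    def __contains__(self, entity_id: object) -> bool:
        return entity_id in self.entities

    def entity_ids(self, etype: str | None = None) -> list[str]:
        if etype is None:
            return list(self.entities)
        return [e.id for e in self.entities.values() if e.etype == etype]

    def gene_ids(self) -> list[str]:
        """Ids of gene-like entities (genes incl. merged proteins, microRNAs)."""
        return [e.id for e in self.entities.values() if e.etype in GENE_LIKE_TYPES]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids())

    def incident(self, entity_id: str, include_self_loops: bool = False) -> list[Interaction]:
        """All interactions touching ``entity_id`` (parallel links included)."""
        links = self._incident[entity_id]
        if include_self_loops:
            return list(links)
        return [i for i in links if not i.is_self_loop]

    def degree(self, entity_id: str) -> int:
        """Number of links of an entity, parallel links counted, self-loops not."""
        return len(self.incident(entity_id))

    def neighbors(self, entity_id: str) -> set[str]:
        out: set[str] = set()
        for i in self.incident(entity_id):
            out.add(i.target if i.source == entity_id else i.source)
        return out

    def simple_projection(self) -> set[tuple[str, str]]:
        """Undirected simple edge set: sorted pairs, self-loops dropped."""
        edges: set[tuple[str, str]] = set()
        for i in self.interactions:
            if i.is_self_loop:
                continue
            a, b = sorted((i.source, i.target))
            edges.add((a, b))
        return edges

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<KnowledgeBase: {len(self.entities)} entities, "
            f"{len(self.interactions)} interactions>"
        )


# -- TSV dialect -----------------------------------------------------------

_NODE_COLUMNS = ("id", "name", "etype")
_EDGE_COLUMNS = ("source", "target", "rtype")  # pmids optional


def _check_header(fieldnames: list[str] | None, required: tuple[str, ...], path: str | Path) -> None:
    if fieldnames is None or not set(required) <= set(fieldnames):
        raise SchemaError(f"{path}: expected header columns {required}, got {fieldnames}")


def read_kb(
    nodes_path: str | Path,
    edges_path: str | Path,
    aliases: Mapping[str, str] | None = None,
) -> KnowledgeBase:
    """Load a knowledge base from node and edge TSV files.

    Node TSV columns: (id, name, etype); edge TSV columns
    (source, target, rtype[, pmids]) with pmids semicolon-separated.
    Gene and protein rows sharing a normalized symbol merge into one
    "gene" node; edges follow the merge through an id map.
    """
    kb = KnowledgeBase()
    id_map: dict[str, str] = {}
    with open(nodes_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        _check_header(reader.fieldnames, _NODE_COLUMNS, nodes_path)
        for lineno, row in enumerate(reader, start=2):
            raw_id = row["id"].strip()
            etype = row["etype"].strip()
            if etype not in ENTITY_TYPES:
                raise SchemaError(
                    f"{nodes_path}:{lineno}: unknown entity type {etype!r} "
                    f"for node {raw_id!r}"
                )
            if etype in ("gene", "protein", "microRNA"):
                canonical = normalize_symbol(raw_id, aliases)
                merged_type = "gene" if etype == "protein" else etype
                # a protein row merging onto an existing gene node is the norm
                if canonical in kb.entities and merged_type == "gene":
                    merged_type = kb.entities[canonical].etype
                kb.add_entity(Entity(canonical, row["name"].strip() or canonical, merged_type))
                id_map[raw_id] = canonical
            else:
                kb.add_entity(Entity(raw_id, row["name"].strip() or raw_id, etype))
                id_map[raw_id] = raw_id
    with open(edges_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        _check_header(reader.fieldnames, _EDGE_COLUMNS, edges_path)
        for lineno, row in enumerate(reader, start=2):
            try:
                source = id_map[row["source"].strip()]
                target = id_map[row["target"].strip()]
            except KeyError as exc:
                raise ReferentialIntegrityError(
                    f"{edges_path}:{lineno}: edge endpoint {exc.args[0]!r} "
                    "is not declared in the node table"
                ) from None
            pmids = tuple(p for p in (row.get("pmids") or "").split(";") if p)
            kb.add_interaction(Interaction(source, target, row["rtype"].strip(), pmids))
    return kb


def write_kb(kb: KnowledgeBase, nodes_path: str | Path, edges_path: str | Path) -> None:
    """Write a knowledge base back to the node/edge TSV dialect."""
    with open(nodes_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_NODE_COLUMNS)
        for eid in sorted(kb.entities):
            e = kb.entities[eid]
            writer.writerow([e.id, e.name, e.etype])
    with open(edges_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_EDGE_COLUMNS + ("pmids",))
        for i in kb.interactions:
            writer.writerow([i.source, i.target, i.rtype, ";".join(i.pmids)])


def read_gmt(path: str | Path, aliases: Mapping[str, str] | None = None) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member ({len(fields)} fields found)"
                )
            members = [f for f in fields[2:] if f.strip()]
            sets.append(GeneSet.from_iterable(fields[0], members, aliases))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description, *sorted(gs.genes)]) + "\n")


def read_annotation(
    path: str | Path, aliases: Mapping[str, str] | None = None
) -> dict[str, GeneSet]:
    """Read a flat term→gene annotation TSV (term_id, term_name, gene)."""
    members: dict[str, set[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        _check_header(reader.fieldnames, ("term_id", "gene"), path)
        for row in reader:
            members.setdefault(row["term_id"].strip(), set()).add(
                normalize_symbol(row["gene"], aliases)
            )
    return {term: GeneSet(term, frozenset(genes)) for term, genes in members.items()}


def write_sif(edges: Iterable[tuple[str, str, str]] | KnowledgeBase, path: str | Path) -> None:
    """Write edges as SIF lines ``source<TAB>rtype<TAB>target``.

    Accepts a KnowledgeBase or an iterable of (source, rtype, target)
    triples.  Output is de-duplicated and lexicographically sorted, so a
    write is deterministic and round-trips through :func:`read_sif` to an
    identical simple edge set.
    """
    if isinstance(edges, KnowledgeBase):
        triples = {(i.source, i.rtype, i.target) for i in edges.interactions}
    else:
        triples = set(edges)
    with open(path, "w", encoding="utf-8") as fh:
        for s, r, t in sorted(triples):
            fh.write(f"{s}\t{r}\t{t}\n")


def read_sif(path: str | Path) -> set[tuple[str, str, str]]:
    """Read SIF triples (source, rtype, target)."""
    triples: set[tuple[str, str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise SchemaError(f"{path}:{lineno}: SIF line needs 3 fields")
            triples.add((fields[0], fields[1], fields[2]))
    return triples
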