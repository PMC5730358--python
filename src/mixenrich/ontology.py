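"""Gene Ontology structure and annotation handling.

Parses GO Biological Process structure (OBO) and gene annotations (GAF),
propagates annotations up the is_a/part_of hierarchy (true-path rule),
applies the 15-500 gene-set size filter, and extracts per-term repressor
gene sets from direct *negatively_regulates* child edges.  The repressor
sets carry the functional-sign logic used downstream: a gene annotated to
a child term that negatively regulates its parent acts as a repressor of
the parent process, so its expression change has the opposite functional
meaning for the parent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Edge kinds retained in the ontology graph.  Anything else is dropped.
RELATION_KINDS = frozenset(
    {"is_a", "part_of", "regulates", "positively_regulates", "negatively_regulates"}
)

#: Relations along which annotations propagate (true-path rule).  The
#: regulates family is recorded but never propagates set membership.
SUBSUMPTION_RELATIONS = frozenset({"is_a", "part_of"})


@dataclass(frozen=True)
class Annotation:
    """One gene-to-term association (GAF row after filtering)."""

    gene_id: str
    term_id: str
    qualifier: str | None = None


@dataclass
class OntologyGraph:
    """GO term graph with typed child->parent edges.

    ``edges`` holds ``(child, parent, relation)`` triples with relation in
    :data:`RELATION_KINDS`.  The subgraph restricted to is_a/part_of edges
    must be acyclic (GO guarantees this; we verify).
    """

    terms: set[str]
    edges: list[tuple[str, str, str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {r for _, _, r in self.edges} - RELATION_KINDS
        if bad:
            raise ValueError(f"unknown edge relations: {sorted(bad)}")
        if not nx.is_directed_acyclic_graph(self.subsumption_graph()):
            raise ValueError("is_a/part_of subgraph contains a cycle")

    def subsumption_graph(self) -> nx.DiGraph:
        """Child->parent digraph over is_a and part_of edges only."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(
            (c, p) for c, p, r in self.edges if r in SUBSUMPTION_RELATIONS
        )
        return g

    def negreg_children(self, term: str) -> set[str]:
        """Direct children connected to ``term`` by a negatively_regulates edge."""
        return {c for c, p, r in self.edges if p == term and r == "negatively_regulates"}


@dataclass
class GeneSetCatalog:
    """Propagated, size-filtered term->gene sets plus repressor partitions.

    ``universe`` is the enrichment background: genes present in the
    expression data AND annotated to at least one term.  Term sizes are
    measured after intersection with the universe so that the 2x2 margins
    of every downstream Fisher test are consistent.  ``repressor_sets`` are
    kept for every term with negatively_regulates children, including terms
    whose own size failed the filter.
    """

    term_sets: dict[str, set[str]]
    repressor_sets: dict[str, set[str]]
    universe: set[str]
    size_bounds: tuple[int, int]

    def repressors_of(self, term: str) -> set[str]:
        return self.repressor_sets.get(term, set())


def load_obo(path: str | Path) -> OntologyGraph:
    """Read an OBO 1.2/1.4 file into an :class:`OntologyGraph`.

    Obsolete terms are skipped (and counted in the log).  Relationship
    lines with kinds outside :data:`RELATION_KINDS` are dropped with a
    warning.  Only [Term] stanzas are considered.
    """
    path = Path(path)
    graph = obonet.read_obo(path, ignore_obsolete=True)
    n_obsolete = sum(
        1 for line in path.read_text().splitlines() if line.strip() == "is_obsolete: true"
    )
    if n_obsolete:
        logger.info("load_obo: skipped %d obsolete terms", n_obsolete)

    terms = set(graph.nodes)
    names = {t: d.get("name", t) for t, d in graph.nodes(data=True)}
    edges: list[tuple[str, str, str]] = []
    n_dropped = 0
    # obonet stores child->parent edges keyed by relation type
    for child, parent, relation in graph.edges(keys=True):
        if relation in RELATION_KINDS:
            edges.append((child, parent, relation))
        else:
            n_dropped += 1
    if n_dropped:
        logger.warning("load_obo: dropped %d edges with unsupported relations", n_dropped)
    return OntologyGraph(terms=terms, edges=edges, term_names=names)


# GAF 2.x column positions (0-based)
_GAF_OBJECT_ID = 1
_GAF_QUALIFIER = 3
_GAF_TERM = 4
_GAF_ASPECT = 8
_GAF_MIN_COLS = 15


def load_gaf(path: str | Path, aspect: str = "P") -> list[Annotation]:
    """Read a GAF 2.x annotation file.

    Returns deduplicated (gene, term) annotations restricted to the given
    aspect (default "P", Biological Process).  Rows whose qualifier
    contains NOT are excluded; malformed rows (fewer than 15 columns) are
    skipped with a logged count.  Gene identifiers are taken from the
    DB Object ID column.
    """
    seen: set[tuple[str, str]] = set()
    out: list[Annotation] = []
    n_malformed = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < _GAF_MIN_COLS:
                n_malformed += 1
                continue
            qualifier = cols[_GAF_QUALIFIER]
            if "NOT" in qualifier.split("|"):
                continue
            if cols[_GAF_ASPECT] != aspect:
                continue
            key = (cols[_GAF_OBJECT_ID], cols[_GAF_TERM])
            if key in seen:
                continue
            seen.add(key)
            out.append(Annotation(gene_id=key[0], term_id=key[1], qualifier=qualifier or None))
    if n_malformed:
        logger.warning("load_gaf: skipped %d malformed rows", n_malformed)
    return out


def propagate_annotations(
    graph: OntologyGraph, annotations: Iterable[Annotation]
) -> dict[str, set[str]]:
    """Apply the true-path rule: annotate each gene to all is_a/part_of ancestors.

    Regulates-family edges never carry membership upward.  Annotations to
    terms absent from the graph are skipped with a warning.
    """
    sub = graph.subsumption_graph()
    direct: dict[str, set[str]] = {t: set() for t in graph.terms}
    n_unknown = 0
    for ann in annotations:
        if ann.term_id not in direct:
            n_unknown += 1
            continue
        direct[ann.term_id].add(ann.gene_id)
    if n_unknown:
        logger.warning("propagate_annotations: skipped %d annotations to unknown terms", n_unknown)

    propagated = {t: set(s) for t, s in direct.items()}
    # child->parent edges: topological order lists every child before its parents
    for node in nx.topological_sort(sub):
        for parent in sub.successors(node):
            propagated[parent] |= propagated[node]
    return propagated


def build_catalog(
    graph: OntologyGraph,
    annotations: Iterable[Annotation],
    universe: set[str],
    min_size: int = 15,
    max_size: int = 500,
) -> GeneSetCatalog:
    """Build the size-filtered enrichment catalog.

    ``universe`` is the set of measured gene identifiers; the catalog
    universe becomes measured ∩ annotated.  Term sizes are computed on
    universe-intersected sets BEFORE the [min_size, max_size] filter so
    contingency-table margins stay consistent.  Repressor sets are the
    union of the propagated gene sets of direct negatively_regulates
    children, intersected with the universe, and are retained even for
    terms that fail the size filter.
    """
    if not universe:
        raise ValueError("universe is empty")
    annotations = list(annotations)
    propagated = propagate_annotations(graph, annotations)

    annotated_genes = set().union(*propagated.values()) if propagated else set()
    eff_universe = universe & annotated_genes

    term_sets: dict[str, set[str]] = {}
    for term, genes in propagated.items():
        s = genes & eff_universe
        if min_size <= len(s) <= max_size:
            term_sets[term] = s

    repressor_sets: dict[str, set[str]] = {}
    for _, parent, relation in graph.edges:
        if relation != "negatively_regulates":
            continue
        rep: set[str] = set()
        for child in graph.negreg_children(parent):
            rep |= propagated.get(child, set())
        rep &= eff_universe
        if rep:
            repressor_sets[parent] = rep

    if not term_sets:
        raise ValueError(
            f"no term passed the size filter [{min_size}, {max_size}] "
            f"against a universe of {len(eff_universe)} annotated measured genes"
        )
    return GeneSetCatalog(
        term_sets=term_sets,
        repressor_sets=repressor_sets,
        universe=eff_universe,
        size_bounds=(min_size, max_size),
    )


def write_gmt(catalog: GeneSetCatalog, path: str | Path, names: Mapping[str, str] | None = None) -> None:
    """Export term gene sets in GMT format (term, description, genes...)."""
    names = names or {}
    with open(path, "w") as fh:
        for term in sorted(catalog.term_sets):
            genes = "\t".join(sorted(catalog.term_sets[term]))
            fh.write(f"{term}\t{names.get(term, term)}\t{genes}\n")


def write_repressor_tsv(catalog: GeneSetCatalog, path: str | Path) -> None:
    """Export (term, repressor_gene) pairs as two-column TSV."""
    with open(path, "w") as fh:
        fh.write("term_id\trepressor_gene\n")
        for term in sorted(catalog.repressor_sets):
            for gene in sorted(catalog.repressor_sets[term]):
                fh.write(f"{term}\t{gene}\n")
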