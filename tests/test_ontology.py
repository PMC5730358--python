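"""Ontology parsing, true-path propagation and catalog construction."""

from __future__ import annotations

import numpy as np
import pytest

from mixenrich import (
    Annotation,
    OntologyGraph,
    build_catalog,
    load_gaf,
    load_obo,
    propagate_annotations,
)
from mixenrich.synthetic import SimulationConfig, generate_ontology, write_gaf, write_obo

from conftest import make_annotations


class TestLoadObo:
    def test_negatively_regulates_edge_parsed(self, minimal_obo):
        graph = load_obo(minimal_obo)
        assert ("GO:0000002", "GO:0000001", "negatively_regulates") in graph.edges

    def test_obsolete_term_absent(self, minimal_obo):
        graph = load_obo(minimal_obo)
        assert "GO:0000003" not in graph.terms
        assert graph.terms == {"GO:0000001", "GO:0000002"}

    def test_generator_round_trip(self, tmp_path):
        config = SimulationConfig(n_genes=500, n_terms=50, term_size_range=(5, 15), seed=3)
        onto = generate_ontology(config)
        write_obo(onto, tmp_path / "t.obo")
        parsed = load_obo(tmp_path / "t.obo")
        assert parsed.terms == onto.graph.terms
        assert sorted(parsed.edges) == sorted(onto.graph.edges)
        assert parsed.term_names == onto.graph.term_names

    def test_unreadable_file_fatal(self, tmp_path):
        with pytest.raises(OSError):
            load_obo(tmp_path / "missing.obo")


class TestLoadGaf:
    def _write(self, tmp_path, rows):
        path = tmp_path / "t.gaf"
        lines = ["!gaf-version: 2.1"]
        for gene, qual, term, aspect in rows:
            cols = ["DB", gene, gene, qual, term, "REF", "IEA", "", aspect,
                    "", "", "gene", "taxon:1", "20200101", "DB"]
            lines.append("\t".join(cols))
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_not_qualifier_excluded_and_dedup(self, tmp_path):
        path = self._write(tmp_path, [
            ("g1", "NOT", "GO:1", "P"),
            ("g2", "", "GO:1", "P"),
            ("g2", "", "GO:1", "P"),  # duplicate, different row
            ("g3", "", "GO:1", "F"),  # wrong aspect
        ])
        anns = load_gaf(path)
        assert anns == [Annotation("g2", "GO:1", None)]

    def test_synthetic_count_by_construction(self, tmp_path):
        # 200 rows total: 10 NOT-qualified, 5 duplicates of valid rows -> 185
        rows = [(f"g{i}", "", f"GO:{i % 40}", "P") for i in range(185)]
        rows += rows[:5]
        rows += [(f"h{i}", "NOT", "GO:1", "P") for i in range(10)]
        assert len(rows) == 200
        anns = load_gaf(self._write(tmp_path, rows))
        assert len(anns) == 185

    def test_malformed_rows_skipped(self, tmp_path):
        path = tmp_path / "bad.gaf"
        path.write_text("!header\nshort\trow\nDB\tg1\tg1\t\tGO:1\tR\tIEA\t\tP\t\t\tgene\ttaxon:1\t2020\tDB\n")
        assert len(load_gaf(path)) == 1


class TestPropagation:
    def test_true_path_rule(self, toy_graph):
        sets = propagate_annotations(toy_graph, [Annotation("g", "GO:B")])
        assert "g" in sets["GO:A"] and "g" in sets["GO:R"]

    def test_part_of_propagates(self, toy_graph):
        sets = propagate_annotations(toy_graph, [Annotation("g", "GO:C")])
        assert "g" in sets["GO:A"]

    def test_regulates_edges_do_not_propagate(self, toy_graph):
        sets = propagate_annotations(toy_graph, [Annotation("g", "GO:N")])
        assert "g" not in sets["GO:A"]
        assert "g" in sets["GO:R"]  # via N is_a R

    def test_unknown_term_skipped(self, toy_graph):
        sets = propagate_annotations(toy_graph, [Annotation("g", "GO:MISSING")])
        assert all("g" not in s for s in sets.values())

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_closure(self, seed):
        """Propagated sets equal per-gene transitive-closure reachability."""
        rng = np.random.default_rng(seed)
        terms = [f"GO:{i}" for i in range(30)]
        edges = []
        for i in range(1, 30):
            for parent in rng.choice(i, size=min(i, 1 + int(rng.integers(2))), replace=False):
                rel = ["is_a", "part_of", "negatively_regulates"][int(rng.integers(3))]
                edges.append((terms[i], terms[parent], rel))
        graph = OntologyGraph(terms=set(terms), edges=edges, term_names={})
        anns = [
            Annotation(f"g{j}", terms[int(rng.integers(30))])
            for j in range(100)
        ]
        got = propagate_annotations(graph, anns)

        parent_map: dict[str, set[str]] = {t: set() for t in terms}
        for c, p, r in edges:
            if r in ("is_a", "part_of"):
                parent_map[c].add(p)

        def ancestors(t):
            out, stack = set(), [t]
            while stack:
                for p in parent_map[stack.pop()]:
                    if p not in out:
                        out.add(p)
                        stack.append(p)
            return out

        expected: dict[str, set[str]] = {t: set() for t in terms}
        for ann in anns:
            for t in {ann.term_id} | ancestors(ann.term_id):
                expected[t].add(ann.gene_id)
        assert got == expected

    def test_monotone_along_subsumption_edges(self, study, study_catalog):
        """set(parent) superset of set(child) for every is_a/part_of edge."""
        props = propagate_annotations(study.ontology.graph, study.ontology.annotations)
        for child, parent, rel in study.ontology.graph.edges:
            if rel in ("is_a", "part_of"):
                assert props[parent] >= props[child]

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            OntologyGraph(
                terms={"GO:1", "GO:2"},
                edges=[("GO:1", "GO:2", "is_a"), ("GO:2", "GO:1", "part_of")],
                term_names={},
            )

    def test_unknown_relation_rejected(self):
        with pytest.raises(ValueError, match="unknown edge relations"):
            OntologyGraph(terms={"GO:1", "GO:2"},
                          edges=[("GO:1", "GO:2", "occurs_in")], term_names={})


class TestCatalog:
    def _graph(self, n_children=0):
        terms = {"GO:R", "GO:T"} | {f"GO:N{i}" for i in range(n_children)}
        edges = [("GO:T", "GO:R", "is_a")]
        for i in range(n_children):
            edges += [(f"GO:N{i}", "GO:T", "negatively_regulates"),
                      (f"GO:N{i}", "GO:R", "is_a")]
        return OntologyGraph(terms=terms, edges=edges, term_names={})

    @pytest.mark.parametrize("n,kept", [(14, False), (15, True), (500, True), (501, False)])
    def test_size_filter_boundaries(self, n, kept):
        terms = {"GO:R", "GO:T", "GO:F"}
        edges = [("GO:T", "GO:R", "is_a"), ("GO:F", "GO:R", "is_a")]
        graph = OntologyGraph(terms=terms, edges=edges, term_names={})
        universe = {f"g{i}" for i in range(600)} | {f"f{i}" for i in range(20)}
        anns = make_annotations({
            "GO:T": [f"g{i}" for i in range(n)],
            "GO:F": [f"f{i}" for i in range(20)],  # filler keeps the catalog nonempty
        })
        cat = build_catalog(graph, anns, universe)
        assert ("GO:T" in cat.term_sets) == kept

    def test_universe_intersected_before_filter(self):
        graph = self._graph()
        anns = make_annotations({"GO:T": [f"g{i}" for i in range(20)]})
        universe = {f"g{i}" for i in range(14)} | {"x1", "x2"}  # only 14 measured members
        with pytest.raises(ValueError, match="no term passed"):
            build_catalog(graph, anns, universe)

    def test_repressor_union_of_direct_children(self):
        graph = self._graph(n_children=2)
        reps0 = [f"r{i}" for i in range(8)]
        reps1 = [f"r{i}" for i in range(6, 15)]  # overlap of 2 with reps0
        anns = make_annotations(
            {"GO:T": [f"g{i}" for i in range(20)], "GO:N0": reps0, "GO:N1": reps1}
        )
        universe = {f"g{i}" for i in range(20)} | set(reps0) | set(reps1)
        cat = build_catalog(graph, anns, universe)
        assert len(cat.repressor_sets["GO:T"]) == 15

    def test_repressor_sets_ignore_grandchild_negreg_edges(self):
        """A negatively_regulates edge below a direct child must not leak up."""
        terms = {"GO:R", "GO:T", "GO:C", "GO:GC"}
        edges = [
            ("GO:T", "GO:R", "is_a"),
            ("GO:C", "GO:T", "is_a"),
            ("GO:GC", "GO:C", "negatively_regulates"),
            ("GO:GC", "GO:R", "is_a"),
        ]
        graph = OntologyGraph(terms=terms, edges=edges, term_names={})
        anns = make_annotations({"GO:T": [f"g{i}" for i in range(20)], "GO:GC": ["r1"]})
        cat = build_catalog(graph, anns, {f"g{i}" for i in range(20)} | {"r1"})
        assert "GO:T" not in cat.repressor_sets
        assert "r1" in cat.repressor_sets["GO:C"]

    def test_repressor_sets_kept_for_size_filtered_terms(self):
        graph = self._graph(n_children=1)
        anns = make_annotations({"GO:T": ["g1", "g2"], "GO:N0": ["r1"]})  # T too small
        universe = {"g1", "g2", "r1"} | {f"pad{i}" for i in range(20)}
        anns += make_annotations({"GO:R": [f"pad{i}" for i in range(20)]})
        cat = build_catalog(graph, anns, universe)
        assert "GO:T" not in cat.term_sets
        assert cat.repressor_sets["GO:T"] == {"r1"}

    def test_empty_universe_fatal(self, toy_graph):
        with pytest.raises(ValueError, match="universe is empty"):
            build_catalog(toy_graph, [], set())

    def test_retained_sizes_verified_by_recount(self, study, study_catalog):
        """Independent recount: every retained term size lies within bounds."""
        lo, hi = study_catalog.size_bounds
        props = propagate_annotations(study.ontology.graph, study.ontology.annotations)
        for term, genes in study_catalog.term_sets.items():
            recount = len(props[term] & study_catalog.universe)
            assert recount == len(genes)
            assert lo <= recount <= hi


def test_gaf_obo_round_trip_through_catalog(tmp_path):
    """Generated fixture -> files -> parsers -> catalog sizes in range."""
    config = SimulationConfig(
        n_genes=800, n_terms=30, term_size_range=(10, 25), frac_negreg_children=0.4, seed=5
    )
    onto = generate_ontology(config)
    write_obo(onto, tmp_path / "o.obo")
    write_gaf(onto.annotations, tmp_path / "a.gaf")
    graph = load_obo(tmp_path / "o.obo")
    anns = load_gaf(tmp_path / "a.gaf")
    cat = build_catalog(graph, anns, set(onto.gene_ids), min_size=10, max_size=25)
    for term, genes in cat.term_sets.items():
        assert 10 <= len(genes) <= 25
    # only leaves and (small) repressor children can pass a tight size filter
    assert set(cat.term_sets) <= set(onto.leaf_terms) | set(onto.child_genes)
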