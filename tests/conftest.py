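"""Shared fixtures: tiny hand-built ontologies and a mid-size simulated study."""

from __future__ import annotations

import numpy as np
import pytest

from mixenrich import (
    Annotation,
    OntologyGraph,
    SimulationConfig,
    build_catalog,
    default_implants,
    simulate_study,
)

MINIMAL_OBO = """\
format-version: 1.2
ontology: test

[Term]
id: GO:0000001
name: parent process

[Term]
id: GO:0000002
name: negative regulation of parent process
relationship: negatively_regulates GO:0000001

[Term]
id: GO:0000003
name: retired process
is_obsolete: true
"""


@pytest.fixture
def minimal_obo(tmp_path):
    path = tmp_path / "minimal.obo"
    path.write_text(MINIMAL_OBO)
    return path


@pytest.fixture
def toy_graph() -> OntologyGraph:
    """root <- A (is_a) <- B (is_a); N negatively_regulates A; C part_of A."""
    return OntologyGraph(
        terms={"GO:R", "GO:A", "GO:B", "GO:C", "GO:N"},
        edges=[
            ("GO:A", "GO:R", "is_a"),
            ("GO:B", "GO:A", "is_a"),
            ("GO:C", "GO:A", "part_of"),
            ("GO:N", "GO:A", "negatively_regulates"),
            ("GO:N", "GO:R", "is_a"),
        ],
        term_names={},
    )


def make_annotations(mapping: dict[str, list[str]]) -> list[Annotation]:
    return [Annotation(g, t) for t, genes in mapping.items() for g in genes]


@pytest.fixture(scope="session")
def study():
    """Mid-size simulated study shared by pipeline-level tests.

    15,000 genes, 300 leaf terms, 20 implanted perturbations with effect
    2.0 over noise 0.3, three replicate pairs sharing the implants.
    """
    config = SimulationConfig(
        n_genes=15000,
        n_terms=300,
        term_size_range=(15, 100),
        frac_negreg_children=0.3,
        implanted_terms=default_implants(20),
        effect_size_mean=2.0,
        effect_size_sd=0.5,
        noise_sd=0.3,
        background_altered_frac=0.02,
        n_replicates=3,
        seed=11,
    )
    return simulate_study(config)


@pytest.fixture(scope="session")
def study_catalog(study):
    return build_catalog(
        study.ontology.graph,
        study.ontology.annotations,
        set(study.profiles[0].gene_ids),
    )


def make_deg(gene: str, direction: str = "up", is_deg: bool = True):
    from mixenrich.mixture import DegCall

    fc = {"up": 1.5, "down": -1.5, "zero": 0.0}[direction]
    return DegCall(gene_id=gene, log2fc=fc, posterior_altered=0.95 if is_deg else 0.05,
                   is_deg=is_deg, direction=direction)


def noise_free_scenario(flip: bool = False):
    """Hand-built catalog + DEG calls with known functional directions.

    Nine 50-gene terms, each with a 5-gene negatively_regulates child:
    three activated (25 member DEGs up, repressors down), three with
    reduced activity (mirror image), two bidirectional (25 up / 25 down
    members, repressors split 2/3), one ambiguous (no DEGs at all), plus
    balanced background DEGs (60 up, 60 down) and non-DEG filler parked
    in an oversized term that fails the size filter.  ``flip`` negates
    every expression direction, which must swap activated and
    reduced_activity while fixing bidirectional and ambiguous.

    Returns (catalog, deg_calls, expected_direction_by_term).
    """
    from mixenrich.ontology import OntologyGraph

    def d(direction):
        if not flip:
            return direction
        return {"up": "down", "down": "up"}[direction]

    categories = ["activated"] * 3 + ["reduced_activity"] * 3 + ["bidirectional"] * 2 + [
        "ambiguous"
    ]
    terms = [f"GO:T{i}" for i in range(9)]
    children = [f"GO:N{i}" for i in range(9)]
    graph_terms = {"GO:ROOT", "GO:BG", *terms, *children}
    edges = [("GO:BG", "GO:ROOT", "is_a")]
    mapping: dict[str, list[str]] = {}
    calls = []
    expected = {}
    for i, (term, cat) in enumerate(zip(terms, categories)):
        members = [f"t{i}_{j}" for j in range(50)]
        reps = [f"r{i}_{j}" for j in range(5)]
        mapping[term] = members
        mapping[children[i]] = reps
        edges += [(term, "GO:ROOT", "is_a"), (children[i], "GO:ROOT", "is_a"),
                  (children[i], term, "negatively_regulates")]
        expected[term] = cat if cat != "activated" or not flip else cat
        if cat == "activated":
            calls += [make_deg(g, d("up")) for g in members[:25]]
            calls += [make_deg(g, d("down")) for g in reps]
        elif cat == "reduced_activity":
            calls += [make_deg(g, d("down")) for g in members[:25]]
            calls += [make_deg(g, d("up")) for g in reps]
        elif cat == "bidirectional":
            calls += [make_deg(g, d("up")) for g in members[:25]]
            calls += [make_deg(g, d("down")) for g in members[25:]]
            calls += [make_deg(g, d("down")) for g in reps[:2]]
            calls += [make_deg(g, d("up")) for g in reps[2:]]
    if flip:
        expected = {
            t: {"activated": "reduced_activity", "reduced_activity": "activated"}.get(c, c)
            for t, c in expected.items()
        }
    background = [f"bu{j}" for j in range(60)] + [f"bd{j}" for j in range(60)]
    filler = [f"fx{j}" for j in range(1500)]
    mapping["GO:BG"] = background + filler
    calls += [make_deg(g, d("up")) for g in background[:60]]
    calls += [make_deg(g, d("down")) for g in background[60:]]
    calls += [make_deg(g, "up", is_deg=False) for g in filler[:50]]

    graph = OntologyGraph(terms=graph_terms, edges=edges, term_names={})
    universe = {g for genes in mapping.values() for g in genes}
    catalog = build_catalog(graph, make_annotations(mapping), universe,
                            min_size=15, max_size=300)
    assert set(catalog.term_sets) == set(terms)  # BG/root/children filtered by size
    return catalog, calls, expected


def random_table(rng: np.random.Generator, max_margin: int = 200) -> tuple[int, int, int, int]:
    """Random 2x2 table with both margins at most ``max_margin``."""
    n = int(rng.integers(4, max_margin + 1))
    k = int(rng.integers(1, n))  # term size
    m = int(rng.integers(1, n))  # DEG count
    a = int(rng.integers(max(0, m + k - n), min(m, k) + 1))
    return a, m - a, k - a, n - m - k + a
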