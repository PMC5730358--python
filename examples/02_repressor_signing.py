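"""How *negatively_regulates* edges change a term's functional direction.

Builds one 20-gene process term with a 5-gene repressor child, makes the
repressors' expression DROP while nothing else moves, and shows that the
term is called activated: falling repressor expression means the process
has lost its brake.
"""

from mixenrich import (
    Annotation,
    OntologyGraph,
    build_catalog,
    run_enrichment,
    sign_all,
)
from mixenrich.mixture import DegCall

graph = OntologyGraph(
    terms={"GO:ROOT", "GO:PROC", "GO:NEG", "GO:BG"},
    edges=[
        ("GO:PROC", "GO:ROOT", "is_a"),
        ("GO:NEG", "GO:ROOT", "is_a"),
        ("GO:NEG", "GO:PROC", "negatively_regulates"),
        ("GO:BG", "GO:ROOT", "is_a"),
    ],
    term_names={"GO:PROC": "example process",
                "GO:NEG": "negative regulation of example process"},
)
members = [f"m{i}" for i in range(20)]
repressors = [f"r{i}" for i in range(5)]
background = [f"b{i}" for i in range(500)]
annotations = (
    [Annotation(g, "GO:PROC") for g in members]
    + [Annotation(g, "GO:NEG") for g in repressors]
    + [Annotation(g, "GO:BG") for g in background]
)
universe = set(members) | set(repressors) | set(background)
catalog = build_catalog(graph, annotations, universe, min_size=15, max_size=400)


def deg(gene, direction, is_deg=True):
    fc = {"up": 1.5, "down": -1.5}[direction]
    return DegCall(gene_id=gene, log2fc=fc, posterior_altered=0.95 if is_deg else 0.05,
                   is_deg=is_deg, direction=direction)


# only the repressors respond — their expression drops — plus light
# balanced background so the directional tests have a realistic pool
calls = [deg(g, "down") for g in repressors]
calls += [deg(g, "up") for g in background[:15]]
calls += [deg(g, "down") for g in background[15:30]]

records = run_enrichment(calls, catalog)
signed = sign_all(records, calls, catalog, report_all=True)
for rec in signed:
    if rec.term_id != "GO:PROC":
        continue
    print(f"term {rec.term_id}: base FDR={rec.base.fdr:.3g}, "
          f"up-side n={rec.n_up_upregulatory}, down-side n={rec.n_down_downregulatory}")
    print(f"functional direction: {rec.direction}")

# All five moving genes have DECREASED expression, yet the call is
# "activated": they sit in a negatively_regulates child, so their loss is
# read as removal of suppression of the parent process.
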