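"""Functional signing of enriched GO-BP terms.

A significant term tells you a process is altered, not which way.  Each
DEG carries an expression direction, but the functional impact of that
change on a given term depends on the gene's regulatory role: a gene
annotated to a *negatively_regulates* child of the term is a repressor of
the term's process, so its functional sign is the REVERSE of its
expression direction (expression up -> process suppressed; expression
down -> suppression removed, i.e. process activated).

Each candidate term gets two auxiliary one-sided FETs: one on the
"upregulated-and-upregulatory" DEG pool and one on its mirror.  The
contingency margins mirror the base enrichment table, with successes
restricted to the functionally concordant DEG subset for that term.
After per-direction B-H correction across candidate terms, the pair of
FDRs maps onto exactly one of four categories:

    activated          fdr_up <= alpha,  fdr_down >  alpha
    reduced_activity   fdr_up >  alpha,  fdr_down <= alpha
    bidirectional      both significant
    ambiguous          neither
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .enrichment import EnrichmentRecord, adjust_pvalues, build_table, fisher_exact
from .mixture import DegCall
from .ontology import GeneSetCatalog

Direction = Literal["activated", "reduced_activity", "bidirectional", "ambiguous"]


@dataclass
class SignedPartition:
    """A term's DEGs split by functional sign (zero-fold-change DEGs excluded)."""

    term_id: str
    up_upregulatory: set[str]
    down_downregulatory: set[str]


@dataclass
class SignedEnrichmentRecord:
    term_id: str
    base: EnrichmentRecord
    fet_up: tuple[float, float]  # (p, fdr)
    fet_down: tuple[float, float]
    direction: Direction
    n_up_upregulatory: int = 0
    n_down_downregulatory: int = 0


def effective_sign(
    gene: str,
    term: str,
    expression_direction: Literal["up", "down"],
    catalog: GeneSetCatalog,
) -> Literal["up_functional", "down_functional"]:
    """Functional sign of a gene's expression change for one term.

    Repressor genes (members of a direct negatively_regulates child of the
    term) have their sign reversed; repressor status wins over plain
    membership when a gene has both roles.
    """
    repressors = catalog.repressors_of(term)
    if gene not in catalog.term_sets.get(term, set()) and gene not in repressors:
        raise ValueError(f"gene {gene!r} is unrelated to term {term!r} (caller bug)")
    flipped = gene in repressors
    up = (expression_direction == "up") != flipped
    return "up_functional" if up else "down_functional"


def build_signed_partition(
    term: str, deg_calls: Iterable[DegCall], catalog: GeneSetCatalog
) -> SignedPartition:
    """Assign each of the term's DEGs to exactly one functional side."""
    members = catalog.term_sets.get(term, set()) | catalog.repressors_of(term)
    up: set[str] = set()
    down: set[str] = set()
    for call in deg_calls:
        if not call.is_deg or call.direction == "zero" or call.gene_id not in members:
            continue
        side = effective_sign(call.gene_id, term, call.direction, catalog)
        (up if side == "up_functional" else down).add(call.gene_id)
    return SignedPartition(term_id=term, up_upregulatory=up, down_downregulatory=down)


def _functional_pools(
    term: str, deg_calls: Sequence[DegCall], catalog: GeneSetCatalog
) -> tuple[set[str], set[str]]:
    """Genome-wide functionally-up / functionally-down DEG pools for a term.

    Outside the term's repressor set the functional sign equals the
    expression sign; inside it the sign flips.  Genes with log2FC exactly
    zero contribute to neither pool.
    """
    repressors = catalog.repressors_of(term)
    up: set[str] = set()
    down: set[str] = set()
    for call in deg_calls:
        if not call.is_deg or call.direction == "zero" or call.gene_id not in catalog.universe:
            continue
        is_up = (call.direction == "up") != (call.gene_id in repressors)
        (up if is_up else down).add(call.gene_id)
    return up, down


def directional_fets(
    partition: SignedPartition,
    deg_calls: Sequence[DegCall],
    catalog: GeneSetCatalog,
) -> tuple[float, float]:
    """Raw p-values of the two directional FETs for one term.

    fet_up asks whether the term's up-and-upregulatory genes are
    overrepresented among all functionally-up DEGs, against the same
    universe as the base enrichment; fet_down mirrors it.  An empty
    partition side yields p = 1.
    """
    term = partition.term_id
    term_col = (catalog.term_sets.get(term, set()) | catalog.repressors_of(term)) & catalog.universe
    pool_up, pool_down = _functional_pools(term, deg_calls, catalog)
    p_up = fisher_exact(build_table(pool_up, term_col, catalog.universe))[0] if pool_up else 1.0
    p_down = (
        fisher_exact(build_table(pool_down, term_col, catalog.universe))[0] if pool_down else 1.0
    )
    return p_up, p_down


def assign_direction(fdr_up: float, fdr_down: float, alpha: float = 0.05) -> Direction:
    """Map the two directional FDRs to the four-way categorical direction."""
    sig_up = fdr_up <= alpha
    sig_down = fdr_down <= alpha
    if sig_up and not sig_down:
        return "activated"
    if sig_down and not sig_up:
        return "reduced_activity"
    if sig_up and sig_down:
        return "bidirectional"
    return "ambiguous"


def sign_all(
    enrichment: Sequence[EnrichmentRecord],
    deg_calls: Sequence[DegCall],
    catalog: GeneSetCatalog,
    alpha: float = 0.05,
    report_all: bool = False,
) -> list[SignedEnrichmentRecord]:
    """Attach a functional direction to enrichment results.

    The base statistics (p, OR, FDR from the full DEG set) are passed
    through untouched — signing never alters them.  Directional FETs are
    computed for every candidate term and B-H corrected per direction
    across all of them; by default only base-significant terms are
    reported, all on request.
    """
    deg_calls = list(deg_calls)
    partitions = [build_signed_partition(r.term_id, deg_calls, catalog) for r in enrichment]
    raw = [directional_fets(p, deg_calls, catalog) for p in partitions]
    p_up = np.array([r[0] for r in raw])
    p_down = np.array([r[1] for r in raw])
    fdr_up = adjust_pvalues(p_up, method="BH")
    fdr_down = adjust_pvalues(p_down, method="BH")

    out = []
    for rec, part, pu, pd, fu, fd in zip(enrichment, partitions, p_up, p_down, fdr_up, fdr_down):
        if not (report_all or rec.significant):
            continue
        out.append(
            SignedEnrichmentRecord(
                term_id=rec.term_id,
                base=rec,
                fet_up=(float(pu), float(fu)),
                fet_down=(float(pd), float(fd)),
                direction=assign_direction(float(fu), float(fd), alpha),
                n_up_upregulatory=len(part.up_upregulatory),
                n_down_downregulatory=len(part.down_downregulatory),
            )
        )
    return out
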