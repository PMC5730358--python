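"""Fisher's Exact Test enrichment of GO-BP terms among DEGs.

One-sided ("greater") tests for overrepresentation, sample odds ratios,
and Benjamini-Yekutieli (default) or Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .mixture import DegCall
from .ontology import GeneSetCatalog


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: DEG membership (rows) vs term membership (columns).

    a: DEGs in the term; b: DEGs outside it; c: non-DEG universe genes in
    the term; d: the rest.  a+b is the DEG count, a+c the in-universe term
    size, a+b+c+d the universe size.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentRecord:
    term_id: str
    table: ContingencyTable
    odds_ratio: float
    p_value: float
    fdr: float
    significant: bool
    term_name: str = ""


def build_table(
    deg_genes: set[str], term_genes: set[str], universe: set[str]
) -> ContingencyTable:
    """Count the 2x2 cells by set intersection.

    Raises if a DEG or term gene falls outside the universe — that signals
    a universe mismatch upstream rather than a condition to paper over.
    """
    if not deg_genes <= universe:
        raise ValueError("DEG genes outside the universe: universe mismatch upstream")
    if not term_genes <= universe:
        raise ValueError("term genes outside the universe: universe mismatch upstream")
    a = len(deg_genes & term_genes)
    b = len(deg_genes) - a
    c = len(term_genes) - a
    d = len(universe) - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


def odds_ratio(table: ContingencyTable, haldane: bool = False) -> float:
    """Sample odds ratio ad/bc.

    Convention: bc = 0 with ad > 0 gives +inf; ad = 0 gives 0.  With
    ``haldane=True`` the Haldane-Anscombe +0.5 correction is applied to
    every cell, yielding finite values suitable for rank comparisons.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if haldane:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    if a * d == 0:
        return 0.0
    if b * c == 0:
        return float("inf")
    return (a * d) / (b * c)


def fisher_exact(table: ContingencyTable) -> tuple[float, float]:
    """One-sided (enrichment) FET p-value and sample odds ratio.

    p = P(K >= a) for K hypergeometric with the table's margins — the
    upper tail of the usual 2x2 exact test with alternative "greater".
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    p = float(hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))
    return min(p, 1.0), odds_ratio(table)


def adjust_pvalues(
    p: Sequence[float] | np.ndarray, method: Literal["BY", "BH"] = "BY"
) -> np.ndarray:
    """Step-up FDR-adjusted p-values (monotone, capped at 1).

    "BY" includes the harmonic-sum factor for arbitrary dependence; "BH"
    is the plain Benjamini-Hochberg procedure.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    key = {"BY": "fdr_by", "BH": "fdr_bh"}[method]
    return multipletests(p, method=key)[1]


def run_enrichment(
    deg_calls: Iterable[DegCall],
    catalog: GeneSetCatalog,
    alpha: float = 0.05,
    method: Literal["BY", "BH"] = "BY",
    term_names: dict[str, str] | None = None,
) -> list[EnrichmentRecord]:
    """FET over every catalog term; records sorted by ascending p.

    DEGs are intersected with the catalog universe (measured genes without
    any annotation cannot enter the 2x2 margins).  Zero DEGs is not an
    error: every term then has p = 1 and nothing is significant.
    Significance is ``fdr <= alpha`` (inclusive).
    """
    term_names = term_names or {}
    deg_genes = {c.gene_id for c in deg_calls if c.is_deg} & catalog.universe
    terms = sorted(catalog.term_sets)
    tables = [build_table(deg_genes, catalog.term_sets[t], catalog.universe) for t in terms]
    ps = np.array([fisher_exact(t)[0] for t in tables])
    fdrs = adjust_pvalues(ps, method=method)
    records = [
        EnrichmentRecord(
            term_id=t,
            table=tab,
            odds_ratio=odds_ratio(tab),
            p_value=float(p),
            fdr=float(f),
            significant=bool(f <= alpha),
            term_name=term_names.get(t, ""),
        )
        for t, tab, p, f in zip(terms, tables, ps, fdrs)
    ]
    records.sort(key=lambda r: (r.p_value, r.term_id))
    return records
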