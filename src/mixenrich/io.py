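"""Tabular readers/writers and run configuration for the CLI surface."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .enrichment import EnrichmentRecord
from .mixture import DegCall
from .signing import SignedEnrichmentRecord

from importlib.metadata import version as _pkg_version

try:
    __version__ = _pkg_version("mixenrich")
except Exception:  # pragma: no cover - not installed
    __version__ = "unknown"


def read_expression_tsv(path: str | Path) -> tuple[dict[str, float], dict[str, float] | None]:
    """Read expression TSV.

    Two layouts: ``gene_id, case, control`` (returns both maps) or
    ``gene_id, value`` (returns one map and None).
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two tab-separated columns")
    genes = df.iloc[:, 0].astype(str)
    if {"case", "control"} <= set(df.columns):
        return (
            dict(zip(genes, df["case"].astype(float))),
            dict(zip(genes, df["control"].astype(float))),
        )
    return dict(zip(genes, df.iloc[:, 1].astype(float))), None


def write_deg_tsv(calls: list[DegCall], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "log2fc": [c.log2fc for c in calls],
            "posterior": [c.posterior_altered for c in calls],
            "is_deg": [int(c.is_deg) for c in calls],
            "direction": [c.direction for c in calls],
        }
    ).to_csv(path, sep="\t", index=False)


def read_deg_tsv(path: str | Path) -> list[DegCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        DegCall(
            gene_id=str(r.gene_id),
            log2fc=float(r.log2fc),
            posterior_altered=float(r.posterior),
            is_deg=bool(r.is_deg),
            direction=str(r.direction),
        )
        for r in df.itertuples()
    ]


def write_enrichment_tsv(records: list[EnrichmentRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "term_id": [r.term_id for r in records],
            "term_name": [r.term_name for r in records],
            "a": [r.table.a for r in records],
            "b": [r.table.b for r in records],
            "c": [r.table.c for r in records],
            "d": [r.table.d for r in records],
            "odds_ratio": [r.odds_ratio for r in records],
            "p_value": [r.p_value for r in records],
            "fdr": [r.fdr for r in records],
            "significant": [int(r.significant) for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def write_signed_tsv(records: list[SignedEnrichmentRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "term_id": [r.term_id for r in records],
            "term_name": [r.base.term_name for r in records],
            "odds_ratio": [r.base.odds_ratio for r in records],
            "p_value": [r.base.p_value for r in records],
            "fdr": [r.base.fdr for r in records],
            "n_up_upregulatory": [r.n_up_upregulatory for r in records],
            "n_down_downregulatory": [r.n_down_downregulatory for r in records],
            "fdr_up": [r.fet_up[1] for r in records],
            "fdr_down": [r.fet_down[1] for r in records],
            "direction": [r.direction for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def write_direction_long_tsv(
    per_sample: dict[str, list[SignedEnrichmentRecord]], path: str | Path
) -> None:
    """Heat-map-ready long format: one row per (term, sample) with a direction code."""
    code = {"activated": 1, "reduced_activity": -1, "bidirectional": 2, "ambiguous": 0}
    rows = [
        {"term_id": r.term_id, "sample": sample, "direction": r.direction,
         "direction_code": code[r.direction]}
        for sample, records in per_sample.items()
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_reference_terms(path: str | Path) -> tuple[set[str], set[str], dict[str, float]]:
    """Read an external reference list: term_id, significant flag, optional odds_ratio.

    Returns (domain, significant set, odds-ratio map).  When the file also
    carries the 2x2 cells (a, b, c, d — e.g. an enrichment TSV from this
    tool), Haldane-corrected odds ratios are recomputed from them so rank
    comparisons use the same finite-OR convention on both sides.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"{path}: reference file has no rows")
    terms = set(df["term_id"].astype(str))
    sig = set(df.loc[df["significant"].astype(int) == 1, "term_id"].astype(str))
    if {"a", "b", "c", "d"} <= set(df.columns):
        ors = {
            str(r.term_id): ((r.a + 0.5) * (r.d + 0.5)) / ((r.b + 0.5) * (r.c + 0.5))
            for r in df.itertuples()
        }
    elif "odds_ratio" in df.columns:
        ors = dict(zip(df["term_id"].astype(str), df["odds_ratio"].astype(float)))
    else:
        ors = {}
    return terms, sig, ors


@dataclass
class RunConfig:
    """Resolved parameters + provenance written alongside every run's outputs."""

    case: str = ""
    control: str = ""
    obo: str = ""
    gaf: str = ""
    outdir: str = ""
    input_scale: str = "log2"
    pseudocount: float = 1.0
    deg_threshold: float = 0.5
    alpha: float = 0.05
    correction: str = "BY"
    min_size: int = 15
    max_size: int = 500
    em_max_iter: int = 1000
    em_tol: float = 1e-8
    em_starts: int = 5
    seed: int = 0
    tool_version: str = field(default_factory=lambda: __version__)
    timestamp: str = ""
    input_checksums: dict = field(default_factory=dict)

    def resolve_provenance(self) -> None:
        self.timestamp = datetime.now(timezone.utc).isoformat()
        for key in ("case", "control", "obo", "gaf"):
            p = getattr(self, key)
            if p and Path(p).is_file():
                digest = hashlib.sha256(Path(p).read_bytes()).hexdigest()
                self.input_checksums[key] = digest

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
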