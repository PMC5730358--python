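"""Synthetic fixtures: toy ontologies, annotations and paired profiles.

Generates everything the pipeline consumes, with known ground truth, so
each stage can be tested without downloading GO or expression data:

* a small GO-like DAG — one root, a few large "hub" terms, and annotated
  leaf process terms, a fraction of which get a *negatively_regulates*
  child term holding that process's repressor genes;
* GAF annotations hitting a configured per-term size range;
* paired log2-scale expression profiles emulating an isogenic pair
  design: a minority of genes are altered between the two conditions
  (bimodal |log2FC|), alterations are implanted coherently at the term
  level with a chosen functional direction, repressor-child genes move
  opposite to their term's direction, and replicates share the altered
  gene assignment while noise is drawn independently.

Defaults emulate a liver microarray transcriptome: ~18,000 measured
genes, effect sizes around 2 log2FC units, replicate noise around 0.3,
and ~2% of transcripts varying between individuals for reasons unrelated
to the contrast (background alterations).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

from .mixture import PairedProfile
from .ontology import Annotation, OntologyGraph

ImplantDirection = Literal["activated", "reduced", "bidirectional"]

ROOT_TERM = "GO:0000001"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the emulated conditions.

    ``n_terms`` counts the annotated leaf process terms; the root, hub
    parents and repressor child terms are structural extras on top.
    ``implanted_terms`` pairs a term id (or None for "pick one for me")
    with a direction.
    """

    n_genes: int = 18000
    n_terms: int = 300
    term_size_range: tuple[int, int] = (15, 100)
    frac_negreg_children: float = 0.3
    implanted_terms: list[tuple[str | None, ImplantDirection]] = field(default_factory=list)
    effect_size_mean: float = 2.0
    effect_size_sd: float = 0.5
    noise_sd: float = 0.3
    background_altered_frac: float = 0.02
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.term_size_range
        if self.n_terms < 2 or self.n_genes < hi or lo > hi or lo < 1:
            raise ValueError("infeasible ontology size constraints")
        for frac in (self.frac_negreg_children, self.background_altered_frac):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.effect_size_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("standard deviations must be positive")


def default_implants(n: int = 20) -> list[tuple[None, ImplantDirection]]:
    """n implant slots cycling activated / reduced / bidirectional."""
    cycle: list[ImplantDirection] = ["activated", "reduced", "bidirectional"]
    return [(None, cycle[i % 3]) for i in range(n)]


@dataclass
class SyntheticOntology:
    graph: OntologyGraph
    annotations: list[Annotation]
    leaf_terms: list[str]
    leaf_genes: dict[str, set[str]]  # direct (== propagated) leaf memberships
    negreg_child_of: dict[str, str]  # leaf term -> its repressor child term
    child_genes: dict[str, set[str]]  # repressor child term -> genes
    gene_ids: list[str]


@dataclass
class SimulatedTruth:
    altered: dict[str, bool]
    expression_sign: dict[str, int]  # +1 / -1 for altered genes
    term_direction: dict[str, ImplantDirection]
    implant_member_of: dict[str, str]  # altered implant gene -> its term
    replicate_seeds: list[int]


def _gene_pool(n_genes: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n_genes + 1)]


def generate_ontology(config: SimulationConfig, rng: np.random.Generator | None = None) -> SyntheticOntology:
    """Random GO-like DAG plus annotations hitting the size range.

    Layout: root <- hubs (is_a) <- leaves (is_a, some extra part_of);
    a ``frac_negreg_children`` fraction of leaves gets a small child term
    attached by negatively_regulates (and is_a root), whose genes are the
    leaf process's repressors.  Hubs carry no direct annotation but
    accumulate their leaves' genes under propagation, deliberately
    overshooting the usual 500-gene catalog cap so implanted leaf signal
    does not cascade into retained ancestors.  Leaf propagated sets equal
    their direct annotations, so catalog sizes land in the configured
    range by construction.
    """
    rng = rng or np.random.default_rng(config.seed)
    genes = _gene_pool(config.n_genes)
    n_hubs = max(1, config.n_terms // 60)
    lo, hi = config.term_size_range

    next_id = 2
    hubs = [f"GO:{i:07d}" for i in range(next_id, next_id + n_hubs)]
    next_id += n_hubs
    leaves = [f"GO:{i:07d}" for i in range(next_id, next_id + config.n_terms)]
    next_id += config.n_terms

    names = {ROOT_TERM: "biological_process"}
    edges: list[tuple[str, str, str]] = []
    for i, h in enumerate(hubs):
        names[h] = f"hub process {i + 1}"
        edges.append((h, ROOT_TERM, "is_a"))

    leaf_genes: dict[str, set[str]] = {}
    annotations: list[Annotation] = []
    for i, leaf in enumerate(leaves):
        names[leaf] = f"leaf process {i + 1}"
        hub = hubs[int(rng.integers(len(hubs)))]
        edges.append((leaf, hub, "is_a"))
        if len(hubs) > 1 and rng.random() < 0.1:
            other = hubs[int(rng.integers(len(hubs)))]
            if other != hub:
                edges.append((leaf, other, "part_of"))
        size = int(rng.integers(lo, hi + 1))
        members = set(rng.choice(genes, size=size, replace=False))
        leaf_genes[leaf] = members
        annotations.extend(Annotation(g, leaf) for g in sorted(members))

    n_negreg = int(round(config.frac_negreg_children * config.n_terms))
    negreg_leaves = [leaves[i] for i in sorted(rng.choice(config.n_terms, size=n_negreg, replace=False))]
    negreg_child_of: dict[str, str] = {}
    child_genes: dict[str, set[str]] = {}
    for leaf in negreg_leaves:
        child = f"GO:{next_id:07d}"
        next_id += 1
        names[child] = f"negative regulation of {names[leaf]}"
        edges.append((child, ROOT_TERM, "is_a"))
        edges.append((child, leaf, "negatively_regulates"))
        # repressors are distinct from the process's own members so the
        # simulated truth stays unambiguous
        candidates = [g for g in genes if g not in leaf_genes[leaf]]
        size = int(rng.integers(5, 11))
        members = set(rng.choice(candidates, size=size, replace=False))
        negreg_child_of[leaf] = child
        child_genes[child] = members
        annotations.extend(Annotation(g, child) for g in sorted(members))

    graph = OntologyGraph(terms=set(names), edges=edges, term_names=names)
    return SyntheticOntology(
        graph=graph,
        annotations=annotations,
        leaf_terms=leaves,
        leaf_genes=leaf_genes,
        negreg_child_of=negreg_child_of,
        child_genes=child_genes,
        gene_ids=genes,
    )


def assign_truth(
    config: SimulationConfig,
    ontology: SyntheticOntology,
    rng: np.random.Generator | None = None,
) -> SimulatedTruth:
    """Pick implanted terms and fix every gene's alteration and sign.

    The expression sign of a repressor-child gene is the REVERSE of its
    term's functional direction (an activated process sheds its
    repressors; a reduced one gains them).  Bidirectional implants split
    members (and repressors) roughly 50/50.  A gene claimed by an earlier
    implant keeps its first assignment.  Background alterations get a
    random sign.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    altered: dict[str, bool] = {}
    expr_sign: dict[str, int] = {}
    member_of: dict[str, str] = {}
    term_direction: dict[str, ImplantDirection] = {}

    chosen: list[tuple[str, ImplantDirection]] = []
    pool = list(ontology.leaf_terms)
    for term_id, direction in config.implanted_terms:
        if term_id is None:
            pick = pool[int(rng.integers(len(pool)))]
            while pick in term_direction:
                pick = pool[int(rng.integers(len(pool)))]
            term_id = pick
        if term_id not in ontology.leaf_genes:
            raise ValueError(f"implanted term {term_id!r} is not a generated leaf term")
        term_direction[term_id] = direction
        chosen.append((term_id, direction))

    for term, direction in chosen:
        members = sorted(ontology.leaf_genes[term])
        child = ontology.negreg_child_of.get(term)
        repressors = sorted(ontology.child_genes[child]) if child else []
        if direction == "bidirectional":
            perm = rng.permutation(len(members))
            func = {members[j]: (1 if k < len(members) / 2 else -1) for k, j in enumerate(perm)}
            rperm = rng.permutation(len(repressors))
            func.update(
                {repressors[j]: (1 if k < len(repressors) / 2 else -1) for k, j in enumerate(rperm)}
            )
        else:
            s = 1 if direction == "activated" else -1
            func = {g: s for g in members + repressors}
        for g in members + repressors:
            if g in altered:
                continue
            altered[g] = True
            flip = -1 if g in ontology.child_genes.get(child or "", set()) else 1
            expr_sign[g] = func[g] * flip
            member_of[g] = term

    unassigned = [g for g in ontology.gene_ids if g not in altered]
    n_bg = int(round(config.background_altered_frac * config.n_genes))
    n_bg = min(n_bg, len(unassigned))
    if n_bg:
        bg = rng.choice(unassigned, size=n_bg, replace=False)
        for g in bg:
            altered[g] = True
            expr_sign[g] = 1 if rng.random() < 0.5 else -1

    rep_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=config.n_replicates)]
    return SimulatedTruth(
        altered=altered,
        expression_sign=expr_sign,
        term_direction=term_direction,
        implant_member_of=member_of,
        replicate_seeds=rep_seeds,
    )


def generate_paired_expression(
    config: SimulationConfig, truth: SimulatedTruth, ontology: SyntheticOntology
) -> list[PairedProfile]:
    """One paired profile per replicate.

    Control values are per-gene log2-scale baselines ~ Normal(8, 2^2);
    case = control + log2FC.  Unaltered genes draw log2FC ~ Normal(0,
    noise_sd^2) independently per replicate; altered genes draw
    sign * Normal(effect_size_mean, effect_size_sd^2), with the sign fixed
    across replicates by the shared truth assignment.
    """
    genes = ontology.gene_ids
    alt = np.array([truth.altered.get(g, False) for g in genes])
    sign = np.array([truth.expression_sign.get(g, 0) for g in genes], dtype=float)
    profiles = []
    for rep_seed in truth.replicate_seeds:
        rng = np.random.default_rng(rep_seed)
        control = rng.normal(8.0, 2.0, size=len(genes))
        fc = rng.normal(0.0, config.noise_sd, size=len(genes))
        effect = sign * rng.normal(config.effect_size_mean, config.effect_size_sd, size=len(genes))
        fc = np.where(alt, effect, fc)
        case = control + fc
        profiles.append(
            PairedProfile(
                gene_ids=list(genes),
                expr_case=case,
                expr_control=control,
                log2fc=fc,
                abs_log2fc=np.abs(fc),
            )
        )
    return profiles


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    ontology: SyntheticOntology
    truth: SimulatedTruth
    profiles: list[PairedProfile]


def simulate_study(config: SimulationConfig, outdir: str | Path | None = None) -> SimulatedStudy:
    """Run the full generator; optionally write the fixture files.

    Files written: ontology.obo, annotations.gaf, replicate_<k>.tsv
    expression pairs, truth tables (genes + terms) and the resolved
    config as YAML.  Identical config + seed reproduce identical bytes.
    """
    rng = np.random.default_rng(config.seed)
    ontology = generate_ontology(config, rng)
    truth = assign_truth(config, ontology, rng)
    profiles = generate_paired_expression(config, truth, ontology)
    study = SimulatedStudy(config=config, ontology=ontology, truth=truth, profiles=profiles)
    if outdir is not None:
        write_study(study, Path(outdir))
    return study


# ---------------------------------------------------------------- writers


def write_obo(ontology: SyntheticOntology, path: str | Path) -> None:
    graph = ontology.graph
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go-bp\n")
        for term in sorted(graph.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {graph.term_names.get(term, term)}\n")
            for child, parent, rel in sorted(graph.edges):
                if child != term:
                    continue
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")


def write_gaf(annotations: list[Annotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for ann in annotations:
            cols = [
                "SYN", ann.gene_id, ann.gene_id, ann.qualifier or "", ann.term_id,
                "SYN:0000001", "IEA", "", "P", "", "", "gene", "taxon:0000", "20180101", "SYN",
            ]
            fh.write("\t".join(cols) + "\n")


def write_profile_tsv(profile: PairedProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcase\tcontrol\n")
        for g, ca, co in zip(profile.gene_ids, profile.expr_case, profile.expr_control):
            fh.write(f"{g}\t{ca:.6f}\t{co:.6f}\n")


def write_study(study: SimulatedStudy, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_obo(study.ontology, outdir / "ontology.obo")
    write_gaf(study.ontology.annotations, outdir / "annotations.gaf")
    for k, profile in enumerate(study.profiles, start=1):
        write_profile_tsv(profile, outdir / f"replicate_{k}.tsv")
    with open(outdir / "truth_genes.tsv", "w") as fh:
        fh.write("gene_id\taltered\texpression_sign\timplant_term\n")
        for g in study.ontology.gene_ids:
            fh.write(
                f"{g}\t{int(study.truth.altered.get(g, False))}\t"
                f"{study.truth.expression_sign.get(g, 0)}\t"
                f"{study.truth.implant_member_of.get(g, '')}\n"
            )
    with open(outdir / "truth_terms.tsv", "w") as fh:
        fh.write("term_id\tdirection\n")
        for t in sorted(study.truth.term_direction):
            fh.write(f"{t}\t{study.truth.term_direction[t]}\n")
    cfg = asdict(study.config)
    cfg["term_size_range"] = list(cfg["term_size_range"])
    cfg["implanted_terms"] = [[t, d] for t, d in cfg["implanted_terms"]]
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
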