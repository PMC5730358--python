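# Methods

## The model

One subject contributes a paired expression vector (case, control) on a
log2 scale; the per-gene contrast is `log2fc = case − control`. The
method's premise is that across a transcriptome most genes are unaltered
between the paired conditions, so the distribution of |log₂FC| is a
mixture of a near-zero noise component and a shifted altered component:

    |log2fc| ~ (1 − π) · N(μ_u, σ_u²) + π · N(μ_a, σ_a²),   μ_u ≤ μ_a

The Gaussian components are fit to the *folded* (absolute) values as the
method defines them, even though the generative truth of a folded
difference is a folded normal. This is deliberate: the package
reproduces the published procedure rather than a corrected variant, and
the parameter-recovery tests quantify how small the resulting bias is
under realistic separations (fitted π within 0.01 of truth at effect 2.0
over noise 0.2–0.5).

A transcript is a DEG when its posterior probability of the altered
component exceeds 0.5 (strict). DEGs feed a one-sided Fisher's Exact
Test per GO-BP term against the universe of measured-and-annotated
genes, with Benjamini–Yekutieli FDR control (the B-Y harmonic factor
covers the strong positive dependence among nested GO terms);
Benjamini–Hochberg is available for the DEG+FET reference mode.
Significance is inclusive, `fdr ≤ alpha`.

## EM details

* Initialisation: one deterministic quantile start (μ_u = median,
  μ_a = 95th percentile, both σ = pooled SD, π = 0.1) plus `n_starts − 1`
  seeded random perturbations of it; the best final log-likelihood wins.
  The deterministic start makes results reproducible; the perturbed
  starts guard against local optima.
* Convergence: relative log-likelihood change < 1e-8 or 1000 iterations.
  The log-likelihood trace is recorded and tested to be non-decreasing
  (EM guarantee, 1e-9 numerical slack).
* Degeneracy: variances are floored at 1e-6 (σ ≥ 1e-3) and π is clamped
  to [1e-6, 1−1e-6]. Inputs shorter than 50 values or all-identical are
  rejected.
* The input vector is sorted before EM. The likelihood is order-free, so
  this is statistically a no-op, but it makes the fit exactly invariant
  to input permutation instead of invariant only up to float-summation
  order.
* **No-signal guard:** if the fitted means are closer than
  0.5·σ_unaltered, the "altered" component is an arbitrary split of
  unimodal noise; the DEG set is then forced empty rather than reporting
  a fabricated tail. The constant is a conservative separation floor —
  genuinely bimodal fold-change data sit far above it (typically > 5σ).
* Linear-scale input is shifted by a configurable pseudocount (default
  1.0) before log2; log2-scale input is used as-is.

## Ontology handling

OBO parsing is delegated to `obonet`; obsolete terms are skipped and
non-GO relations dropped with a warning. GAF 2.x rows are filtered to
aspect P, NOT-qualified rows removed, (gene, term) pairs deduplicated,
and malformed rows skipped with a count. Annotations propagate along
is_a/part_of only (true-path rule); regulates-family edges never carry
membership. Term sizes are computed after intersection with the
enrichment universe (measured ∩ annotated) and then filtered to 15–500,
so all 2×2 margins refer to one consistent universe.

Repressor sets come from **direct** *negatively_regulates* children
only: transitive negative regulation (odd/even path parity) is not
chased, and a grandchild negative edge changes nothing. A gene annotated
both to the parent and to a negative child is treated as a repressor —
the curated repressor role is the more specific claim. Repressor sets
are retained even for terms whose own size fails the filter.

## Functional signing

For a term *t*, a DEG's functional sign is its expression sign, flipped
iff the gene is in *t*'s repressor set. The term column of both
directional tests is `term_set(t) ∪ repressor_set(t)`; the success
margin of the "up" test is the genome-wide functionally-up DEG pool *in
t's context* (expression-up non-repressors plus expression-down
repressors of *t*), mirrored for "down"; the universe is the base
universe. The two raw p-value vectors are B-H corrected per direction
across all tested terms, and (FDR_up ≤ α, FDR_down ≤ α) maps to
activated / reduced_activity / bidirectional / ambiguous — a total,
mutually exclusive four-way rule. DEGs with log2fc exactly 0 belong to
neither side. Signing reads the base enrichment but never modifies it;
stripping every negative edge leaves base p/OR/FDR bit-identical.

By default only base-significant terms are reported signed;
`report_all` signs everything tested (useful for heat-map exports and
for inspecting sub-threshold terms).

## The synthetic generator

The generator emulates the fold-change structure of an isogenic paired
design, not platform physics: control baselines are N(8, 2²) per gene,
case = control + log2fc, unaltered genes draw log2fc ~ N(0, noise_sd²)
per replicate, altered genes draw sign·N(effect_mean, effect_sd²) with
the sign and assignment shared across replicates (the "genotype effect")
and magnitudes redrawn per replicate (biological noise). Defaults:
18,000 genes, noise_sd 0.3, effect 2.0 ± 0.5, 2% background-altered
genes (the reported range of baseline inter-individual liver variation
spans roughly 1–10%; 2% is a conservative middle), three replicates.

The toy ontology is a three-level DAG: root → a few hub terms → leaf
process terms (plus small *negatively_regulates* child terms attached to
30% of leaves, each holding 5–10 repressor genes disjoint from the leaf's
own members). Hubs carry no direct annotations but inherit their leaves'
genes, deliberately overshooting the 500-gene cap so that implanted leaf
signal cannot cascade into retained ancestors — this keeps "implanted
terms" a well-defined truth set for precision scoring. Leaf memberships
are sampled uniformly, so unperturbed terms overlap implanted signal
only by chance.

Implants set every member of a term coherently: activated → members up,
repressors down; reduced → mirrored; bidirectional → a 50/50 member
split (the simplest symmetric reading of the category — no generative
recipe exists for it). A gene claimed by two implants keeps its first
assignment. Identical config + seed reproduce byte-identical files.

What passing these simulations does **not** show: real transcriptomes
have correlated genes, non-Gaussian tails, term-size-biased annotation
depth and context-dependent (sometimes bidirectional) regulators, none
of which the generator models. The simulation results certify the
machinery — calling, testing, signing, scoring — under the stated
conditions, not field performance on any particular dataset.

## Evaluation

ROC/AUC ranks terms by candidate p (ties grouped; trapezoid AUC equals
the tie-corrected Mann–Whitney statistic). Precision/recall threshold
the candidate p directly; precision at zero calls is 1 by convention.
Spearman rho uses average-rank ties and the t-approximation p-value, on
Haldane-corrected (+0.5 per cell) odds ratios so every rank is finite;
when a reference file carries 2×2 cells the same correction is applied
to its ORs. Replicate overlap reports both denominator conventions
(per-replicate list size and smallest list) side by side. Matching is by
exact term identifier; no credit for semantically similar terms.

## Problem sizes in tests

The acceptance-level simulations use 15,000 genes × 300 terms × 20
implants (pipeline recovery, replicate AUC) and 50 null repeats at 4,000
genes × 60 terms (type-I calibration); these sizes give stable pass/fail
behaviour at desk scale while keeping the full suite under a minute.

## Known limitations

* Tested only for paired designs; no cohort mode (that is limma/SAM
  territory) and no RNA-Seq count model — counts enter via log2 + pseudocount.
* All genes with a *negatively_regulates* path are treated as pure
  repressors of the parent; bidirectional regulatory capacity is not
  represented.
* FET is the only set statistic offered; rank-based alternatives
  (GSEA-style, Mann-Whitney) are out of scope, as is any normalization
  or batch correction — inputs are assumed preprocessed.
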