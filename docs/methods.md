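# Methods

## Scope and model

The package infers structure at the *pathway* level from multi-condition
perturbation transcriptomics.  Its core object is the pathway × condition
**NES matrix** ("meta-activity"): for each condition, genes are ranked by a
signed significance metric and every pathway is scored by preranked
enrichment.  All downstream inference — responsiveness classes, the
correlation network, hubs, the A/B bipartition, anti-correlation scoring —
consumes only this matrix and its nominal-p companion, which is why a
precomputed NES/p pair can be supplied directly for downstream-only runs.

Input expression values are assumed to be normalized log-ratio intensities
with ≥ 2 treated and ≥ 2 control replicates per condition.  Normalization,
probe→gene collapsing and any cross-species homolog mapping are upstream of
this package; gene identifiers are opaque, case-sensitive strings.

## Per-condition ranking

Each gene is tested with a two-sided pooled-variance (Student's) t-test;
Welch's variant is available behind a flag (`welch=True`) but the
equal-variance test is the default because that is what the plain name
denotes for replicated microarray contrasts.  The ranking metric is
`log10(1/p)`, signed by the mean treated−control difference.  Decisions:

- **p floor 1e-16** before the log keeps the metric finite; genes at the
  floor are ordered by the global tie rule.
- **Tie rule**: descending metric, then ascending gene id.  A stated
  deterministic order beats inheriting the input file order.
- Two constant, equal groups are degenerate: p = 1, direction reported as
  "up" with a flag.
- One- vs two-sided is not forced by the method's description; two-sided is
  used and stated.

## Preranked enrichment

The running sum rises by `|r_g|^w / Σ_hits |r|^w` at gene-set members and
falls by `1/(N−k)` elsewhere; the ES is the maximum deviation from zero.
`w = 1` (the standard weighted statistic) is the default; `w = 0` gives the
classic unweighted KS walk and is the form checked against an exhaustive
brute-force oracle in the tests.  Numerical choices:

- A tie `|max| == |min|` resolves to the **positive** deviation, compared
  with a small tolerance so float accumulation order cannot flip a true tie.
- A set whose mapped members all have metric 0 under `w = 1` would have an
  undefined hit increment; it falls back to equal weights.
- Sets with fewer than `min_size` (default 10) mapped genes are skipped;
  a set mapping to the whole list has no miss decrement and is an error.

**Permutation null.** Random same-size gene sets are drawn from the ranked
list.  Preranked data has no phenotype labels, so gene-label permutation is
the only available scheme.  Because this null depends only on the ranked
list and the set size, it is computed once per size and shared among
same-size sets; nulls are seeded by (root seed, size), which makes results
independent of the order of sets in the GMT file.  The batch ES evaluator
works from sorted hit positions in O(k) per permutation after one sort, so
~200 sets × 43 conditions × 1000 permutations runs in minutes.

**Nominal p** is the add-one empirical tail over the same-signed null part:
`p = (1 + #{|null| ≥ |ES|, same sign}) / (1 + #same-sign)`; with no
same-signed null values the cell is flagged missing.  **NES** divides the
ES by the mean |ES| of the same-signed null — the standard
operationalization of normalizing the score to set size.  Missing NES and
missing p coincide by construction.

## Responsiveness and NPC

`n_i` counts conditions with nominal p < α (default 0.05); missing cells
never count.  `NPC(θ)` is the mean of `n_i / C` over pathways with
`n_i ≥ θ`; an empty survivor set yields a *missing* value, not 0, because 0
would fake a point on the curve.  Class thresholds default to HR ≥ 10,
MR 5–9, LR < 5; choosing them (reading the curve's elbow) remains a human
/config decision — there is deliberately no automatic elbow detector.

## Correlation network and hubs

NES columns are z-scored **per condition** (sample, n−1 standard deviation;
zero-variance columns are flagged missing).  Row-wise scaling would be a
no-op for Pearson correlation — the tests assert PCC invariance under
positive affine row rescaling — so the column-wise reading is the only one
that changes anything, and it makes heterogeneous perturbations comparable.

Pairwise correlations use **pairwise-complete** overlap with
`min_overlap = 10` conditions (how untested cells enter the correlation is
otherwise unspecified); p is two-sided from `t = r·sqrt((n−2)/(1−r²))`.
Edges require `|PCC| > 0.5` **strictly** and p < `p_max`.  The method's
description carries two correlation-p thresholds (1e-4 in the methods text,
1e-3 in the results text); 1e-4 is the default and 1e-3 a config
alternative, and `analysis/04` reports both side by side.  Degrees are
computed over all pathways, not only hubs.  A hub needs `n_i ≥ 10` and
degree ≥ 10.

**Bipartition.** The hub-induced signed subgraph is two-colored by
traversal (keep color across positive edges, flip across negative).  If
consistent, the graph is structurally balanced and the coloring is the A/B
split; the side containing a configured anchor pathway is named "A" (else
the larger side, ties to the side with the lexicographically first member —
the naming is semantic, not structural).  If inconsistent, the frustrated
edges are reported and no labels are assigned; no frustration-minimizing
partition is attempted.

## Anti-correlation scoring

A group's consensus direction in a condition is the sign of the mean NES of
its significantly responding hubs, defined only with ≥ 3 of them (the
mean-sign rule is a declared decision for the case of split signs).  Seeds
are conditions where both consensuses exist and are opposite; a manual seed
list can override the automatic rule but is validated the same way.

The ±1 rule is **symmetric transfer**: a significant seed response matching
group A adds +1 to A_score and −1 to B_score, and vice versa.  This is the
only reading under which "A_score ≥ +3 (B_score ≤ −3)" is an equivalence
and |score| ≤ n, as the score ratio requires.  `anti_score =
max(A_score, B_score)/n` with `n` counting only significant responses
within seed conditions, so its attainable values are the finite grid
`(2k−n)/n`.  Group membership needs a score ≥ 3 (hence n ≥ 3); the
anti-correlation call needs `anti_score > 0.7`, strictly — e.g. n = 20,
k = 17 (ratio exactly 0.7) fails.

## Synthetic data

The generator emulates the study design the method was developed on:
**189 pathways × 43 conditions, 20 toxicopathological, 16 hubs split 8/8,
triplicate treated/control groups, unit-variance noise** (all defaults of
`SimulationConfig`).  Structure:

- Toxic condition *c* draws a severity `s(c) ~ U(0.5, 1.5)` — heterogeneous
  but consistently signed conditions exercise correlation, not just sign
  agreement — and follows Scheme B with 80% probability (most toxic states
  activate group B and suppress group A), else Scheme A.
- Hub meta-activity is `±s(c)` in every toxic condition; non-hub group
  members participate per toxic condition with probability 0.35, placing
  them below the hub responsiveness threshold while preserving the group's
  sign where they respond; background pathways and physiological conditions
  are exactly 0.
- Genes belong to exactly one pathway (sizes U{10..30}); member genes get
  treated mean `m(p,c)·effect_size` against control mean 0, plus i.i.d.
  Gaussian noise.  The default effect size 1.2 gives modest per-gene power
  with triplicates — realistic for replicated microarrays — which the
  set-level statistic aggregates into reliable pathway calls.
- `simulate_nes_matrix` emits a NES/p matrix directly (planted activity +
  Gaussian noise, calls at a configurable power with false positives at a
  configurable rate) for tests that do not need the gene level.

All randomness flows through substreams of one root seed, so any stage can
be regenerated independently and reruns are byte-identical (the pipeline
manifest records content hashes).

What the generator does **not** model: array-level artifacts (dye bias,
spatial effects), gene sharing between pathways (configurable off by
default, to isolate the statistics from the glycolysis/gluconeogenesis-style
confound), dose/sex covariates, and correlated noise across genes.  Passing
recovery tests therefore show the inference machinery is sound under the
planted model, not that real screens meet its assumptions.

## Problem sizes used in the checks

The end-to-end recovery check runs 10 simulated studies of 40 conditions
(20 toxic) × 150 pathways with 12 planted hubs, per-gene power 0.9
(n = 4 replicates, effect solved from the noncentral-t closed form) and 200
permutations, plus 10 matched null studies — sizes chosen so the whole
suite stays interactive while leaving the planted-signal margins wide.  The
analysis scripts run the full 189 × 43 design with 500 permutations.

## Known limitations

- Nominal p-values only; no FDR across pathways (downstream calls use the
  nominal threshold by design), no leading-edge analysis.
- The permutation p has resolution 1/(n_perm+1); at the default α = 0.05
  use ≥ 200 permutations.
- Pairwise-complete correlations can rest on different condition subsets
  per pair; `min_overlap` guards the worst cases but p-values are not
  corrected for the varying overlap.
- An unbalanced hub subgraph yields frustrated edges and no A/B labels;
  interpreting near-balanced structures is left to the analyst.
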