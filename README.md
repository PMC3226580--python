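# pathwayhubs

Finding **hub molecular pathways** — pathways that are both frequently
perturbed and highly co-regulated — and their **inverted (anti-correlated)
activity groups** in multi-condition transcriptomic perturbation screens.

The motivating setting is a liver-toxicology screen: dozens of chemical
perturbations (doses × durations × sexes) plus a few physiological
contrasts, each profiled as a treated-vs-control expression experiment.
Under strong (toxicopathological) perturbations, a core of hub pathways
splits into two groups whose activities move in opposite directions — one
group activated exactly when the other is suppressed.  This package
implements the full analysis as a tested, reusable pipeline, together with
a synthetic-data generator that plants that structure with known truth.

## The method

For each condition, every gene gets a two-sample Student's t-test between
treated and control replicates and the signed ranking metric

```
r(g) = ± log10(1 / p_g)        (+ for up-, − for down-regulated)
```

Preranked gene-set enrichment walks the ranked list with a weighted
Kolmogorov–Smirnov-like running sum; the enrichment score ES is the maximum
deviation from zero.  A gene-label permutation null (default 1000 draws)
gives the nominal p-value (add-one empirical tail) and the normalized
enrichment score `NES = ES / mean |ES_null, same sign|`.  The pathway ×
condition NES matrix is the *meta-activity* of each pathway.

Downstream of the NES matrix:

- **Responsiveness.** `n_i` = number of conditions with nominal p < 0.05.
  The normalized pathway coverage, `NPC(θ) = mean_{i: n_i ≥ θ} n_i / C`
  over `C` conditions, guides the class cutoffs: HR (`n_i ≥ 10`),
  MR (`5 ≤ n_i ≤ 9`), LR (`n_i < 5`).
- **Network.** NES columns are z-scored per condition; pathway pairs are
  correlated across conditions (pairwise-complete Pearson).  Edges require
  `|PCC| > 0.5` (strict) and correlation p < 1e-4; degree = incident edges.
- **Hubs.** Pathways with `n_i ≥ 10` *and* degree ≥ 10.
- **A/B bipartition.** The signed hub subgraph is two-colored (positive
  edges keep the color, negative flip it).  If it is structurally balanced,
  the two sides are the inverted groups A and B; otherwise the frustrated
  edges are reported.
- **Anti-correlation scoring.** Conditions where the two groups' consensus
  directions (each from ≥ 3 significant hubs) are opposite act as *seeds*.
  For every pathway, each significant seed response transfers +1 to the
  group it matches and −1 to the other, so `A_score = −B_score`.  With `n`
  significant seed responses, `anti_score = max(A_score, B_score) / n`; a
  pathway joins a group at score ≥ 3 and is anti-correlated when
  `anti_score > 0.7` (strict), with `3 ≤ n`.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data with planted truth (intermediates under `scratch/`, tables under
`results/`):

```sh
python analysis/01_simulate_study.py --seed 7
python analysis/02_rank_and_enrich.py --seed 7     # ~1 min
python analysis/03_responsiveness.py
python analysis/04_network_and_hubs.py
python analysis/05_anticorrelation.py
```

Output from the run recorded in `results/` (seed 7, 500 permutations):

```
study: 189 pathways x 43 conditions, seed 7
planted hubs: 16  pathway groups: {'background': 113, 'A': 38, 'B': 38}
condition states: {'physiological': 23, 'toxic_scheme_B': 16, 'toxic_scheme_A': 4}
classes: {'LR': 111, 'MR': 47, 'HR': 31} ({'LR': 58.7, 'MR': 24.9, 'HR': 16.4} %)
p<1e-4: {'edges': 119, 'mean_degree': 1.26, 'degree_ge_10': 16, 'hubs': 16,
         'frustrated_edges': 0, 'group_sizes': {'A': 8, 'B': 8}}
recovered 16/16 planted hubs; group agreement up to label swap: 100%
20 seed conditions; 73 anti-correlated pathways
planted members assigned: 58 (group agreement 100%); background rejected: 97%
```

Reading this: all 16 planted hubs are recovered with the correct A/B split
and a perfectly balanced (frustration-free) sign structure; the 20 planted
toxic conditions are re-identified as seeds from the data alone; and the
planted non-hub group members are assigned to the right group by the
scoring scheme while 97% of background pathways are rejected.

The same stages are available as a CLI (`pathwayhubs simulate | rank |
enrich | respond | network | anticorr | run-all | render`) for running on
real expression tables + GMT gene sets; `run-all` writes a manifest with
content hashes so a rerun under the same seed is verifiably identical.

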