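"""Synthetic perturbation studies with a planted inverted-hub structure.

The generator emulates a liver-perturbation screen of ~43 conditions by
~189 pathways: a minority of "toxicopathological" conditions switch on an
inverted meta-activity profile in which one hub group is activated while
the other is suppressed (Scheme A activates group A, Scheme B activates
group B; most toxic conditions follow Scheme B), while "physiological"
conditions carry no planted signal.  Hub pathways participate in every
toxic condition; planted non-hub group members participate only in a
random subset, so they fall below the hub responsiveness threshold but
still show the group's sign where they respond.  Background pathways have
no planted signal anywhere.

Everything is realized down to gene-level replicated expression: member
genes of pathway p in condition c have treated mean m(p, c) * effect_size
against control mean 0, plus i.i.d. Gaussian noise; genes belong to exactly
one pathway (the default), with the remainder unannotated.  A fast path
(:func:`simulate_nes_matrix`) emits a NES matrix directly for tests that do
not need the gene level.

All randomness flows through substreams derived from ``config.seed``, so
every output is reproducible and stages are independent of each other's
execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .enrichment import NESMatrix
from .io_formats import ExpressionExperiment, GeneSetCollection

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_meta_activity",
    "planted_gene_sets",
    "simulate_expression",
    "simulate_nes_matrix",
    "simulate_study",
    "Study",
]


@dataclass
class SimulationConfig:
    """Study-design knobs for the generator.

    Defaults mirror the emulated study: 189 pathways × 43 conditions, 20 of
    them toxicopathological, 16 hubs split 8/8, triplicate treated and
    control groups, unit-variance log-ratio noise.
    """

    n_genes: int = 8000
    n_pathways: int = 189
    genes_per_pathway: tuple[int, int] = (10, 30)
    n_conditions: int = 43
    n_toxic_conditions: int = 20
    n_hubs_A: int = 8
    n_hubs_B: int = 8
    effect_size: float = 1.2  # mean log-expression shift per unit severity
    noise_sd: float = 1.0
    n_replicates: int = 3
    background_fraction: float = 0.6
    seed: int = 0
    scheme_b_fraction: float = 0.8  # most toxic conditions follow Scheme B
    member_participation: float = 0.35  # per-condition response rate of non-hub members
    severity_range: tuple[float, float] = (0.5, 1.5)

    def __post_init__(self) -> None:
        if self.n_hubs_A + self.n_hubs_B > self.n_pathways:
            raise ValueError("more hubs than pathways")
        if self.n_toxic_conditions > self.n_conditions:
            raise ValueError("more toxic conditions than conditions")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per group")
        if not 0 <= self.background_fraction <= 1:
            raise ValueError("background_fraction must be in [0, 1]")
        lo, hi = self.genes_per_pathway
        if not 1 <= lo <= hi:
            raise ValueError("invalid genes_per_pathway range")
        n_bg = round(self.background_fraction * self.n_pathways)
        if self.n_pathways - n_bg < self.n_hubs_A + self.n_hubs_B:
            raise ValueError(
                "background_fraction leaves too few pathways for the hubs"
            )

    @property
    def pathway_names(self) -> list[str]:
        width = len(str(self.n_pathways))
        return [f"pw{i:0{width}d}" for i in range(1, self.n_pathways + 1)]

    @property
    def condition_names(self) -> list[str]:
        width = len(str(self.n_conditions))
        return [f"cond{i:0{width}d}" for i in range(1, self.n_conditions + 1)]


@dataclass
class SimulationTruth:
    """Planted ground truth: group labels, condition states, meta-activities."""

    pathway_group: dict[str, str]  # pathway -> "A" | "B" | "background"
    condition_state: dict[str, str]  # condition -> toxic_scheme_A/B | physiological
    planted_meta_activity: pd.DataFrame  # pathway × condition
    is_hub: dict[str, bool] = field(default_factory=dict)

    def hub_pathways(self, group: str | None = None) -> list[str]:
        return [
            p
            for p, hub in self.is_hub.items()
            if hub and (group is None or self.pathway_group[p] == group)
        ]

    def toxic_conditions(self) -> list[str]:
        return [c for c, s in self.condition_state.items() if s != "physiological"]


def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed), spawn_key=tuple(key))
    )


def simulate_meta_activity(config: SimulationConfig) -> SimulationTruth:
    """Plant the pathway × condition meta-activity matrix.

    Toxic condition c draws a severity s(c) ~ U(severity_range); the
    activated group's pathways get +s(c) and the suppressed group's -s(c)
    according to the condition's scheme.  Physiological conditions and
    background pathways are zero everywhere.
    """
    rng = _rng(config, 1)
    pathways = config.pathway_names
    conditions = config.condition_names

    n_bg = round(config.background_fraction * config.n_pathways)
    n_members = config.n_pathways - n_bg - config.n_hubs_A - config.n_hubs_B
    n_members_a = n_members // 2
    group: dict[str, str] = {}
    is_hub: dict[str, bool] = {}
    order = list(rng.permutation(pathways))
    cursor = 0
    for p in order[cursor : cursor + config.n_hubs_A]:
        group[p], is_hub[p] = "A", True
    cursor += config.n_hubs_A
    for p in order[cursor : cursor + config.n_hubs_B]:
        group[p], is_hub[p] = "B", True
    cursor += config.n_hubs_B
    for p in order[cursor : cursor + n_members_a]:
        group[p], is_hub[p] = "A", False
    cursor += n_members_a
    for p in order[cursor : cursor + (n_members - n_members_a)]:
        group[p], is_hub[p] = "B", False
    cursor += n_members - n_members_a
    for p in order[cursor:]:
        group[p], is_hub[p] = "background", False

    toxic = list(rng.permutation(conditions)[: config.n_toxic_conditions])
    n_scheme_b = round(config.scheme_b_fraction * len(toxic)) if toxic else 0
    state: dict[str, str] = {c: "physiological" for c in conditions}
    for i, c in enumerate(toxic):
        state[c] = "toxic_scheme_B" if i < n_scheme_b else "toxic_scheme_A"

    lo, hi = config.severity_range
    m = pd.DataFrame(0.0, index=pathways, columns=conditions)
    for c in toxic:
        s = rng.uniform(lo, hi)
        sign_a = 1.0 if state[c] == "toxic_scheme_A" else -1.0
        for p in pathways:
            g = group[p]
            if g == "background":
                continue
            if not is_hub[p] and rng.random() >= config.member_participation:
                continue
            direction = sign_a if g == "A" else -sign_a
            m.loc[p, c] = direction * s
    return SimulationTruth(
        pathway_group=group,
        condition_state=state,
        planted_meta_activity=m,
        is_hub=is_hub,
    )


def planted_gene_sets(config: SimulationConfig) -> tuple[GeneSetCollection, dict[str, str]]:
    """Assign genes to pathways without replacement; returns (sets, gene->pathway)."""
    rng = _rng(config, 2)
    lo, hi = config.genes_per_pathway
    sizes = rng.integers(lo, hi + 1, size=config.n_pathways)
    if sizes.sum() > config.n_genes:
        raise ValueError(
            f"n_genes={config.n_genes} too small for {config.n_pathways} pathways "
            f"of up to {hi} genes (need {int(sizes.sum())})"
        )
    width = len(str(config.n_genes))
    genes = [f"g{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    shuffled = list(rng.permutation(genes))
    sets: dict[str, list[str]] = {}
    membership: dict[str, str] = {}
    cursor = 0
    for name, size in zip(config.pathway_names, sizes):
        members = sorted(shuffled[cursor : cursor + int(size)])
        cursor += int(size)
        sets[name] = members
        for g in members:
            membership[g] = name
    return GeneSetCollection(sets=sets), membership


def simulate_expression(
    truth: SimulationTruth, config: SimulationConfig
) -> list[ExpressionExperiment]:
    """Gene-level replicated expression for every condition.

    Member genes of pathway p: treated mean m(p, c) * effect_size, control
    mean 0; every value gets independent Gaussian(0, noise_sd) noise.
    """
    _, membership = planted_gene_sets(config)
    width = len(str(config.n_genes))
    genes = [f"g{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    shift_row = np.array(
        [
            truth.planted_meta_activity.loc[membership[g]].to_numpy()
            if g in membership
            else np.zeros(config.n_conditions)
            for g in genes
        ]
    )  # genes × conditions planted meta-activity
    n_rep = config.n_replicates
    experiments = []
    for ci, cond in enumerate(config.condition_names):
        rng = _rng(config, 3, ci)
        values = rng.normal(0.0, config.noise_sd, size=(config.n_genes, 2 * n_rep))
        values[:, :n_rep] += (shift_row[:, ci] * config.effect_size)[:, None]
        samples = [f"{cond}_t{i + 1}" for i in range(n_rep)] + [
            f"{cond}_c{i + 1}" for i in range(n_rep)
        ]
        design = {s: ("treated" if i < n_rep else "control") for i, s in enumerate(samples)}
        experiments.append(
            ExpressionExperiment(
                condition_id=cond,
                values=pd.DataFrame(values, index=genes, columns=samples),
                design=design,
            )
        )
    return experiments


def simulate_nes_matrix(
    truth: SimulationTruth,
    nes_noise_sd: float,
    sig_alpha: float = 0.05,
    power_param: float = 0.9,
    alpha: float = 0.05,
    seed_key: int = 4,
    config: SimulationConfig | None = None,
) -> NESMatrix:
    """Fast fixture: NES = planted meta-activity + Gaussian noise.

    Planted cells are called significant with probability ``power_param``;
    unplanted cells are false positives at rate ``sig_alpha``.  Nominal
    p-values are drawn uniformly below ``alpha`` for significant cells and
    above it otherwise, so downstream p < alpha masks reproduce the calls.
    """
    if nes_noise_sd <= 0:
        raise ValueError("nes_noise_sd must be > 0")
    m = truth.planted_meta_activity
    if config is not None:
        rng = _rng(config, seed_key)
    else:
        rng = np.random.default_rng(np.random.SeedSequence(spawn_key=(seed_key,)))
    nes = m + rng.normal(0.0, nes_noise_sd, size=m.shape)
    planted = m.to_numpy() != 0
    called = np.where(
        planted,
        rng.random(m.shape) < power_param,
        rng.random(m.shape) < sig_alpha,
    )
    pvals = np.where(
        called,
        rng.uniform(0.0, alpha, size=m.shape),
        rng.uniform(alpha, 1.0, size=m.shape),
    )
    return NESMatrix(
        nes=pd.DataFrame(nes, index=m.index, columns=m.columns),
        nominal_p=pd.DataFrame(pvals, index=m.index, columns=m.columns),
        alpha=alpha,
    )


@dataclass
class Study:
    config: SimulationConfig
    truth: SimulationTruth
    gene_sets: GeneSetCollection
    experiments: list[ExpressionExperiment]


def simulate_study(config: SimulationConfig) -> Study:
    """Full gene-level study: truth, planted gene sets, per-condition data."""
    truth = simulate_meta_activity(config)
    gene_sets, _ = planted_gene_sets(config)
    experiments = simulate_expression(truth, config)
    return Study(
        config=config, truth=truth, gene_sets=gene_sets, experiments=experiments
    )
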