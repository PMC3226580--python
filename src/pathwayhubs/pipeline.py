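"""End-to-end orchestration: simulate → rank → enrich → respond → network → anticorr.

:class:`PipelineConfig` collects every threshold of the method in one
validated place.  :func:`analyze_nes` runs everything downstream of a NES
matrix and tolerates degenerate outcomes (no hubs, frustrated sign
structure, no seed conditions) by leaving the corresponding result fields
empty; :func:`run_full` is the strict file-writing driver that aborts with
the failing stage's name and records a manifest with content hashes so a
rerun under the same config and seed is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import anticorrelation as ac
from . import io_formats, network as net, ranking, responsiveness as resp
from .enrichment import NESMatrix, build_nes_matrix, enrich_collection
from .io_formats import ExpressionExperiment, GeneSetCollection
from .synthetic import SimulationConfig, simulate_study

__all__ = [
    "PipelineConfig",
    "AnalysisResult",
    "StageError",
    "rank_condition",
    "rank_and_enrich",
    "analyze_nes",
    "run_study",
    "run_full",
    "render_meta_activity",
]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Every analysis threshold, defaulting to the method's published values."""

    alpha: float = 0.05  # nominal enrichment significance
    min_size: int = 10  # minimum mapped genes per set
    n_perm: int = 1000
    weight: int = 1  # running-sum exponent
    theta_hr: int = 10  # HR responsiveness threshold
    theta_mr: int = 5  # MR responsiveness threshold
    r_min: float = 0.5  # |PCC| edge threshold (strict)
    p_max: float = 1e-4  # correlation p threshold (1e-3 is the documented alternative)
    min_overlap: int = 10  # pairwise-complete overlap for PCC
    theta_resp: int = 10  # hub responsiveness threshold
    theta_deg: int = 10  # hub connectivity threshold
    min_hubs: int = 3  # hubs needed for a group consensus
    min_group_score: int = 3
    anti_threshold: float = 0.7
    seed: int = 0
    p_floor: float = 1e-16
    welch: bool = False
    anchor: str | None = None  # pathway whose side is labelled "A"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_size < 1 or self.n_perm < 1:
            raise ValueError("min_size and n_perm must be >= 1")
        if self.weight not in (0, 1):
            raise ValueError("weight must be 0 or 1")
        if not self.theta_mr < self.theta_hr:
            raise ValueError("theta_mr must be < theta_hr")
        if not 0 <= self.r_min < 1:
            raise ValueError("r_min must be in [0, 1)")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must be in (0, 1]")
        if self.min_overlap < 3:
            raise ValueError("min_overlap must be >= 3")
        if not 0 <= self.anti_threshold <= 1:
            raise ValueError("anti_threshold must be in [0, 1]")

    @classmethod
    def from_dict(cls, values: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**values)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AnalysisResult:
    """Everything computed downstream of the NES matrix."""

    nes_matrix: NESMatrix
    profile: pd.DataFrame  # n_significant, n_conditions, class
    npc_curve: pd.DataFrame
    zscored: pd.DataFrame
    network: net.PathwayNetwork
    hub_flags: pd.Series
    hub_groups: dict[str, str]
    frustrated_edges: list[tuple[str, str]]
    seeds: ac.SeedConditionSet | None
    anticorr: pd.DataFrame | None

    @property
    def hubs(self) -> list[str]:
        return list(self.hub_flags[self.hub_flags].index)


def _condition_seed(root_seed: int, index: int) -> int:
    state = np.random.SeedSequence(
        entropy=int(root_seed), spawn_key=(1000, index)
    ).generate_state(1)[0]
    return int(state % (2**31))


def rank_condition(
    experiment: ExpressionExperiment, cfg: PipelineConfig
) -> io_formats.RankedList:
    return ranking.build_ranked_list(
        experiment, welch=cfg.welch, p_floor=cfg.p_floor
    )


def rank_and_enrich(
    experiments: list[ExpressionExperiment],
    gene_sets: GeneSetCollection,
    cfg: PipelineConfig,
) -> NESMatrix:
    """Per-condition ranking + enrichment, assembled into the NES matrix."""
    results = {}
    for ci, exp in enumerate(experiments):
        ranked = rank_condition(exp, cfg)
        res, _skipped = enrich_collection(
            ranked,
            gene_sets,
            min_size=cfg.min_size,
            n_perm=cfg.n_perm,
            weight=cfg.weight,
            seed=_condition_seed(cfg.seed, ci),
        )
        results[exp.condition_id] = res
    return build_nes_matrix(results, alpha=cfg.alpha)


def analyze_nes(nes_matrix: NESMatrix, cfg: PipelineConfig) -> AnalysisResult:
    """All downstream stages; degenerate outcomes leave fields empty, not raise."""
    profile = resp.responsiveness_profile(
        nes_matrix, theta_hr=cfg.theta_hr, theta_mr=cfg.theta_mr
    )
    curve = resp.npc_curve(profile["n_significant"], len(nes_matrix.conditions))
    zscored = net.zscore_by_condition(nes_matrix)
    pcc, pcc_p = net.pearson_with_p(zscored, min_overlap=cfg.min_overlap)
    graph = net.build_network(pcc, pcc_p, r_min=cfg.r_min, p_max=cfg.p_max)
    graph.node_attrs = profile
    hub_flags = net.identify_hubs(
        profile["n_significant"],
        graph.degree,
        theta_resp=cfg.theta_resp,
        theta_deg=cfg.theta_deg,
    )
    graph.hub_flags = hub_flags
    hubs = list(hub_flags[hub_flags].index)
    hub_groups: dict[str, str] = {}
    frustrated: list[tuple[str, str]] = []
    if hubs:
        hub_groups, frustrated = net.partition_signed(
            graph.subnetwork(hubs), anchor=cfg.anchor
        )
        graph.group = dict(hub_groups)
    seeds = None
    anticorr = None
    if hub_groups and {"A", "B"} <= set(hub_groups.values()):
        try:
            seeds = ac.select_seed_conditions(
                nes_matrix, hub_groups, min_hubs=cfg.min_hubs
            )
        except ValueError:
            seeds = None
        if seeds is not None:
            anticorr = ac.score_all(
                nes_matrix,
                seeds,
                min_group_score=cfg.min_group_score,
                anti_threshold=cfg.anti_threshold,
            )
    return AnalysisResult(
        nes_matrix=nes_matrix,
        profile=profile,
        npc_curve=curve,
        zscored=zscored,
        network=graph,
        hub_flags=hub_flags,
        hub_groups=hub_groups,
        frustrated_edges=frustrated,
        seeds=seeds,
        anticorr=anticorr,
    )


def run_study(
    sim_config: SimulationConfig, cfg: PipelineConfig
) -> tuple["object", AnalysisResult]:
    """Simulate a gene-level study and run the full analysis on it."""
    study = simulate_study(sim_config)
    nes_matrix = rank_and_enrich(study.experiments, study.gene_sets, cfg)
    return study, analyze_nes(nes_matrix, cfg)


# ---------------------------------------------------------------------------
# file-writing driver
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(
    cfg: PipelineConfig,
    out_dir: str | Path,
    experiments: list[ExpressionExperiment] | None = None,
    gene_sets: GeneSetCollection | None = None,
    sim_config: SimulationConfig | None = None,
    nes_matrix: NESMatrix | None = None,
) -> Path:
    """Run every stage and write all outputs plus a hash manifest.

    Inputs are either per-condition experiments + gene sets (or a
    ``sim_config`` to generate them) or, to resume downstream-only, a
    precomputed ``nes_matrix``.  Any stage failure raises
    :class:`StageError` naming the stage; outputs written so far remain.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def save(name: str, writer) -> None:
        path = out / name
        writer(path)
        written[name] = _sha256(path)

    if nes_matrix is None:
        if sim_config is not None:
            try:
                study = simulate_study(sim_config)
            except Exception as exc:
                raise StageError(f"simulate: {exc}") from exc
            experiments, gene_sets = study.experiments, study.gene_sets
            save("planted_sets.gmt", lambda p: io_formats.write_gmt(gene_sets, p))
            save(
                "truth_meta_activity.tsv",
                lambda p: io_formats.write_matrix(
                    study.truth.planted_meta_activity, p
                ),
            )
        if experiments is None or gene_sets is None:
            raise StageError("input: need experiments + gene sets, sim_config, or nes_matrix")
        try:
            results = {}
            for ci, exp in enumerate(experiments):
                ranked = rank_condition(exp, cfg)
                save(
                    f"{exp.condition_id}.rnk",
                    lambda p, r=ranked: io_formats.write_rnk(r, p),
                )
                res, _ = enrich_collection(
                    ranked,
                    gene_sets,
                    min_size=cfg.min_size,
                    n_perm=cfg.n_perm,
                    weight=cfg.weight,
                    seed=_condition_seed(cfg.seed, ci),
                )
                results[exp.condition_id] = res
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"rank/enrich: {exc}") from exc
        nes_matrix = build_nes_matrix(results, alpha=cfg.alpha)
    save("nes.tsv", lambda p: io_formats.write_matrix(nes_matrix.nes, p))
    save("nominal_p.tsv", lambda p: io_formats.write_matrix(nes_matrix.nominal_p, p))

    try:
        result = analyze_nes(nes_matrix, cfg)
    except Exception as exc:
        raise StageError(f"analyze: {exc}") from exc
    save("responsiveness.tsv", lambda p: result.profile.to_csv(p, sep="\t"))
    save("npc_curve.tsv", lambda p: result.npc_curve.to_csv(p, sep="\t", index=False))
    save("pcc.tsv", lambda p: io_formats.write_matrix(result.network.pcc, p))
    save("pcc_p.tsv", lambda p: io_formats.write_matrix(result.network.pcc_p, p))
    save(
        "edges.tsv",
        lambda p: io_formats.export_network(result.network, p, format="edge-list"),
    )
    save(
        "network.graphml",
        lambda p: io_formats.export_network(result.network, p, format="graphml"),
    )
    node_table = result.profile.assign(
        degree=result.network.degree,
        hub=result.hub_flags,
        group=[result.hub_groups.get(p, "") for p in result.profile.index],
    )
    save("nodes.tsv", lambda p: node_table.to_csv(p, sep="\t"))
    if result.anticorr is not None:
        save("anticorrelation.tsv", lambda p: result.anticorr.to_csv(p, sep="\t"))

    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "sim_config": dataclasses.asdict(sim_config) if sim_config else None,
        "outputs": written,
        "counts": {
            "conditions": len(nes_matrix.conditions),
            "pathways": len(nes_matrix.pathways),
            "edges": int(len(result.network.edges)),
            "hubs": int(result.hub_flags.sum()),
            "frustrated_edges": len(result.frustrated_edges),
            "seed_conditions": len(result.seeds.conditions) if result.seeds else 0,
            "anti_correlated": int(result.anticorr["anti_correlated"].sum())
            if result.anticorr is not None
            else 0,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def render_meta_activity(
    nes_matrix: NESMatrix,
    groups: dict[str, str],
    out_png: str | Path | None = None,
    out_tsv: str | Path | None = None,
) -> pd.DataFrame:
    """Plain heatmap of the meta-activity matrix, rows ordered A, B, rest.

    Cell intensity encodes NES sign, saturated where nominally significant,
    neutral (0) where missing.  The exact plotted NES values are also
    emitted as TSV; the return value is that plotted frame.
    """
    order = (
        [p for p in nes_matrix.pathways if groups.get(p) == "A"]
        + [p for p in nes_matrix.pathways if groups.get(p) == "B"]
        + [p for p in nes_matrix.pathways if groups.get(p) not in ("A", "B")]
    )
    plotted = nes_matrix.nes.loc[order]
    if out_tsv is not None:
        io_formats.write_matrix(plotted, out_tsv)
    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        sig = nes_matrix.significant().loc[order].to_numpy()
        sign = np.sign(plotted.fillna(0.0).to_numpy())
        shade = sign * np.where(sig, 2.0, 1.0)
        fig, ax = plt.subplots(
            figsize=(max(4, 0.18 * plotted.shape[1]), max(4, 0.08 * plotted.shape[0]))
        )
        ax.imshow(shade, cmap="bwr", vmin=-2, vmax=2, aspect="auto")
        ax.set_xticks(range(plotted.shape[1]))
        ax.set_xticklabels(plotted.columns, rotation=90, fontsize=5)
        ax.set_yticks([])
        ax.set_xlabel("condition")
        ax.set_ylabel("pathway (A block, B block, rest)")
        fig.tight_layout()
        fig.savefig(out_png, dpi=150)
        plt.close(fig)
    return plotted
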