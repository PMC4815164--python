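"""Scenario-grid construction, replicate orchestration and persistence.

The full design crosses beta_M x beta_I x MAF_M x MAF_I x mtry x the five
interaction models (2*2*2*2*2*5 = 160 scenario cells); evaluating the five
importance measures on each cell gives 800 scenario-measure combinations.
Three special variants are appended: 2 marginal-only SNPs, 2493 noise SNPs,
and the LD-mode panel (all with mtry=50, beta_M=beta_I=0.4, MAF=0.2).

Every replicate is reproducible in isolation: its random streams derive
from (master seed, scenario id, replicate id) through a SeedSequence, so
records can be recomputed or resumed without rerunning the grid.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .forest import grow_forest, oob_accuracy
from .importance import gini_importance, permutation_importance
from .pairwise import (
    effect_pairs,
    jmst,
    jvimp,
    pairwise_permutation_importance,
)
from .ranking import (
    RankSummary,
    capture_fraction,
    detection_fraction,
    marginal_topk,
    rank_items,
)
from .simulate import ScenarioConfig, simulate_dataset

__all__ = [
    "SINGLE_MEASURES",
    "PAIR_MEASURES",
    "ExperimentGrid",
    "ResultRecord",
    "build_grid",
    "scenario_id",
    "run_replicate",
    "run_experiment",
    "summarize_records",
    "plot_topk_curves",
]

SINGLE_MEASURES = ("gini", "permutation")
PAIR_MEASURES = ("ppi", "jmst", "jvimp")

MODELS = ("interaction_only", "modifier_snp", "no_interaction", "redundant", "synergistic")


@dataclass
class ExperimentGrid:
    scenarios: list[ScenarioConfig]
    ids: list[str]
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if len(self.scenarios) != len(self.ids):
            raise ValueError("one id per scenario required")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("scenario ids must be unique")


def scenario_id(s: ScenarioConfig) -> str:
    tag = "ld" if s.ld else f"m{s.n_marginal}n{s.n_noise}"
    return (
        f"{s.model}_bM{s.beta_M}_bI{s.beta_I}"
        f"_fM{s.maf_M}_fI{s.maf_I}_mtry{s.mtry}_{tag}"
    )


def build_grid(
    models=MODELS,
    beta_m_values=(0.4, 0.8),
    beta_i_values=(0.4, 0.8),
    maf_m_values=(0.2, 0.4),
    maf_i_values=(0.2, 0.4),
    mtry_values=(10, 50),
    n_replicates: int = 30,
    n_trees: int = 200,
    include_variants: bool = True,
    scale_factor: float = 1.0,
    **overrides,
) -> ExperimentGrid:
    """Deterministic enumeration of the scenario grid.

    Cell order: model, beta_M, beta_I, MAF_M, MAF_I, mtry (slowest to
    fastest).  Defaults use the desk-scale profile (30 replicates, 200
    trees); the production profile is n_replicates=100, n_trees=500.
    ``scale_factor`` multiplies replicate and tree counts (min 1 each).
    """
    unknown_models = set(models) - set(MODELS)
    if unknown_models:
        raise ValueError(f"unknown models {sorted(unknown_models)}")
    reps = max(1, int(round(n_replicates * scale_factor)))
    trees = max(1, int(round(n_trees * scale_factor)))
    scenarios = []
    for model in models:
        for bm in beta_m_values:
            for bi in beta_i_values:
                for fm in maf_m_values:
                    for fi in maf_i_values:
                        for mtry in mtry_values:
                            scenarios.append(ScenarioConfig(
                                model=model, beta_M=bm, beta_I=bi,
                                maf_M=fm, maf_I=fi, mtry=mtry,
                                n_replicates=reps, n_trees=trees,
                                **overrides,
                            ))
    if include_variants:
        variant_model = models[0] if models else "interaction_only"
        base = dict(
            model=variant_model, maf_M=0.2, maf_I=0.2, mtry=50,
            n_replicates=reps, n_trees=trees,
        )
        base.update(overrides)
        # fixed-parameter variants: fewer marginal SNPs, more noise SNPs
        scenarios.append(ScenarioConfig(beta_M=0.4, beta_I=0.4, n_marginal=2, **base))
        scenarios.append(ScenarioConfig(beta_M=0.4, beta_I=0.4, n_noise=2493, **base))
        # LD variants: the null and all effect-size combinations
        for bm, bi in [(0.0, 0.0)] + [
            (bm, bi) for bm in beta_m_values for bi in beta_i_values
        ]:
            scenarios.append(ScenarioConfig(beta_M=bm, beta_I=bi, ld=True, **base))
    ids = [scenario_id(s) for s in scenarios]
    return ExperimentGrid(scenarios=scenarios, ids=ids, scale_factor=scale_factor)


@dataclass
class ResultRecord:
    """Per-replicate ranks of the target SNPs and pairs, per measure."""

    scenario_id: str
    replicate_id: int
    master_seed: int
    forest_oob_accuracy: float
    interacting_ranks: dict  # measure -> (rank1, rank2), single measures
    marginal_ranks: dict  # measure -> tuple of marginal-SNP ranks
    pair_rank: dict  # measure -> rank of the true pair
    marginal_pair_ranks: dict  # measure -> tuple of marginal-pair ranks

    def to_row(self) -> dict:
        row = {
            "scenario_id": self.scenario_id,
            "replicate_id": self.replicate_id,
            "master_seed": self.master_seed,
            "forest_oob_accuracy": self.forest_oob_accuracy,
        }
        for m in SINGLE_MEASURES:
            row[f"{m}_rank1"], row[f"{m}_rank2"] = self.interacting_ranks[m]
            row[f"{m}_marginal_ranks"] = ";".join(map(str, self.marginal_ranks[m]))
        for m in PAIR_MEASURES:
            row[f"{m}_pair_rank"] = self.pair_rank[m]
            row[f"{m}_marginal_pair_ranks"] = ";".join(
                map(str, self.marginal_pair_ranks[m])
            )
        return row


def _replicate_seed_sequence(
    scen_id: str, replicate_id: int, master_seed: int
) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        entropy=(master_seed, zlib.crc32(scen_id.encode()), replicate_id)
    )


def run_replicate(
    scenario: ScenarioConfig, replicate_id: int, master_seed: int
) -> ResultRecord:
    """Simulate one dataset, grow the forest, compute all five measures and
    rank the targets.  Fully determined by (scenario, replicate, seed)."""
    scen_id = scenario_id(scenario)
    try:
        ss = _replicate_seed_sequence(scen_id, replicate_id, master_seed)
        sim_ss, forest_ss, perm_ss, ppi_ss, jv_ss = ss.spawn(5)
        data = simulate_dataset(scenario, np.random.default_rng(sim_ss))
        X = data.genotypes.values
        y = data.phenotype
        forest = grow_forest(
            X, y, scenario.n_trees, scenario.mtry, np.random.default_rng(forest_ss)
        )
        base_accs = [
            oob_accuracy(t, X, y) for t in forest.trees if t.oob.size
        ]

        roles = data.genotypes.roles
        marg_idx = data.genotypes.columns_with_role("marginal")
        pairs = effect_pairs(roles)
        true_pair_pos = pairs.index((0, 1))
        marg_set = set(marg_idx.tolist())
        marg_pair_pos = [
            i for i, (a, b) in enumerate(pairs) if a in marg_set and b in marg_set
        ]

        single = {
            "gini": gini_importance(forest),
            "permutation": permutation_importance(
                forest, X, y, np.random.default_rng(perm_ss)
            ),
        }
        pairwise = {
            "ppi": pairwise_permutation_importance(
                forest, X, y, pairs, np.random.default_rng(ppi_ss)
            ),
            "jmst": jmst(forest, pairs),
            "jvimp": jvimp(forest, X, y, pairs, np.random.default_rng(jv_ss)),
        }

        interacting_ranks, marginal_ranks = {}, {}
        for m, iv in single.items():
            r = rank_items(iv.scores, iv.direction)
            interacting_ranks[m] = (int(r[0]), int(r[1]))
            marginal_ranks[m] = tuple(int(r[i]) for i in marg_idx)
        pair_rank, marginal_pair_ranks = {}, {}
        for m, pm in pairwise.items():
            r = rank_items(pm.scores, pm.direction)
            pair_rank[m] = int(r[true_pair_pos])
            marginal_pair_ranks[m] = tuple(int(r[i]) for i in marg_pair_pos)

        return ResultRecord(
            scenario_id=scen_id,
            replicate_id=replicate_id,
            master_seed=master_seed,
            forest_oob_accuracy=float(np.mean(base_accs)),
            interacting_ranks=interacting_ranks,
            marginal_ranks=marginal_ranks,
            pair_rank=pair_rank,
            marginal_pair_ranks=marginal_pair_ranks,
        )
    except Exception as exc:  # noqa: BLE001 - annotate with context
        raise RuntimeError(
            f"replicate {replicate_id} of scenario {scen_id} failed: {exc}"
        ) from exc


# ---------------------------------------------------------------------------
# aggregation


def summarize_records(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-replicate rank records into top-k fraction tables.

    Returns one row per (scenario, measure, criterion, k).  Re-running this
    on persisted records reproduces the summary exactly (no simulation).
    """
    out = []
    for scen, grp in records.groupby("scenario_id", sort=True):
        n = len(grp)
        for m in SINGLE_MEASURES:
            ranks = grp[[f"{m}_rank1", f"{m}_rank2"]].to_numpy()
            summ = capture_fraction(ranks, measure=m)
            out.extend(_summary_rows(scen, summ))
            marg = _split_rank_column(grp[f"{m}_marginal_ranks"])
            if marg.shape[1]:
                lo = marg.shape[1]
                summ = marginal_topk(
                    marg, range(lo, lo + 11), measure=m
                )
                out.extend(_summary_rows(scen, summ))
        for m in PAIR_MEASURES:
            summ = detection_fraction(
                grp[f"{m}_pair_rank"].to_numpy(), measure=m
            )
            out.extend(_summary_rows(scen, summ))
            marg = _split_rank_column(grp[f"{m}_marginal_pair_ranks"])
            if marg.shape[1]:
                lo = marg.shape[1]
                summ = marginal_topk(
                    marg, range(lo, lo + 11), measure=m
                )
                out.extend(_summary_rows(scen, summ))
    return pd.DataFrame(out)


def _split_rank_column(col: pd.Series) -> np.ndarray:
    rows = [list(map(int, v.split(";"))) if v else [] for v in col.astype(str)]
    return np.asarray(rows, dtype=int) if rows and rows[0] else np.empty((len(rows), 0), int)


def _summary_rows(scen: str, summ: RankSummary) -> list[dict]:
    return [
        {
            "scenario_id": scen,
            "measure": summ.measure,
            "criterion": summ.criterion,
            "k": int(k),
            "fraction": float(f),
            "n_replicates": summ.n_replicates,
        }
        for k, f in zip(summ.k_values, summ.fractions)
    ]


# ---------------------------------------------------------------------------
# execution


def run_experiment(
    grid: ExperimentGrid,
    output_dir: str | Path,
    master_seed: int = 0,
    resume: bool = False,
    make_plots: bool = True,
) -> pd.DataFrame:
    """Execute every replicate of every scenario, persist records and
    summaries, and write a machine-readable manifest.

    With ``resume=True``, replicates already present in ``records.csv`` are
    kept and only missing ones are executed.  Partial failures keep the
    completed records; the manifest marks incomplete scenarios.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    records_path = out / "records.csv"
    existing = pd.DataFrame()
    if resume and records_path.exists():
        existing = pd.read_csv(records_path)

    rows = [] if existing.empty else existing.to_dict("records")
    done = {
        (r["scenario_id"], r["replicate_id"]) for r in rows
    }
    incomplete: dict[str, str] = {}
    for scen in grid.scenarios:
        scen_id = scenario_id(scen)  # records key on the canonical id
        for rep in range(scen.n_replicates):
            if (scen_id, rep) in done:
                continue
            try:
                rows.append(run_replicate(scen, rep, master_seed).to_row())
            except RuntimeError as exc:
                incomplete[scen_id] = str(exc)
                break
    records = pd.DataFrame(rows)
    records.to_csv(records_path, index=False)
    summaries = summarize_records(records)
    summaries.to_csv(out / "summaries.csv", index=False)
    manifest = {
        "master_seed": master_seed,
        "n_scenarios": len(grid.scenarios),
        "scale_factor": grid.scale_factor,
        "scenarios": [
            {"id": i, "config": s.to_dict()} for s, i in zip(grid.scenarios, grid.ids)
        ],
        "incomplete": incomplete,
        "n_records": len(records),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if make_plots and not summaries.empty:
        plot_topk_curves(
            summaries[summaries.criterion == "capture_both_snps"],
            out / "capture_curves.png",
            ylabel="fraction with both interacting SNPs in top k",
        )
        plot_topk_curves(
            summaries[summaries.criterion == "detect_true_pair"],
            out / "detection_curves.png",
            ylabel="fraction with true pair in top k",
        )
    return summaries


def plot_topk_curves(
    summaries: pd.DataFrame, path: str | Path, ylabel: str = "fraction"
) -> None:
    """One panel per scenario, one line per measure; x = k, y = fraction."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scens = sorted(summaries.scenario_id.unique())
    ncol = min(3, len(scens))
    nrow = int(np.ceil(len(scens) / ncol))
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False, sharey=True
    )
    for ax, scen in zip(axes.ravel(), scens):
        sub = summaries[summaries.scenario_id == scen]
        for m, g in sub.groupby("measure"):
            ax.plot(g.k, g.fraction, marker="o", ms=3, label=m)
        ax.set_title(scen, fontsize=7)
        ax.set_xlabel("k")
        ax.set_ylim(-0.02, 1.02)
        ax.legend(fontsize=6)
    for ax in axes.ravel()[len(scens):]:
        ax.set_visible(False)
    axes[0, 0].set_ylabel(ylabel, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
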