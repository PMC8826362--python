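"""End-to-end pipeline: exclusions -> reversal -> imputation -> screening
-> per-timepoint networks -> centrality/communities -> stability ->
temporal comparison, with every stage's output persisted and a manifest
recording the configuration and per-stage counts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortTable, apply_exclusions, read_cohort_csv, write_cohort_csv
from .comparison import difference_network, edge_weight_correlation, nct_paired
from .estimator import NetworkEstimator
from .model import QolNetworkModel
from .preprocess import default_reversal_rules, impute_copy_mean, missing_summary, reverse_scales
from .screening import select_nodes, spearman_screen
from .stability import DEFAULT_DROP_GRID, stability_report

__all__ = ["PipelineConfig", "run_pipeline", "write_network", "read_network_csv"]


@dataclass
class PipelineConfig:
    """All pipeline settings; defaults are the published analysis settings."""

    cohort_csv: str | None = None
    metadata_yaml: str | None = None
    discontinued_csv: str | None = None   # optional: one subject_id per line
    output_dir: str = "qolnet_output"
    target: str = "global_qol"
    selection_threshold: float = 0.3
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    bootstrap_B: int = 1000
    drop_proportions: tuple = DEFAULT_DROP_GRID
    nct_iterations: int = 5000
    alpha_univariate: float = 0.05
    alpha_comparison: float = 0.005
    display_threshold_network: float = 0.05
    display_threshold_difference: float = 0.04
    clip_imputed: bool = True
    seed: int = 0
    run_stability: bool = True
    run_comparison: bool = True

    def __post_init__(self) -> None:
        checks = [
            (0 < self.selection_threshold < 1, "selection_threshold in (0,1)"),
            (self.gamma >= 0, "gamma >= 0"),
            (self.n_lambda >= 2, "n_lambda >= 2"),
            (0 < self.lambda_min_ratio < 1, "lambda_min_ratio in (0,1)"),
            (self.bootstrap_B >= 1, "bootstrap_B >= 1"),
            (self.nct_iterations >= 1, "nct_iterations >= 1"),
            (0 < self.alpha_univariate < 1, "alpha_univariate in (0,1)"),
            (0 < self.alpha_comparison < 1, "alpha_comparison in (0,1)"),
            (self.display_threshold_network >= 0, "display thresholds >= 0"),
            (self.display_threshold_difference >= 0, "display thresholds >= 0"),
            (self.seed >= 0, "seed >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")
        self.drop_proportions = tuple(float(x) for x in self.drop_proportions)

    def estimator(self) -> NetworkEstimator:
        return NetworkEstimator(
            gamma=self.gamma, n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def write_network(net, path_base, threshold: float = 0.05) -> dict:
    """Persist a network: full + display-filtered edge lists and GraphML.

    The full-precision edge list is always written; the display list keeps
    only edges with |weight| above ``threshold``.  Returns the file paths.
    """
    path_base = Path(path_base)
    full = net.edge_list(threshold=0.0)
    display = net.edge_list(threshold=threshold)
    full_path = path_base.with_suffix(".edges.csv")
    disp_path = path_base.with_suffix(".display.csv")
    gml_path = path_base.with_suffix(".graphml")
    full.to_csv(full_path, index=False)
    display.to_csv(disp_path, index=False)
    G = nx.Graph()
    G.add_nodes_from(net.node_names)
    value_col = full.columns[2]  # weight / difference
    for _, r in full.iterrows():
        G.add_edge(r["node_i"], r["node_j"], weight=float(r[value_col]))
    nx.write_graphml(G, gml_path)
    return {"full": str(full_path), "display": str(disp_path), "graphml": str(gml_path)}


def read_network_csv(path, node_names: list[str]) -> np.ndarray:
    """Weight matrix from a full edge-list CSV (round-trip of write_network)."""
    df = pd.read_csv(path)
    idx = {n: i for i, n in enumerate(node_names)}
    W = np.zeros((len(node_names), len(node_names)))
    value_col = df.columns[2]
    for _, r in df.iterrows():
        i, j = idx[r["node_i"]], idx[r["node_j"]]
        W[i, j] = W[j, i] = float(r[value_col])
    return W


def _read_discontinued(path) -> set:
    ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and line != "subject_id":
                ids.add(line)
    return ids


def run_pipeline(config: PipelineConfig, table: CohortTable | None = None) -> dict:
    """Execute every stage and persist outputs under ``config.output_dir``.

    Pass ``table`` directly or point ``config.cohort_csv`` at a tidy CSV.
    Returns the manifest (also written as ``manifest.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "qolnet",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    # -- load & exclusions -------------------------------------------------
    if table is None:
        if config.cohort_csv is None:
            raise ValueError("pipeline stage 'load': no cohort given")
        table = read_cohort_csv(config.cohort_csv, config.metadata_yaml)
    n_initial = table.n_subjects
    discontinued = (
        _read_discontinued(config.discontinued_csv)
        if config.discontinued_csv
        else set()
    )
    table = apply_exclusions(table, discontinued=discontinued)
    manifest["stages"]["exclusions"] = {
        "subjects_initial": n_initial,
        "discontinued": len(discontinued),
        "subjects_analyzed": table.n_subjects,
    }
    miss = missing_summary(table)
    miss.to_csv(out / "missingness.csv")
    manifest["stages"]["missingness"] = {
        tp: float(miss.loc[tp, "missing_fraction"]) for tp in table.timepoints
    }

    # -- reversal & imputation --------------------------------------------
    rules = default_reversal_rules(table)
    table = reverse_scales(table, rules)
    table, imp_log = impute_copy_mean(
        table, clip=config.clip_imputed, return_log=True
    )
    imp_log.to_csv(out / "imputation_log.csv", index=False)
    write_cohort_csv(table, out / "cohort_imputed.csv")
    manifest["stages"]["preprocess"] = {
        "scales_reversed": [r.scale for r in rules],
        "cells_imputed": int(len(imp_log)),
    }

    # -- univariate screening & node selection -----------------------------
    if config.target not in table.scales:
        raise ValueError(
            f"pipeline stage 'screening': target {config.target!r} not in cohort"
        )
    screen = spearman_screen(table, config.target, threshold=config.selection_threshold)
    screen.to_csv(out / "univariate_screen.csv")
    nodes = select_nodes(screen, config.target, threshold=config.selection_threshold)
    if len(nodes) < 3:
        raise ValueError(
            "pipeline stage 'selection': fewer than 3 nodes pass the filter"
        )
    k = len(nodes)
    manifest["stages"]["selection"] = {
        "nodes": nodes,
        "n_nodes": k,
        "potential_edges": k * (k - 1) // 2,
    }

    # -- per-timepoint networks -------------------------------------------
    estimator_kwargs = dict(
        gamma=config.gamma, n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
    )
    results = {}
    for tp in table.timepoints:
        model = QolNetworkModel.from_cohort(table, tp, nodes, **estimator_kwargs)
        res = model.fit()
        results[tp] = res
        res.correlation.to_frame().to_csv(out / f"correlation_{tp}.csv")
        res.correlation.methods_frame().to_csv(out / f"correlation_methods_{tp}.csv")
        res.network.ebic_path.to_csv(out / f"ebic_path_{tp}.csv", index=False)
        write_network(
            res.network, out / f"network_{tp}",
            threshold=config.display_threshold_network,
        )
        cent = res.centrality()
        cent.to_csv(out / f"centrality_{tp}.csv")
        part = res.communities(seed=config.seed)
        pd.Series(part.labels, name="community").rename_axis("node").to_csv(
            out / f"communities_{tp}.csv"
        )
        manifest["stages"][f"network_{tp}"] = {
            "edges": res.network.edge_count,
            "lambda": res.network.lambda_selected,
            "global_strength": res.network.global_strength,
            "modularity_Q": part.modularity,
            "modularity_algorithm": part.algorithm,
            "n_communities": len(set(part.labels.values())),
            "pd_repaired": bool(res.correlation.pd_repaired),
        }

    # -- stability ---------------------------------------------------------
    if config.run_stability:
        for tp in table.timepoints:
            rep = stability_report(
                table.scores(tp)[nodes],
                estimator=config.estimator(),
                proportions=config.drop_proportions,
                B=config.bootstrap_B,
                seed=config.seed,
            )
            rep.case_drop.curves.to_csv(out / f"stability_curves_{tp}.csv", index=False)
            rep.edge_boot.ci.to_csv(out / f"edge_ci_{tp}.csv", index=False)
            rep.edge_differences.to_csv(out / f"edge_difference_tests_{tp}.csv")
            rep.strength_differences.to_csv(
                out / f"strength_difference_tests_{tp}.csv"
            )
            manifest["stages"][f"stability_{tp}"] = {
                "B": rep.B,
                "cs": {q: (None if np.isnan(v) else v) for q, v in rep.cs.items()},
                "failed_replicates": rep.case_drop.n_failed + rep.edge_boot.n_failed,
            }

    # -- temporal comparison ----------------------------------------------
    if config.run_comparison and len(table.timepoints) == 2:
        tp0, tp1 = table.timepoints
        rho, rho_p = edge_weight_correlation(
            results[tp0].network, results[tp1].network
        )
        nct = nct_paired(
            table, nodes=nodes, estimator=config.estimator(),
            iterations=config.nct_iterations, alpha=config.alpha_comparison,
            seed=config.seed,
        )
        diff = difference_network(
            results[tp0].network, results[tp1].network,
            display_threshold=config.display_threshold_difference,
        )
        write_network(
            diff, out / "difference_network",
            threshold=config.display_threshold_difference,
        )
        nct_summary = {
            "edge_weight_spearman_rho": rho,
            "edge_weight_spearman_p": rho_p,
            "structure_M": nct.m_structure,
            "p_structure": nct.p_structure,
            "global_strength": list(nct.global_strength),
            "p_global_strength": nct.p_global_strength,
            "iterations": nct.iterations,
            "alpha": nct.alpha,
            "n_significant_edges": int(len(nct.significant_edges())),
            "n_significant_strengths": int((nct.strength_p < nct.alpha).sum()),
        }
        with open(out / "nct_summary.json", "w") as fh:
            json.dump(nct_summary, fh, indent=2, sort_keys=True)
        pd.DataFrame(
            {"perm_structure_M": nct.perm_m,
             "perm_global_strength_diff": nct.perm_strength}
        ).to_csv(out / "nct_permutations.csv", index=False)
        nct.strength_p.rename_axis("node").to_csv(out / "nct_strength_p.csv")
        manifest["stages"]["comparison"] = nct_summary

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
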