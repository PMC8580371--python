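"""End-to-end pipeline: EV-miRNA profiling -> target network -> PPI topology
-> randomization nulls.

``run_pipeline`` composes every stage with the parameters of a
:class:`~evmirnet.config.RunConfig`, writes each stage's outputs under the
configured directory, and returns (and writes) a single JSON summary with
the headline quantities: number of detectable miRNAs, EV/intracellular
Pearson R, DE-transcript coverage, up/down mean-degree ratio with Student's
t and permutation p-values, the consensus hub list with miRNA-targeting
counts, and the hubs' betweenness null p-values.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Any

from . import io, nulls, profiling, simulate, targets, topology
from .config import RunConfig, stage_seed

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_inputs"]


def load_inputs(config: RunConfig) -> dict[str, Any]:
    """Read the five input tables, or generate them from the simulate block."""
    if config.input_paths:
        required = ["ct_ev", "ct_ic", "de_table", "interactions", "ppi_edges"]
        missing = [k for k in required if k not in config.input_paths]
        if missing:
            raise ValueError(f"input_paths missing {missing}")
        return {
            "ct_ev": io.read_ct_matrix(config.input_paths["ct_ev"]),
            "ct_ic": io.read_ct_matrix(config.input_paths["ct_ic"]),
            "de_table": io.read_de_table(config.input_paths["de_table"]),
            "interactions": io.read_interactions(config.input_paths["interactions"]),
            "ppi_edges": io.read_ppi_edges(config.input_paths["ppi_edges"]),
            "planted_hubs": None,
        }
    sim = dataclasses.replace(config.simulate, seed=config.seed)
    return simulate.simulate_all(sim)


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict[str, Any]:
    """Execute the full analysis; returns a result bundle.

    The bundle maps stage names to their in-memory products plus a
    ``summary`` dict (also written as ``summary.json``).  Any stage failure
    raises with the stage name; outputs written so far are retained.
    """
    outdir = Path(config.output_dir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {}
    stage = "load_inputs"
    try:
        inputs = load_inputs(config)
        bundle["inputs"] = inputs

        stage = "detect"
        detected_ev = profiling.detect_mirnas(inputs["ct_ev"], config.ct_max, config.min_count)
        detected_ic = profiling.detect_mirnas(inputs["ct_ic"], config.ct_max, config.min_count)

        stage = "normalize"
        rel_ev = profiling.normalize_global_mean(inputs["ct_ev"], detected_ev, config.ct_max)
        rel_ic = profiling.normalize_global_mean(inputs["ct_ic"], detected_ic, config.ct_max)
        bundle["rel_ev"], bundle["rel_ic"] = rel_ev, rel_ic

        stage = "rank"
        ranking = profiling.rank_mirnas(rel_ev)
        bundle["ranking"] = ranking

        stage = "correlate"
        corr = profiling.compartment_correlation(rel_ev, rel_ic)
        bundle["correlation"] = corr

        stage = "filter_targets"
        filtered = targets.filter_top_percent(inputs["interactions"], config.top_pct)

        stage = "build_networks"
        net_both = targets.build_bipartite(detected_ev, inputs["de_table"], filtered, "both")
        net_up = targets.build_bipartite(detected_ev, inputs["de_table"], filtered, "up")
        bundle["net_both"], bundle["net_up"] = net_both, net_up

        stage = "enrichment"
        enr = targets.enrichment_stats(
            net_both,
            inputs["de_table"],
            min_mirna_degree=config.min_mirna_degree,
            include_zero_degree=config.include_zero_degree,
        )
        if not enr.degenerate:
            enr.permutation_p = targets.label_permutation_test(
                net_both,
                inputs["de_table"],
                n_perm=config.n_perm,
                seed=stage_seed(config.seed, "label_permutation"),
                include_zero_degree=config.include_zero_degree,
            )
        bundle["enrichment"] = enr
        top_mirnas = targets.degree_report(net_both, "mirna", 0)
        top_targets_up = targets.degree_report(net_up, "target", 0)

        stage = "ppi_filter"
        ppi_kept = topology.filter_ppi_edges(
            inputs["ppi_edges"], config.ppi_thresholds, config.ppi_channel_mode
        )
        ppi_net = topology.graph_from_edges(ppi_kept)
        bundle["ppi_net"] = ppi_net

        stage = "centralities"
        report = topology.centrality_report(ppi_net)
        bundle["centrality_report"] = report

        stage = "hubs"
        hubset = topology.select_hubs(report, mode=config.hub_mode)
        hubset = topology.crosslink_hubs(hubset, net_both)
        bundle["hubs"] = hubset

        stage = "null_models"
        null_cb = nulls.null_distribution(
            ppi_net,
            "betweenness",
            n_random=config.n_random,
            seed=stage_seed(config.seed, "null_models"),
            n_swaps=config.n_swaps,
        )
        bundle["null_betweenness"] = null_cb
        null_p = null_cb.empirical_p("upper")
        hub_null_p = {h: null_p[h] for h in hubset.hubs if h in null_p}

        stage = "summary"
        summary = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_mirnas_panel": int(inputs["ct_ev"].shape[0]),
            "n_detected_ev": len(detected_ev),
            "n_detected_ic": len(detected_ic),
            "pearson_r_ev_ic": corr.r,
            "pearson_n": corr.n,
            "top_ranked_mirna": ranking.iloc[0]["mirna"],
            "coverage_count": enr.coverage_count,
            "n_de_transcripts": int(len(inputs["de_table"])),
            "coverage_fraction": enr.coverage_fraction,
            "mean_degree_up": enr.mean_degree_up,
            "mean_degree_down": enr.mean_degree_down,
            "degree_ratio_up_down": enr.ratio,
            "t_stat": enr.t_stat,
            "t_df": enr.df,
            "t_p_value": enr.p_value,
            "permutation_p": enr.permutation_p,
            "mean_up_fraction": enr.mean_up_fraction,
            "enrichment_degenerate": enr.degenerate,
            "ppi_nodes": ppi_net.number_of_nodes(),
            "ppi_edges_kept": int(len(ppi_kept)),
            "hubs": hubset.hubs,
            "hub_mirna_counts": hubset.crosslink,
            "hub_betweenness_null_p": hub_null_p,
        }
        bundle["summary"] = summary

        if write_outputs:
            io.write_ct_matrix(inputs["ct_ev"], outdir / "ct_ev.csv")
            io.write_ct_matrix(inputs["ct_ic"], outdir / "ct_ic.csv")
            io.write_de_table(inputs["de_table"], outdir / "de_table.csv")
            io.write_interactions(inputs["interactions"], outdir / "interactions.tsv")
            io.write_ppi_edges(inputs["ppi_edges"], outdir / "ppi_edges.tsv")
            rel_ev.to_csv(outdir / "rel_expr_ev.csv")
            rel_ic.to_csv(outdir / "rel_expr_ic.csv")
            ranking.to_csv(outdir / "mirna_ranking.tsv", sep="\t", index=False)
            top_mirnas.to_csv(outdir / "mirna_degree_report.tsv", sep="\t", index=False)
            top_targets_up.to_csv(outdir / "target_degree_report_up.tsv", sep="\t", index=False)
            io.write_graph(net_both, outdir / "bipartite_both")
            io.write_graph(net_up, outdir / "bipartite_up")
            io.write_graph(ppi_net, outdir / "ppi_filtered")
            report.to_csv(outdir / "centrality_report.tsv", sep="\t")
            null_cb.tidy().to_csv(outdir / "null_betweenness.tsv", sep="\t", index=False)
            io.write_json(
                {"hubs": hubset.hubs, "means": hubset.means, "crosslink": hubset.crosslink},
                outdir / "hubs.json",
            )
            io.write_json(summary, outdir / "summary.json")
            io.write_json({"config": config.to_dict()}, outdir / "run_config.json")
        return bundle
    except Exception as err:
        logger.exception("pipeline failed at stage %r", stage)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
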