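"""Randomized-network significance of the PPI topology.

The observed betweenness of every protein is compared against 40
degree-preserving rewirings of the filtered PPI network (double-edge swaps,
10x|E| attempts each).  Because rewiring preserves each protein's degree,
an empirical p-value below 1/(n_random+1)+epsilon means the protein's
centrality reflects the network's modular wiring, not merely its degree.
"""

import json
from pathlib import Path

from evmirnet import io, nulls, topology
from evmirnet.config import stage_seed

IN = Path("results/inputs")
OUT = Path("results/nulls")
SEED = 1
N_RANDOM = 40


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    edges = io.read_ppi_edges(IN / "ppi_edges.tsv")
    net = topology.graph_from_edges(topology.filter_ppi_edges(edges))

    summary = nulls.null_distribution(
        net, "betweenness", n_random=N_RANDOM, seed=stage_seed(SEED, "null_models")
    )
    pvals = summary.empirical_p("upper")
    q975 = summary.quantiles(0.975)

    summary.tidy().to_csv(OUT / "null_betweenness.tsv", sep="\t", index=False)
    io.write_json(
        {"empirical_p_upper": pvals, "null_q975": q975, "n_random": N_RANDOM},
        OUT / "null_betweenness.json",
    )

    planted = json.loads((IN / "manifest.json").read_text())["planted_hubs"]
    print(f"degree-preserving null: {N_RANDOM} rewired replicates of {net.number_of_edges()} edges")
    min_p = 1.0 / (N_RANDOM + 1)
    for h in planted:
        print(
            f"  planted hub {h}: observed betweenness {summary.observed[h]:.0f}, "
            f"null 97.5% quantile {q975[h]:.0f}, empirical p = {pvals[h]:.3f}"
            + (" (minimum attainable)" if abs(pvals[h] - min_p) < 1e-12 else "")
        )
    n_sig = sum(1 for v in pvals.values() if v <= min_p + 1e-12)
    print(f"proteins whose betweenness beats every rewired replicate: {n_sig}")


if __name__ == "__main__":
    main()
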