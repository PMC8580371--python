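"""Synthetic-data generators with planted ground truth.

Every downstream stage of the pipeline (detectability filtering, global-mean
normalization, EV/intracellular correlation, target-enrichment statistics,
PPI hub selection, randomization nulls) is exercised against data generated
here, so that each estimator has a known quantity to recover:

* ``simulate_ct_profiles`` plants an EV/intracellular correlation on the
  latent abundance scale;
* ``simulate_de_table`` fixes the up/down composition of the DE list;
* ``simulate_interactions`` plants a targeting-rate enrichment for
  upregulated transcripts;
* ``simulate_ppi`` plants cross-module hub proteins in a modular background.

All generators are driven by a single root seed through named substreams, so
one :class:`~evmirnet.config.SimConfig` determines every artifact exactly.
"""

from __future__ import annotations

import logging
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd

from .config import SimConfig, stage_seed

logger = logging.getLogger(__name__)

__all__ = [
    "simulate_ct_profiles",
    "simulate_de_table",
    "simulate_interactions",
    "simulate_ppi",
    "simulate_all",
]


def _mirna_ids(n: int) -> list[str]:
    return [f"hsa-miR-sim-{i + 1:04d}" for i in range(n)]


def _correlated_pair(
    rng: np.random.Generator, n: int, rho: float, sd: float
) -> tuple[np.ndarray, np.ndarray]:
    """Draw two length-``n`` abundance vectors with *empirical* correlation rho.

    The correlation is imposed on the realized sample (Gram-Schmidt
    construction), not just in expectation: the generator plants a ground
    truth for the recovery estimator, and for that purpose the sample itself
    must carry the stated correlation.  For n < 3 the construction is
    under-determined and a population (Cholesky) draw is used instead.
    """
    x = rng.standard_normal(n)
    g = rng.standard_normal(n)
    if n < 3 or abs(rho) == 1.0:
        y = rho * x + np.sqrt(max(0.0, 1.0 - rho**2)) * g
        return sd * x, sd * y
    xc = x - x.mean()
    u = xc / np.linalg.norm(xc)
    gc = g - g.mean()
    go = gc - (gc @ u) * u
    w = go / np.linalg.norm(go)
    scale = np.linalg.norm(xc)
    y = scale * (rho * u + np.sqrt(1.0 - rho**2) * w)
    return sd * x, sd * y


def simulate_ct_profiles(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate EV and intracellular Ct matrices (miRNA x subject).

    A ``detect_fraction`` of the panel is expressed: each expressed miRNA
    gets a latent abundance per compartment (correlated across compartments
    with ``ev_ic_correlation``), plus independent subject-level noise, and
    Ct = ct_detect_mean - abundance (more abundant -> fewer cycles).  The
    remaining miRNAs report the non-detection sentinel Ct in every subject.

    Returns
    -------
    (ct_ev, ct_ic):
        Two DataFrames sharing row index (miRNA ids) and columns (subjects).
    """
    rng = np.random.default_rng(stage_seed(config.seed, "ct_profiles"))
    n, s = config.n_mirnas_total, config.n_subjects
    ids = _mirna_ids(n)
    n_detect = int(round(config.detect_fraction * n))
    detected_idx = rng.choice(n, size=n_detect, replace=False)

    ct_ev = np.full((n, s), config.ct_floor_undetected, dtype=float)
    ct_ic = np.full((n, s), config.ct_floor_undetected, dtype=float)
    if n_detect > 0:
        mu_ev, mu_ic = _correlated_pair(
            rng, n_detect, config.ev_ic_correlation, config.ct_detect_sd
        )
        mu_ic = mu_ic + config.ct_ic_offset
        noise_ev = rng.normal(0.0, config.ct_subject_sd, size=(n_detect, s))
        noise_ic = rng.normal(0.0, config.ct_subject_sd, size=(n_detect, s))
        abund_ev = mu_ev[:, None] + noise_ev
        abund_ic = mu_ic[:, None] + noise_ic
        ct_ev[detected_idx] = np.clip(
            config.ct_detect_mean - abund_ev, 5.0, config.ct_floor_undetected
        )
        ct_ic[detected_idx] = np.clip(
            config.ct_detect_mean - abund_ic, 5.0, config.ct_floor_undetected
        )

    subjects = [f"S{j + 1}" for j in range(s)]
    ev = pd.DataFrame(ct_ev, index=ids, columns=subjects)
    ic = pd.DataFrame(ct_ic, index=ids, columns=subjects)
    ev.index.name = ic.index.name = "mirna"
    return ev, ic


def simulate_de_table(config: SimConfig) -> pd.DataFrame:
    """Generate the differential-expression table (n_up up, n_down down).

    Log2 fold changes are drawn uniform in [0.5, 4] with the sign of the
    direction label; transcript ids are synthetic gene symbols.
    """
    rng = np.random.default_rng(stage_seed(config.seed, "de_table"))
    n_up, n_down = config.n_up, config.n_down
    ids = [f"GENE{i + 1:04d}" for i in range(n_up + n_down)]
    lfc_up = rng.uniform(0.5, 4.0, size=n_up)
    lfc_down = -rng.uniform(0.5, 4.0, size=n_down)
    de = pd.DataFrame(
        {
            "transcript": ids,
            "log2fc": np.concatenate([lfc_up, lfc_down]),
            "direction": ["up"] * n_up + ["down"] * n_down,
        }
    )
    return de


def simulate_interactions(
    mirna_ids: list[str], de_table: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Bernoulli bipartite miRNA-target interactions over the DE list.

    Each (miRNA, transcript) pair is an independent edge with probability
    ``p_up = enrichment_ratio * p_base`` for upregulated transcripts and
    ``p_base`` for downregulated ones.  Records carry a uniform score in
    (0, 100] solely to exercise the top-percent retrieval filter; scores do
    not affect edge existence.
    """
    rng = np.random.default_rng(stage_seed(config.seed, "interactions"))
    p = np.where(de_table["direction"].to_numpy() == "up", config.p_up, config.p_base)
    draws = rng.random((len(mirna_ids), len(de_table))) < p[None, :]
    mi, ti = np.nonzero(draws)
    targets = de_table["transcript"].to_numpy()
    scores = 100.0 * (1.0 - rng.random(mi.size))  # uniform in (0, 100]
    return pd.DataFrame(
        {
            "mirna": np.asarray(mirna_ids, dtype=object)[mi],
            "target": targets[ti],
            "source": "synthdb",
            "score": scores,
        }
    )


def _background_graph(rng: np.random.Generator, config: SimConfig) -> nx.Graph:
    params: dict[str, Any] = dict(config.ppi_model_params)
    model = params.pop("model", "communities")
    n = config.ppi_n_nodes
    gseed = int(rng.integers(2**31))
    if model == "uniform":
        g = nx.gnp_random_graph(n, params.get("p_edge", 0.05), seed=gseed)
    elif model == "attachment":
        g = nx.barabasi_albert_graph(n, params.get("m_attach", 2), seed=gseed)
    elif model == "communities":
        k = params.get("n_communities", 4)
        sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
        p_in, p_out = params.get("p_within", 0.15), params.get("p_between", 0.005)
        probs = [[p_in if i == j else p_out for j in range(k)] for i in range(k)]
        g = nx.stochastic_block_model(sizes, probs, seed=gseed)
        g = nx.Graph(g)  # drop SBM metadata/partition attributes
    else:
        raise ValueError(f"unknown PPI background model {model!r}")
    return nx.relabel_nodes(g, {i: f"PROT{i + 1:04d}" for i in g.nodes})


def simulate_ppi(
    config: SimConfig, node_ids: list[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Generate a PPI edge table with planted hub proteins.

    The background is drawn from the configured generative model (default: a
    planted-partition graph, since protein networks are organized in dense
    modules sparsely linked to each other).  Each of ``n_planted_hubs``
    additional proteins is wired to a random ``hub_attach_fraction`` of the
    background nodes, spanning modules, which makes it central by
    construction.  Every edge carries two evidence-channel scores
    ("experiments", "databases") drawn uniform in [0, 1].

    Parameters
    ----------
    node_ids:
        Optional identifiers to use for the proteins (background nodes first,
        then hubs).  The full pipeline passes DE transcript symbols here so
        that PPI hubs and bipartite-network targets share a namespace, as
        they do when the PPI network is built from the DE gene list.

    Returns
    -------
    (edge_table, hub_ids):
        Edge table with columns protein_a, protein_b, experiments, databases,
        and the list of planted hub node ids.
    """
    rng = np.random.default_rng(stage_seed(config.seed, "ppi"))
    g = _background_graph(rng, config)
    n_needed = config.ppi_n_nodes + config.n_planted_hubs
    if node_ids is not None:
        if len(node_ids) < n_needed:
            raise ValueError(
                f"need {n_needed} node ids (background + hubs), got {len(node_ids)}"
            )
        mapping = dict(zip(sorted(g.nodes), node_ids))
        g = nx.relabel_nodes(g, mapping)
        hubs = list(node_ids[config.ppi_n_nodes : n_needed])
    else:
        hubs = [f"HUB{i + 1:02d}" for i in range(config.n_planted_hubs)]
    background = sorted(g.nodes)
    if not nx.is_connected(g):
        logger.warning(
            "synthetic PPI background is disconnected (%d components)",
            nx.number_connected_components(g),
        )
    k_attach = max(2, int(round(config.hub_attach_fraction * len(background))))
    for h in hubs:
        partners = rng.choice(len(background), size=k_attach, replace=False)
        g.add_edges_from((h, background[j]) for j in partners)

    rows = []
    for a, b in sorted(tuple(sorted(e)) for e in g.edges):
        rows.append((a, b, rng.random(), rng.random()))
    edges = pd.DataFrame(rows, columns=["protein_a", "protein_b", "experiments", "databases"])
    return edges, hubs


def simulate_all(config: SimConfig) -> dict[str, Any]:
    """Generate the complete input bundle for one pipeline run."""
    ct_ev, ct_ic = simulate_ct_profiles(config)
    de = simulate_de_table(config)
    # interactions are drawn for the truly expressed miRNAs (the EV cargo);
    # downstream detection recovers (approximately) this same set
    detected = ct_ev.index[(ct_ev < config.ct_floor_undetected).any(axis=1)].tolist()
    interactions = simulate_interactions(detected, de, config)
    # PPI nodes drawn from the DE transcript namespace (the protein network
    # is built from the DE gene list); hubs take the last ids so they are
    # also bipartite-network targets and the crosslink is exercised
    n_needed = config.ppi_n_nodes + config.n_planted_hubs
    de_ids = de["transcript"].tolist()
    node_ids = de_ids[:n_needed] if len(de_ids) >= n_needed else None
    ppi_edges, hubs = simulate_ppi(config, node_ids=node_ids)
    return {
        "ct_ev": ct_ev,
        "ct_ic": ct_ic,
        "de_table": de,
        "interactions": interactions,
        "ppi_edges": ppi_edges,
        "planted_hubs": hubs,
        "config": config,
    }
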