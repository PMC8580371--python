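"""Configuration objects for the synthetic cohort and the pipeline.

``SimConfig`` holds the dimensions and effect sizes of the simulated study:
a five-subject qPCR panel of 752 miRNAs of which ~8% are expressed, an
EV/intracellular latent correlation of 0.5, a differential-expression list of
231 up- and 129 down-regulated transcripts, a Bernoulli miRNA-target structure
in which upregulated transcripts are targeted at twice the baseline rate, and
a modular protein-protein interaction background with planted cross-module
hubs.  ``RunConfig`` bundles the stage parameters of the full pipeline, whose
defaults are the thresholds used throughout the analysis (Ct < 35 in >= 4/5
subjects, top-20% interaction score filter, PPI evidence-channel cutoffs
0.0031 / 0.36, hub consensus over three centralities).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Any


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"configuration parameter {name!r} must be finite, got {value!r}")


@dataclass
class SimConfig:
    """Dimensions, effect sizes and seed of the synthetic study.

    Attributes
    ----------
    n_mirnas_total:
        Number of miRNAs on the qPCR panel (assay rows), default 752.
    n_subjects:
        Number of donors profiled per compartment, default 5.
    detect_fraction:
        Fraction of panel miRNAs that are truly expressed (will amplify
        below the detection ceiling), default 0.08 (~60/752).
    ct_detect_mean, ct_detect_sd:
        Location and between-miRNA spread of the Ct values of expressed
        miRNAs, in qPCR cycles.
    ct_subject_sd:
        Subject-level (technical + biological replicate) noise sd, in cycles.
    ct_floor_undetected:
        Sentinel Ct reported for non-amplifying wells (qPCR exports report a
        ceiling cycle number rather than a missing value), default 40.0.
    ev_ic_correlation:
        Planted Pearson correlation between the latent EV and intracellular
        abundances of expressed miRNAs, default 0.5.
    ct_ic_offset:
        Additive abundance offset of the intracellular compartment relative
        to EVs (cycles); purely a location shift, default 0.
    n_up, n_down:
        Number of up-/down-regulated transcripts in the DE list (231 / 129).
    p_base:
        Per-(miRNA, transcript) Bernoulli targeting probability for
        downregulated transcripts.
    enrichment_ratio:
        Multiplier giving the targeting probability of upregulated
        transcripts, p_up = enrichment_ratio * p_base.
    ppi_n_nodes:
        Number of background proteins in the synthetic PPI network.
    ppi_model_params:
        Background generative model; ``model`` is one of ``"communities"``
        (planted-partition, the default — PPI networks are modular),
        ``"uniform"`` (Erdos-Renyi) or ``"attachment"`` (Barabasi-Albert),
        with model-specific keys (``n_communities``, ``p_within``,
        ``p_between``; ``p_edge``; ``m_attach``).
    n_planted_hubs:
        Number of extra hub proteins, each wired to a random
        ``hub_attach_fraction`` of the background nodes (across modules).
    hub_attach_fraction:
        Fraction of background nodes each planted hub connects to (>= 0.3).
    seed:
        Root seed; fully determines every generated artifact.
    """

    n_mirnas_total: int = 752
    n_subjects: int = 5
    detect_fraction: float = 0.08
    ct_detect_mean: float = 28.0
    ct_detect_sd: float = 2.0
    ct_subject_sd: float = 0.3
    ct_floor_undetected: float = 40.0
    ev_ic_correlation: float = 0.5
    ct_ic_offset: float = 0.0
    n_up: int = 231
    n_down: int = 129
    p_base: float = 0.05
    enrichment_ratio: float = 2.0
    ppi_n_nodes: int = 150
    ppi_model_params: dict[str, Any] = field(
        default_factory=lambda: {
            "model": "communities",
            "n_communities": 4,
            "p_within": 0.3,
            "p_between": 0.005,
        }
    )
    n_planted_hubs: int = 3
    hub_attach_fraction: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "detect_fraction",
            "ct_detect_mean",
            "ct_detect_sd",
            "ct_subject_sd",
            "ct_floor_undetected",
            "ev_ic_correlation",
            "ct_ic_offset",
            "p_base",
            "enrichment_ratio",
            "hub_attach_fraction",
        ):
            _require_finite(name, float(getattr(self, name)))
        for name in ("n_mirnas_total", "n_subjects", "n_up", "n_down"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0.0 <= self.detect_fraction <= 1.0:
            raise ValueError(f"detect_fraction must lie in [0, 1], got {self.detect_fraction}")
        if not 0.0 <= self.p_base <= 1.0:
            raise ValueError(f"p_base must lie in [0, 1], got {self.p_base}")
        if self.p_base * self.enrichment_ratio > 1.0:
            raise ValueError(
                "p_base * enrichment_ratio must be <= 1 "
                f"(got {self.p_base} * {self.enrichment_ratio} = "
                f"{self.p_base * self.enrichment_ratio})"
            )
        if not -1.0 <= self.ev_ic_correlation <= 1.0:
            raise ValueError(
                f"ev_ic_correlation must lie in [-1, 1], got {self.ev_ic_correlation}"
            )
        if self.n_planted_hubs < 0:
            raise ValueError(f"n_planted_hubs must be >= 0, got {self.n_planted_hubs}")
        if self.ppi_n_nodes < self.n_planted_hubs + 2:
            raise ValueError(
                f"ppi_n_nodes ({self.ppi_n_nodes}) must be >= "
                f"n_planted_hubs + 2 ({self.n_planted_hubs + 2})"
            )
        if self.n_planted_hubs > 0 and self.hub_attach_fraction < 0.3:
            raise ValueError(
                f"hub_attach_fraction must be >= 0.3, got {self.hub_attach_fraction}"
            )

    @property
    def p_up(self) -> float:
        return self.p_base * self.enrichment_ratio

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        return cls(**d)


@dataclass
class RunConfig:
    """Parameters of the full pipeline run.

    Input tables are either read from ``input_paths`` (keys ``ct_ev``,
    ``ct_ic``, ``de_table``, ``interactions``, ``ppi_edges``) or generated
    from the embedded ``simulate`` block when ``input_paths`` is empty.
    """

    input_paths: dict[str, str] = field(default_factory=dict)
    simulate: SimConfig = field(default_factory=SimConfig)
    # profiling
    ct_max: float = 35.0
    min_count: int | None = None  # None -> ceil(0.8 * n_subjects)
    # target network
    top_pct: float = 20.0
    min_mirna_degree: int = 2
    degree_report_mirna_min: int = 30
    degree_report_target_min: int = 30
    include_zero_degree: bool = True
    # PPI topology
    ppi_thresholds: dict[str, float] = field(
        default_factory=lambda: {"experiments": 0.0031, "databases": 0.36}
    )
    ppi_channel_mode: str = "union"  # or "intersection"
    hub_mode: str = "all"  # or "any"
    # null models
    n_random: int = 40
    n_swaps: int | None = None  # None -> 10 * |E|
    n_perm: int = 999
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if isinstance(self.simulate, dict):
            self.simulate = SimConfig(**self.simulate)
        if self.ppi_channel_mode not in ("union", "intersection"):
            raise ValueError(f"ppi_channel_mode must be union|intersection, got {self.ppi_channel_mode}")
        if self.hub_mode not in ("all", "any"):
            raise ValueError(f"hub_mode must be all|any, got {self.hub_mode}")
        if not 0.0 < self.top_pct <= 100.0:
            raise ValueError(f"top_pct must lie in (0, 100], got {self.top_pct}")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        return cls(**d)

    def config_hash(self) -> str:
        # hash of the scientific parameters: where outputs land does not
        # change what is computed
        d = self.to_dict()
        d.pop("output_dir", None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def stage_seed(root_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed below 2**31 from the root seed.

    Stages can be re-run in isolation and still reproduce the full-pipeline
    draw; the derivation is a hash so that neighbouring root seeds do not
    produce overlapping stage streams.
    """
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
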