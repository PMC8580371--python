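"""qPCR miRNA profiling: detectability, global-mean normalization, ranking.

The EV-miRNA cargo panel is a Ct matrix (miRNA x subject, one matrix per
compartment).  A miRNA is *detectable* when it amplifies below a Ct ceiling
in enough subjects (default: Ct < 35 in at least 4 of 5).  Detected miRNAs
are normalized per subject against the global mean Ct of the detected panel,
on the log2 (cycle) scale:

    rel(m, s) = global_mean(s) - Ct(m, s)

so positive values mean more abundant than the panel average.  Per-miRNA
mean relative expression orders the panel from most to least expressed, and
the EV versus intracellular agreement is summarized as the Pearson
correlation of the two mean-relative-expression vectors over the shared
detected miRNAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "detect_mirnas",
    "normalize_global_mean",
    "rank_mirnas",
    "compartment_correlation",
    "CorrelationResult",
]


def default_min_count(n_subjects: int) -> int:
    """Detectability support default: at least 80% of subjects (4 of 5)."""
    return math.ceil(0.8 * n_subjects)


def detect_mirnas(
    ct: pd.DataFrame, ct_max: float = 35.0, min_count: int | None = None
) -> set[str]:
    """Return the set of miRNAs with Ct strictly below ``ct_max`` in at
    least ``min_count`` subjects.

    ``min_count`` defaults to ceil(0.8 * n_subjects), i.e. 4 of 5.
    """
    n_subjects = ct.shape[1]
    if min_count is None:
        min_count = default_min_count(n_subjects)
    if not 1 <= min_count <= n_subjects:
        raise ValueError(
            f"min_count ({min_count}) must lie in [1, n_subjects={n_subjects}]"
        )
    hits = (ct < ct_max).sum(axis=1)
    return set(ct.index[hits >= min_count])


def normalize_global_mean(
    ct: pd.DataFrame, detected: set[str], ct_max: float = 35.0
) -> pd.DataFrame:
    """Global-mean normalization of detected miRNAs, per subject.

    For each subject the global mean is the mean Ct over detected miRNAs
    that amplify (Ct < ct_max) in that subject; the relative expression of
    miRNA m is ``global_mean(s) - Ct(m, s)``.  Cells where m does not
    amplify in s are NaN and excluded from all means, so the present values
    of each subject sum to zero by construction.
    """
    missing = detected - set(ct.index)
    if missing:
        raise ValueError(f"detected ids absent from Ct matrix: {sorted(missing)[:5]}")
    if len(detected) < 2:
        raise ValueError(f"need at least 2 detected miRNAs, got {len(detected)}")
    sub = ct.loc[sorted(detected)].astype(float)
    present = sub < ct_max
    n_present = present.sum(axis=0)
    low = n_present[n_present < 2]
    if not low.empty:
        raise ValueError(
            f"subject(s) with fewer than 2 amplifying detected miRNAs: {list(low.index)}"
        )
    vals = sub.where(present)
    rel = vals.mean(axis=0) - vals
    return rel


def rank_mirnas(rel: pd.DataFrame) -> pd.DataFrame:
    """Rank miRNAs by mean relative expression, most expressed first.

    Ties are broken lexicographically by miRNA id so the ordering is
    deterministic.  Returns columns (mirna, mean_rel_expr, rank).
    """
    if rel.empty:
        raise ValueError("relative-expression matrix is empty")
    means = rel.mean(axis=1, skipna=True)
    out = (
        means.rename("mean_rel_expr")
        .rename_axis("mirna")
        .reset_index()
        .sort_values(["mean_rel_expr", "mirna"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int


def compartment_correlation(
    rel_ev: pd.DataFrame, rel_ic: pd.DataFrame
) -> CorrelationResult:
    """Pearson correlation of per-miRNA mean relative expression between
    compartments, over the miRNAs detected in both.

    One point per miRNA (the across-subject mean), so the returned R is a
    single panel-level agreement index.
    """
    mean_ev = rel_ev.mean(axis=1, skipna=True)
    mean_ic = rel_ic.mean(axis=1, skipna=True)
    shared = mean_ev.index.intersection(mean_ic.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 miRNAs detected in both compartments, got {len(shared)}")
    x = mean_ev.loc[shared].to_numpy()
    y = mean_ic.loc[shared].to_numpy()
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in a compartment's mean expression vector")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=len(shared))
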