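"""Carbon response factor (CRF) computation and group assignment.

The CRF of a gene is the unweighted mean of its log2 fold changes across a
panel of reference sugar-manipulation contrasts; its sign encodes induction
(+) or repression (-) by high sugar.  Genes responding in the induced-TPS
contrast are partitioned by comparing their response sign with the CRF:

* G1 -- same sign as the CRF (inferred direct Tre6P effect),
* G2 -- opposite sign (inferred indirect / low-sugar effect),
* G0 -- |CRF| at or below the threshold, or no usable CRF
        (sugar-unresponsive),
* unassigned -- genes failing the responsiveness filter.

A relaxed CRF magnitude threshold (|CRF| > 0.1, strict inequality, applied
two-sidedly) maximizes assignment to G1/G2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ContrastResult

__all__ = [
    "compute_crf",
    "flag_context_dependent",
    "assign_group",
    "group_summary",
    "GROUPS",
]

GROUPS = ("G1", "G2", "G0", "unassigned")


def compute_crf(panel: pd.DataFrame, min_obs: int = 3) -> pd.DataFrame:
    """Per-gene CRF: arithmetic mean over the observed panel contrasts.

    Missing cells (NaN) are skipped, never treated as zero.  Genes with
    fewer than ``min_obs`` observed contrasts get no CRF (NaN) and remain
    eligible only for G0.  Returns columns ``crf`` and ``n_obs``.
    """
    if min_obs < 1:
        raise ValueError("min_obs must be >= 1")
    if panel.shape[1] < 1:
        raise ValueError("response panel needs at least one contrast")
    n_obs = panel.notna().sum(axis=1).astype(int)
    crf = panel.mean(axis=1, skipna=True)
    crf[n_obs < min_obs] = np.nan
    out = pd.DataFrame({"crf": crf, "n_obs": n_obs})
    out.index.name = "gene_id"
    return out


def flag_context_dependent(panel_row, thr: float) -> bool:
    """True iff the row responds in opposing directions at magnitude thr.

    Some observed value >= +thr AND some observed value <= -thr (both
    inclusive); missing values are ignored.
    """
    if thr <= 0:
        raise ValueError("context-dependence threshold must be positive")
    vals = np.asarray(pd.Series(panel_row).dropna(), dtype=float)
    if vals.size == 0:
        return False
    return bool((vals >= thr).any() and (vals <= -thr).any())


def flag_context_dependent_panel(panel: pd.DataFrame, thr: float) -> pd.Series:
    """Vectorized :func:`flag_context_dependent` over a whole panel."""
    if thr <= 0:
        raise ValueError("context-dependence threshold must be positive")
    up = (panel >= thr).any(axis=1)
    down = (panel <= -thr).any(axis=1)
    flag = up & down
    flag.name = "context_dependent"
    return flag


def assign_group(
    itps: ContrastResult,
    crf: pd.DataFrame,
    responsiveness: str = "relaxed",
    crf_threshold: float = 0.1,
    absent_panel_policy: str = "g0",
) -> pd.DataFrame:
    """Assign every gene of the iTPS contrast to exactly one group.

    Genes failing the chosen responsiveness filter are unassigned.  For a
    responsive gene: |CRF| > crf_threshold with matching sign gives G1,
    opposing sign gives G2; |CRF| <= crf_threshold or no CRF gives G0.
    Responsive genes absent from the panel default to G0 with ``in_panel``
    False (set ``absent_panel_policy="unassigned"`` to leave them out).

    Returns a CRF-record table: crf, n_obs, in_panel, group.
    """
    if responsiveness not in ("strict", "relaxed"):
        raise ValueError(f"unknown responsiveness mode {responsiveness!r}")
    if absent_panel_policy not in ("g0", "unassigned"):
        raise ValueError(f"unknown absent-panel policy {absent_panel_policy!r}")
    if crf_threshold < 0:
        raise ValueError("crf_threshold must be non-negative")

    genes = itps.table.index
    responsive = itps.table[f"passes_{responsiveness}"].astype(bool).to_numpy()
    fc = itps.table["log2_fc"].to_numpy()

    in_panel = genes.isin(crf.index)
    crf_val = np.full(len(genes), np.nan)
    n_obs = np.zeros(len(genes), dtype=int)
    crf_val[in_panel] = crf.loc[genes[in_panel], "crf"].to_numpy()
    n_obs[in_panel] = crf.loc[genes[in_panel], "n_obs"].to_numpy()

    group = np.full(len(genes), "unassigned", dtype=object)
    has_crf = np.isfinite(crf_val)
    big = has_crf & (np.abs(crf_val) > crf_threshold)
    same = big & (np.sign(crf_val) == np.sign(fc))
    group[responsive] = "G0"
    group[responsive & same] = "G1"
    group[responsive & big & ~same] = "G2"
    if absent_panel_policy == "unassigned":
        group[responsive & ~in_panel] = "unassigned"

    out = pd.DataFrame(
        {
            "crf": crf_val,
            "n_obs": n_obs,
            "in_panel": in_panel,
            "group": pd.Categorical(group, categories=list(GROUPS)),
        },
        index=genes,
    )
    return out


def group_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Counts per group and fractions of assigned among responsive genes.

    Fractions are over G1+G2+G0 (the responsive, assigned genes) and
    reported NaN when no gene was assigned.
    """
    counts = records["group"].value_counts().reindex(list(GROUPS), fill_value=0)
    n_assigned = int(counts[["G1", "G2", "G0"]].sum())
    fractions = pd.Series(np.nan, index=counts.index, dtype=float)
    if n_assigned > 0:
        for g in ("G1", "G2", "G0"):
            fractions[g] = counts[g] / n_assigned
    out = pd.DataFrame({"count": counts.astype(int), "fraction_of_assigned": fractions})
    out.index.name = "group"
    return out
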