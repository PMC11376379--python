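"""PageMan-style functional-category (BIN) display.

Non-significant genes are zeroed (never dropped), then the log2 fold changes
of all member genes of each hierarchical BIN are averaged, zeros included.
A populated BIN in which nothing passes the filter therefore shows exactly
0, while a BIN with no member genes under the current subset shows NA.
Ancestor categories average over the union of their descendants' genes plus
directly assigned genes (cumulative display); a gene mapped to several BINs
contributes to each, but counts once within any one BIN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import BINMap, ContrastResult

__all__ = ["zero_filtered_fc", "bin_average", "build_heatmap", "plot_heatmap"]


def zero_filtered_fc(contrast: ContrastResult, filter: str = "strict") -> pd.Series:
    """Per-gene display FC: log2 FC if the gene passes the filter, else 0."""
    passing = contrast.passing(filter)
    fc = pd.Series(0.0, index=contrast.table.index, name="display_fc")
    fc.loc[passing] = contrast.table.loc[passing, "log2_fc"]
    return fc


def bin_average(
    display_fc: pd.Series,
    binmap: BINMap,
    gene_subset=None,
    cumulative: bool = True,
) -> pd.Series:
    """Mean display FC per category (including implicit ancestors).

    Member genes are restricted to ``gene_subset`` (e.g. one CRF group) when
    given; zeros from the filter are included in the mean.  Categories with
    no members under the subset are NA.
    """
    fc = pd.Series(display_fc).astype(float)
    fc.index = [str(g).strip().upper() for g in fc.index]
    universe = set(fc.index)
    if gene_subset is not None:
        universe &= {str(g).strip().upper() for g in gene_subset}
    out = {}
    for code in binmap.all_codes():
        members = [g for g in binmap.members(code, cumulative=cumulative) if g in universe]
        out[code] = fc.loc[members].mean() if members else np.nan
    result = pd.Series(out, name="mean_display_fc")
    result.index.name = "bincode"
    return result


def build_heatmap(
    contrasts,
    groups: pd.DataFrame | None,
    binmap: BINMap,
    cumulative: bool = True,
    group_order=("G1", "G2", "G0"),
) -> pd.DataFrame:
    """BIN x (group, contrast) matrix of average display fold changes.

    ``contrasts`` is a sequence of (label, display_fc) pairs; ``groups`` is
    a CRF-record table whose ``group`` column partitions the genes (pass
    ``None`` for a single ungrouped column block).  Row order is by BIN
    code; column order is (group, contrast) as configured.
    """
    columns = {}
    if groups is None:
        for label, fc in contrasts:
            columns[("all", label)] = bin_average(fc, binmap, cumulative=cumulative)
    else:
        for group in group_order:
            subset = groups.index[groups["group"].astype(str) == group]
            for label, fc in contrasts:
                columns[(group, label)] = bin_average(
                    fc, binmap, gene_subset=subset, cumulative=cumulative
                )
    heatmap = pd.DataFrame(columns)
    heatmap.columns = pd.MultiIndex.from_tuples(heatmap.columns, names=["group", "contrast"])
    heatmap = heatmap.loc[binmap.all_codes()]
    heatmap.index.name = "bincode"
    return heatmap


def plot_heatmap(heatmap: pd.DataFrame, path, binmap: BINMap | None = None, vmax=None):
    """Render the BIN heatmap with a symmetric diverging color scale."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = heatmap.to_numpy(dtype=float)
    if vmax is None:
        finite = data[np.isfinite(data)]
        vmax = float(np.nanmax(np.abs(finite))) if finite.size else 1.0
        vmax = vmax or 1.0
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * heatmap.shape[1] + 3), max(3, 0.3 * heatmap.shape[0] + 2))
    )
    im = ax.imshow(data, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    labels = heatmap.index
    if binmap is not None:
        labels = [f"{c} {binmap.names.get(c, '')}".strip() for c in heatmap.index]
    ax.set_yticks(range(heatmap.shape[0]), labels=labels, fontsize=7)
    ax.set_xticks(
        range(heatmap.shape[1]),
        labels=[" / ".join(map(str, c)) for c in heatmap.columns],
        rotation=90,
        fontsize=7,
    )
    fig.colorbar(im, ax=ax, label="mean log2 FC (filtered, zeros included)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
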