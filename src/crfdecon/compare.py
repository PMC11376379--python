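"""Cross-dataset concordance between the iTPS response and external signatures.

External vectors (e.g. a transient SnRK1a1-overexpression signature, a
constitutive-TPS response, TORC inactivation) are joined on the gene-id
intersection.  Agreement is quantified two ways: sign concordance (counts
of same-sign, opposite-sign and zero-containing pairs) and an OLS
regression of the iTPS response on the external vector, overall and per
CRF group.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io import ContrastResult

__all__ = [
    "RegressionStats",
    "sign_concordance",
    "response_regression",
    "per_group_comparison",
]


def _paired(vec_a, vec_b):
    a = pd.Series(vec_a).astype(float)
    b = pd.Series(vec_b).astype(float)
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("empty gene-id intersection between the two vectors")
    return a.loc[shared], b.loc[shared]


def sign_concordance(vec_a, vec_b) -> tuple[int, int, int]:
    """(n_same, n_opposite, n_zero) over the paired gene universe.

    n_same counts pairs with equal nonzero signs, n_opposite pairs with
    opposite nonzero signs, n_zero pairs where either member is exactly 0
    (zeros are "did not respond" and are never tie-broken into a direction).
    The three counts sum to the paired count; negating one argument swaps
    n_same and n_opposite exactly.
    """
    a, b = _paired(vec_a, vec_b)
    sa = np.sign(a.to_numpy())
    sb = np.sign(b.to_numpy())
    nz = (sa != 0) & (sb != 0)
    n_same = int(np.sum(nz & (sa == sb)))
    n_opposite = int(np.sum(nz & (sa == -sb)))
    n_zero = int(np.sum(~nz))
    return n_same, n_opposite, n_zero


@dataclasses.dataclass(frozen=True)
class RegressionStats:
    r_squared: float
    slope: float
    intercept: float
    p_value: float
    n: int


def response_regression(vec_a, vec_b) -> RegressionStats:
    """OLS of vec_a (response) on vec_b (predictor).

    r_squared is the squared Pearson correlation; the p-value is the
    two-sided test of slope = 0.  Requires >= 3 paired genes and nonzero
    variance in the predictor.
    """
    a, b = _paired(vec_a, vec_b)
    if len(a) < 3:
        raise ValueError(f"need >= 3 paired genes for a regression, got {len(a)}")
    if np.allclose(b.to_numpy(), b.to_numpy()[0]):
        raise ValueError("predictor vector has zero variance")
    fit = stats.linregress(b.to_numpy(), a.to_numpy())
    return RegressionStats(
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        n=int(len(a)),
    )


def per_group_comparison(
    itps,
    external: pd.Series,
    groups: pd.DataFrame | None,
    filter: str = "relaxed",
) -> pd.DataFrame:
    """Concordance and regression per gene set in {all, G1, G2, G0}.

    ``itps`` is a ContrastResult (its genes are restricted to those passing
    the chosen filter) or a bare per-gene log2 FC Series (used as-is, e.g. a
    planted ground-truth response).  Genes missing from the group table fall
    only into the "all" row.  Sets with < 3 usable pairs get NA statistics.
    """
    if isinstance(itps, ContrastResult):
        vec = itps.table.loc[itps.passing(filter), "log2_fc"]
    else:
        vec = pd.Series(itps).astype(float)
    rows = {}
    sets: dict[str, pd.Index] = {"all": vec.index}
    if groups is not None:
        for g in ("G1", "G2", "G0"):
            members = groups.index[groups["group"].astype(str) == g]
            sets[g] = vec.index.intersection(members)
    for name, genes in sets.items():
        sub = vec.loc[genes]
        shared = sub.index.intersection(external.index)
        row = {
            "n_genes": int(len(shared)),
            "n_same": np.nan,
            "n_opposite": np.nan,
            "n_zero": np.nan,
            "r_squared": np.nan,
            "slope": np.nan,
            "p_value": np.nan,
        }
        if len(shared) > 0:
            n_same, n_opp, n_zero = sign_concordance(sub.loc[shared], external.loc[shared])
            row.update(n_same=n_same, n_opposite=n_opp, n_zero=n_zero)
        if len(shared) >= 3:
            ext = external.loc[shared].to_numpy()
            if not np.allclose(ext, ext[0]):
                reg = response_regression(sub.loc[shared], external.loc[shared])
                row.update(r_squared=reg.r_squared, slope=reg.slope, p_value=reg.p_value)
        rows[name] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out = out.loc[[k for k in ("all", "G1", "G2", "G0") if k in rows]]
    out.index.name = "gene_set"
    return out
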