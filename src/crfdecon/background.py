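"""Removal of ethanol/empty-vector (alcR) off-target effects.

Two modes mirror the two experimental arms:

* array-era residualization -- regress the iTPS ethanol-minus-water
  difference on the alcR difference gene-by-gene and subtract the fitted
  component, leaving the corrected signal orthogonal to the off-target
  predictor;
* RNAseq-era flagging -- list genes passing the strict DEG filter in BOTH
  the iTPS and alcR contrasts, split by direction, and mark the
  same-direction genes for omission from all downstream analyses.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import ContrastResult

__all__ = [
    "OffTargetModel",
    "SharedDEGReport",
    "fit_offtarget_model",
    "correct_itps",
    "flag_shared_degs",
]


@dataclasses.dataclass(frozen=True)
class OffTargetModel:
    """OLS of the iTPS difference on the alcR (off-target) difference."""

    beta: float
    intercept: float
    r_squared: float
    n_genes: int
    fit_intercept: bool


def _align(delta_itps: pd.Series, delta_alcr: pd.Series):
    a = pd.Series(delta_itps).astype(float)
    b = pd.Series(delta_alcr).astype(float)
    missing = a.index.symmetric_difference(b.index)
    if len(missing):
        raise ValueError(
            f"gene universes differ; {len(missing)} unmatched gene(s), "
            f"e.g. {list(missing[:5])}"
        )
    b = b.loc[a.index]
    return a, b


def fit_offtarget_model(
    delta_itps: pd.Series,
    delta_alcr: pd.Series,
    fit_intercept: bool = False,
) -> OffTargetModel:
    """Fit the linear off-target model by ordinary least squares.

    Differences are already centered contrasts, so the default fit has no
    intercept; an intercept can be requested by flag.  Requires >= 10 paired
    genes and nonzero variance in the alcR predictor.
    """
    y, x = _align(delta_itps, delta_alcr)
    if len(y) < 10:
        raise ValueError(f"need >= 10 genes to fit the off-target model, got {len(y)}")
    if np.allclose(x.to_numpy(), x.to_numpy()[0]):
        raise ValueError(
            "alcR differences have zero variance; no off-target model can be fitted"
        )
    design = sm.add_constant(x.to_numpy()) if fit_intercept else x.to_numpy()[:, None]
    fit = sm.OLS(y.to_numpy(), design).fit()
    if fit_intercept:
        intercept, beta = float(fit.params[0]), float(fit.params[1])
    else:
        intercept, beta = 0.0, float(fit.params[0])
    r2 = float(min(max(fit.rsquared, 0.0), 1.0))
    return OffTargetModel(
        beta=beta,
        intercept=intercept,
        r_squared=r2,
        n_genes=int(len(y)),
        fit_intercept=fit_intercept,
    )


def correct_itps(
    delta_itps: pd.Series,
    delta_alcr: pd.Series,
    model: OffTargetModel,
) -> pd.Series:
    """Subtract the fitted off-target component from the iTPS differences.

    corrected[g] = delta_itps[g] - beta * delta_alcr[g] (- intercept when the
    model was fitted with one).  By OLS orthogonality the corrected vector
    has zero slope against the alcR differences, so re-correcting with a
    refitted model is an identity up to numerical noise.
    """
    y, x = _align(delta_itps, delta_alcr)
    corrected = y - model.beta * x - model.intercept
    corrected.name = "corrected_log2_fc"
    return corrected


@dataclasses.dataclass
class SharedDEGReport:
    """Genes passing the strict filter in both the iTPS and alcR contrasts.

    ``table`` columns: itps_log2_fc, alcr_log2_fc, same_direction.
    ``excluded`` lists the same-direction genes, which are omitted from all
    downstream analyses; opposite-direction shared genes are only reported.
    """

    table: pd.DataFrame
    excluded: pd.Index

    @property
    def n_shared(self) -> int:
        return int(len(self.table))

    @property
    def n_same_direction(self) -> int:
        return int(self.table["same_direction"].sum())


def flag_shared_degs(
    itps_contrast: ContrastResult,
    alcr_contrast: ContrastResult,
) -> SharedDEGReport:
    """Report DEGs shared between the iTPS and alcR ethanol responses.

    Both contrasts must have been called at the same thresholds.  Exclusion
    only ever removes genes; no statistic is altered.
    """
    if itps_contrast.thresholds != alcr_contrast.thresholds:
        raise ValueError(
            "iTPS and alcR contrasts were called at different thresholds: "
            f"{itps_contrast.thresholds} vs {alcr_contrast.thresholds}"
        )
    shared = itps_contrast.passing("strict").intersection(alcr_contrast.passing("strict"))
    shared = pd.Index(sorted(shared), name="gene_id")
    itps_fc = itps_contrast.table.loc[shared, "log2_fc"]
    alcr_fc = alcr_contrast.table.loc[shared, "log2_fc"]
    same = np.sign(itps_fc.to_numpy()) == np.sign(alcr_fc.to_numpy())
    table = pd.DataFrame(
        {
            "itps_log2_fc": itps_fc.to_numpy(),
            "alcr_log2_fc": alcr_fc.to_numpy(),
            "same_direction": same,
        },
        index=shared,
    )
    excluded = shared[same]
    return SharedDEGReport(table=table, excluded=excluded)
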