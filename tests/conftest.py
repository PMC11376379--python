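"""Shared fixtures: a hand-written miniature dataset and one session-scoped
pipeline run on the default synthetic experiment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from crfdecon.io import CountMatrix
from crfdecon.pipeline import DEFAULT_CONFIG, run_pipeline


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 genes x 4 samples, two replicates each of treated/control."""
    counts = pd.DataFrame(
        {
            "s1": [10, 0, 50],
            "s2": [12, 0, 48],
            "s3": [40, 0, 50],
            "s4": [44, 0, 52],
        },
        index=["AT1G01010", "AT1G01020", "AT1G01030"],
    )
    samples = pd.DataFrame(
        {
            "genotype": ["iTPS"] * 4,
            "treatment": ["water", "water", "ethanol", "ethanol"],
            "timepoint": ["4h"] * 4,
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    libs = pd.Series([1_000_000] * 4, index=samples.index, name="library_size")
    return CountMatrix(counts=counts, samples=samples, library_sizes=libs)


@pytest.fixture
def tiny_lengths() -> pd.Series:
    return pd.Series(
        [1000, 2000, 2500],
        index=pd.Index(["AT1G01010", "AT1G01020", "AT1G01030"], name="gene_id"),
        name="length",
    )


@pytest.fixture(scope="session")
def pipeline_results(tmp_path_factory):
    """One full pipeline run on the default synthetic study conditions."""
    outdir = tmp_path_factory.mktemp("pipeline_default")
    return run_pipeline(dict(DEFAULT_CONFIG), outdir), outdir


@pytest.fixture(scope="session")
def dataset(pipeline_results):
    return pipeline_results[0]["data"]


def make_contrast_table(log2_fc, q_value, thresholds=None):
    """Build a minimal ContrastResult from fold changes and q-values."""
    from crfdecon.io import ContrastResult, Thresholds

    thresholds = thresholds or Thresholds()
    fc = pd.Series(log2_fc, dtype=float)
    q = pd.Series(q_value, index=fc.index, dtype=float)
    sig = q < thresholds.fdr
    table = pd.DataFrame(
        {
            "mean_expr_treated": np.exp2(fc),
            "mean_expr_control": 1.0,
            "log2_fc": fc,
            "stat": fc,
            "p_value": q,
            "q_value": q,
            "testable": True,
            "passes_strict": sig & (fc.abs() >= thresholds.log2_fc_strict),
            "passes_relaxed": sig & (fc.abs() >= thresholds.log2_fc_relaxed),
        }
    )
    return ContrastResult(table=table, thresholds=thresholds)
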