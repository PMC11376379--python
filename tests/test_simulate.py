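"""The planted-truth generator: determinism, class semantics, noise models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crfdecon.crf import compute_crf, flag_context_dependent_panel
from crfdecon.simulate import (
    default_design,
    generate_counts,
    generate_external,
    generate_panel,
    generate_truth,
    simulate_all,
)


class TestGenerateTruth:
    def test_deterministic_class_apportionment(self):
        truth = generate_truth(1000, fractions=(0.2, 0.15, 0.1, 0.02, 0.53), seed=1)
        counts = truth.table["gene_class"].value_counts()
        assert counts["direct"] == 200
        assert counts["indirect"] == 150
        assert counts["orthogonal"] == 100
        assert counts["offtarget"] == 20
        assert counts["null"] == 530

    def test_seed_determinism(self):
        a = generate_truth(500, seed=4)
        b = generate_truth(500, seed=4)
        pd.testing.assert_frame_equal(a.table, b.table)
        pd.testing.assert_frame_equal(a.panel, b.panel)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_truth(100, fractions=(0.5, 0.2, 0.1, 0.05, 0.05))

    def test_class_sign_semantics(self):
        truth = generate_truth(2000, seed=5).table
        direct = truth[truth.gene_class == "direct"]
        indirect = truth[truth.gene_class == "indirect"]
        orth = truth[truth.gene_class == "orthogonal"]
        null = truth[truth.gene_class == "null"]
        assert (np.sign(direct.true_crf) == np.sign(direct.true_itps_log2fc)).all()
        assert (np.sign(indirect.true_crf) == -np.sign(indirect.true_itps_log2fc)).all()
        assert (direct.true_itps_log2fc.abs() >= 1.0).all()
        assert (orth.true_crf.abs() <= 0.05).all()
        assert (orth.true_itps_log2fc != 0).all()
        assert (null.true_itps_log2fc == 0).all()

    def test_context_rows_preserve_the_row_mean(self):
        truth = generate_truth(2000, seed=6)
        ctx = truth.table.index[truth.table.context_dependent]
        assert len(ctx) > 0
        np.testing.assert_allclose(
            truth.panel.loc[ctx].mean(axis=1), truth.table.loc[ctx, "true_crf"], atol=1e-12
        )


class TestGenerateCounts:
    def test_negative_theta_rejected(self):
        truth = generate_truth(50, seed=1)
        with pytest.raises(ValueError, match="theta"):
            generate_counts(truth, theta=-1e-6)

    def test_seed_determinism(self):
        truth = generate_truth(100, seed=2)
        a = generate_counts(truth, seed=3)
        b = generate_counts(truth, seed=3)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_library_sizes_cover_column_sums(self):
        truth = generate_truth(300, seed=2)
        cm = generate_counts(truth, seed=4)
        assert (cm.library_sizes >= cm.counts.sum(axis=0)).all()

    def test_theta_zero_is_binomial(self):
        # pooled dispersion statistic over null genes ~ chi2 with G*(m-1) df
        truth = generate_truth(1000, fractions=(0, 0, 0, 0, 1.0), seed=7)
        design = default_design(timepoints=("4h",), n_replicates=4)
        cell = design[(design.genotype == "iTPS") & (design.treatment == "water")]
        cm = generate_counts(truth, design=cell, theta=0.0, seed=8, depth=1e5)
        x = cm.counts.to_numpy(dtype=float)
        n = cm.library_sizes.to_numpy(dtype=float)
        p_hat = x.sum(axis=1) / n.sum()
        keep = p_hat > 0
        expected = p_hat[keep, None] * n[None, :]
        disp = ((x[keep] - expected) ** 2 / (expected * (1 - p_hat[keep, None]))).sum()
        df = keep.sum() * (x.shape[1] - 1)
        p_val = stats.chi2.sf(disp, df)
        assert 0.01 < p_val or stats.chi2.cdf(disp, df) < 0.99  # not rejected at alpha 0.01

    def test_doubling_depth_shrinks_proportion_error(self):
        # at depth 5e4 and theta 5e-6 (theta*n = 1/4) the overdispersion
        # floor makes the expected se ratio
        # sqrt((1/(2n)+theta)/(1/n+theta)) ~= 0.78 rather than 1/2
        truth = generate_truth(600, fractions=(0, 0, 0, 0, 1.0), seed=9)
        design = default_design(timepoints=("4h",), n_replicates=30)
        cell = design[(design.genotype == "iTPS") & (design.treatment == "water")]

        def median_se(depth, seed):
            cm = generate_counts(truth, design=cell, theta=5e-6, depth=depth, seed=seed)
            p = cm.counts.to_numpy(dtype=float) / cm.library_sizes.to_numpy(dtype=float)
            return np.median(p.std(axis=1, ddof=1) / np.sqrt(p.shape[1]))

        ratio = median_se(1e5, 10) / median_se(5e4, 10)
        assert 0.6 <= ratio <= 0.85

    def test_null_strict_call_rate_is_controlled(self, pipeline_results):
        results, _ = pipeline_results
        truth = results["data"].truth.table
        nulls = truth.index[truth.gene_class == "null"]
        cr = results["contrasts"][("iTPS", "4h")]
        assert cr.table.loc[nulls, "passes_strict"].mean() <= 0.07


class TestGeneratePanel:
    def test_noise_free_panel_recovers_truth_exactly(self):
        truth = generate_truth(500, seed=11)
        panel = generate_panel(truth, noise_sd=0.0, missing_rate=0.0, seed=12)
        crf = compute_crf(panel, min_obs=1)
        plain = ~truth.table.context_dependent
        np.testing.assert_allclose(
            crf.loc[plain.index[plain], "crf"],
            truth.table.loc[plain, "true_crf"][plain.index[plain]],
            atol=1e-12,
        )

    def test_missingness_matches_binomial_expectation(self):
        truth = generate_truth(2000, seed=13)
        panel = generate_panel(truth, missing_rate=0.3, seed=14)
        n_obs = panel.notna().sum(axis=1)
        assert n_obs.mean() == pytest.approx(9 * 0.7, abs=0.2)

    def test_context_dependent_genes_are_flagged(self):
        truth = generate_truth(2000, seed=15)
        panel = generate_panel(truth, noise_sd=0.15, missing_rate=0.1, seed=16)
        flags = flag_context_dependent_panel(panel, thr=truth.effect_scale / 2)
        ctx = truth.table.context_dependent
        assert flags[ctx].mean() >= 0.95

    def test_mismatched_k_rejected(self):
        truth = generate_truth(50, seed=1, k_contrasts=9)
        with pytest.raises(ValueError, match="K="):
            generate_panel(truth, k_contrasts=5)


class TestGenerateExternal:
    def test_reciprocal_mode_is_exact_without_noise(self):
        truth = generate_truth(500, seed=17)
        ext = generate_external(truth, mode="reciprocal", noise_sd=0.0, seed=18)
        direct = truth.genes_of("direct")
        indirect = truth.genes_of("indirect")
        np.testing.assert_allclose(
            ext[direct], -truth.table.loc[direct, "true_itps_log2fc"]
        )
        np.testing.assert_allclose(
            ext[indirect], truth.table.loc[indirect, "true_itps_log2fc"]
        )

    def test_unknown_mode_rejected(self):
        truth = generate_truth(50, seed=1)
        with pytest.raises(ValueError, match="mode"):
            generate_external(truth, mode="anticorrelated")


def test_simulate_all_is_deterministic_and_consistent():
    a = simulate_all(n_genes=200, seed=23)
    b = simulate_all(n_genes=200, seed=23)
    pd.testing.assert_frame_equal(a.counts.counts, b.counts.counts)
    pd.testing.assert_frame_equal(a.panel, b.panel)
    pd.testing.assert_series_equal(a.external, b.external)
    # different seed: same schema, different values
    c = simulate_all(n_genes=200, seed=24)
    assert list(c.counts.counts.columns) == list(a.counts.counts.columns)
    assert not a.counts.counts.equals(c.counts.counts)
    # binmap covers every gene and lengths are positive
    assert set(a.binmap.genes()) <= set(a.truth.gene_ids)
    assert (a.lengths > 0).all()
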