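"""The weighted proportions test, RPKM normalization and DEG calling."""

import numpy as np
import pandas as pd
import pytest

from crfdecon.de import (
    bh_fdr,
    compute_rpkm,
    fit_group_proportions,
    run_contrast,
    weighted_t_test,
    weighted_t_test_arrays,
)
from crfdecon.io import Thresholds
from crfdecon.simulate import (
    default_design,
    generate_counts,
    generate_lengths,
    generate_truth,
    simulate_null_groups,
)


class TestRpkm:
    def test_unit_formula(self, tiny_counts, tiny_lengths):
        rpkm = compute_rpkm(tiny_counts, tiny_lengths)
        # 10 reads, 1 kb transcript, 1e6 library -> RPKM 10
        assert rpkm.loc["AT1G01010", "s1"] == pytest.approx(10.0)
        # 50 reads, 2500 bp, library 1e6 -> 50e9/(2500*1e6) = 20
        assert rpkm.loc["AT1G01030", "s1"] == pytest.approx(20.0)
        assert (rpkm.loc["AT1G01020"] == 0).all()

    def test_linearity_in_counts(self, tiny_counts, tiny_lengths):
        scaled = tiny_counts
        scaled.counts.loc["AT1G01010"] *= 3
        before = compute_rpkm(tiny_counts, tiny_lengths)
        assert before.loc["AT1G01010", "s1"] == pytest.approx(30.0)

    def test_zero_length_rejected(self, tiny_counts, tiny_lengths):
        tiny_lengths["AT1G01010"] = 0
        with pytest.raises(Exception):
            compute_rpkm(tiny_counts, tiny_lengths)


class TestGroupFit:
    def test_identical_replicates_symmetric_weights(self):
        fit = fit_group_proportions([30, 30], [1000, 1000])
        np.testing.assert_allclose(fit.weights, [0.5, 0.5])
        assert fit.p_hat == pytest.approx(0.03)

    def test_underdispersed_theta_clamped_to_zero(self):
        # equal proportions leave zero excess variance over binomial
        fit = fit_group_proportions([30, 60], [1000, 2000])
        assert fit.theta_hat == 0.0
        assert fit.p_hat == pytest.approx(0.03)
        # theta 0 reduces var_hat to the binomial variance of the pooled p
        assert fit.var_hat == pytest.approx(0.03 * 0.97 / 3000)

    def test_moments_match_brute_force(self):
        x = np.array([12.0, 30.0, 19.0, 25.0])
        n = np.array([900.0, 1100.0, 1000.0, 1050.0])
        fit = fit_group_proportions(x, n)
        p = x / n
        p_pool = x.sum() / n.sum()
        pq = p_pool * (1 - p_pool)
        theta = max(p.var(ddof=1) / pq - np.mean(1 / n), 0.0)
        assert fit.theta_hat == pytest.approx(theta)
        w = (1 / (1 / n + theta)) / (1 / (1 / n + theta)).sum()
        assert fit.p_hat == pytest.approx(np.sum(w * p))
        assert fit.var_hat == pytest.approx(pq / np.sum(1 / (1 / n + theta)))

    def test_variance_shrinks_with_replication(self):
        fit2 = fit_group_proportions([30, 60], [1000, 2000])
        fit4 = fit_group_proportions([30, 60, 30, 60], [1000, 2000, 1000, 2000])
        assert fit4.var_hat <= fit2.var_hat


class TestWeightedTTest:
    def test_identical_groups_give_null_result(self):
        stat, p = weighted_t_test(([10, 12], [1000, 1000]), ([10, 12], [1000, 1000]))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_antisymmetry_under_group_swap(self):
        a = ([30, 45, 38], [1000, 1200, 1100])
        b = ([12, 9, 14], [1000, 1100, 900])
        s1, p1 = weighted_t_test(a, b)
        s2, p2 = weighted_t_test(b, a)
        assert s1 == pytest.approx(-s2)
        assert p1 == pytest.approx(p2)
        assert s1 > 0

    def test_untestable_gene_reports_no_evidence(self):
        stat, p = weighted_t_test(([0, 0], [1000, 1000]), ([0, 0], [1000, 1000]))
        assert (stat, p) == (0.0, 1.0)

    def test_null_type_i_error_calibrated(self):
        # identically distributed beta-binomial groups, 4 vs 4
        xA, nA, xB, nB = simulate_null_groups(10_000, 4, theta=0.005, seed=1)
        _, pval, _ = weighted_t_test_arrays(xA, nA, xB, nB)
        alpha = float(np.mean(pval < 0.05))
        assert 0.035 <= alpha <= 0.065


class TestBhFdr:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_degenerate_vectors(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_order_preserving_under_permutation(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm])

    def test_q_at_least_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=200)
        assert (bh_fdr(p) >= p - 1e-15).all()


class TestRunContrast:
    def test_flat_gene_has_no_signal(self, tiny_counts, tiny_lengths):
        res = run_contrast(
            tiny_counts, tiny_lengths,
            "treatment=ethanol,timepoint=4h", "treatment=water,timepoint=4h",
        )
        flat = res.table.loc["AT1G01030"]
        assert abs(flat.log2_fc) < 0.1
        assert flat.p_value > 0.5
        assert not flat.passes_relaxed
        zero = res.table.loc["AT1G01020"]
        assert not zero.testable and zero.p_value == 1.0 and zero.log2_fc == 0.0

    def test_fourfold_change_recovered(self, tiny_counts, tiny_lengths):
        res = run_contrast(
            tiny_counts, tiny_lengths, "treatment=ethanol", "treatment=water"
        )
        # 42 vs 11 mean counts at equal libraries: log2 FC close to 2
        assert res.table.loc["AT1G01010", "log2_fc"] == pytest.approx(2.0, abs=0.15)

    def test_unknown_cell_is_named(self, tiny_counts, tiny_lengths):
        with pytest.raises(ValueError, match="genotype=alcR"):
            run_contrast(tiny_counts, tiny_lengths, "genotype=alcR", "treatment=water")

    def test_strict_implies_relaxed(self, pipeline_results):
        results, _ = pipeline_results
        for cr in results["contrasts"].values():
            tab = cr.table
            assert (tab.passes_strict <= tab.passes_relaxed).all()
            ok = tab.testable
            assert (tab.loc[ok, "q_value"] >= tab.loc[ok, "p_value"] - 1e-12).all()


def _planted_contrast(effect_log2: float, n_genes=600, n_signal=100, seed=11):
    """Counts for one contrast with n_signal planted |log2FC|=effect genes."""
    truth = generate_truth(n_genes, fractions=(0.0, 0.0, 0.0, 0.0, 1.0), seed=seed)
    fc = np.zeros(n_genes)
    rng = np.random.default_rng(seed + 1)
    fc[:n_signal] = rng.choice([-1.0, 1.0], n_signal) * effect_log2
    truth.table["true_itps_log2fc"] = fc
    design = default_design(timepoints=("4h",))
    cm = generate_counts(truth, design=design, seed=seed + 2)
    lengths = generate_lengths(truth.gene_ids, seed=seed + 3)
    res = run_contrast(
        cm, lengths,
        "genotype=iTPS,treatment=ethanol", "genotype=iTPS,treatment=water",
    )
    return truth, res


def test_planted_fourfold_genes_pass_strict_filter():
    truth, res = _planted_contrast(2.0)
    planted = truth.table.index[truth.table.true_itps_log2fc != 0]
    nulls = truth.table.index[truth.table.true_itps_log2fc == 0]
    n_hit = int(res.table.loc[planted, "passes_strict"].sum())
    n_false = int(res.table.loc[nulls, "passes_strict"].sum())
    assert n_hit >= 90
    assert n_false <= 0.1 * max(n_hit + n_false, 1)


def test_power_monotone_in_effect_size():
    rates = []
    for effect in (0.5, 1.0, 2.0):
        truth, res = _planted_contrast(effect)
        planted = truth.table.index[truth.table.true_itps_log2fc != 0]
        rates.append(res.table.loc[planted, "passes_strict"].mean())
    assert rates[0] <= rates[1] <= rates[2]
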