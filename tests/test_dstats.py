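"""Responses, binning, DISCO and permutation interaction tests.

Independent oracles: scipy's one-way ANOVA F for DISCO at exponent 2,
statsmodels' two-way ANOVA for the interaction F on balanced designs,
and brute-force double loops for the distance components.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import f_oneway

from dose.dstats import (
    CONTRAST_NAMES,
    analyze_contrast,
    bin_values,
    compute_response,
    disco_statistic,
    interaction_f_statistic,
    interaction_plot_data,
    permutation_test,
)


def _results_frame(ridge, lasso, enet):
    return pd.DataFrame({
        "mse_ridge": ridge, "mse_lasso": lasso, "mse_enet": enet,
    })


class TestResponses:
    def test_paired_contrast_signs(self):
        res = _results_frame([0.4], [0.9], [0.6])
        assert compute_response(res, "ridge_vs_lasso").values[0] == pytest.approx(0.5)
        assert compute_response(res, "ridge_vs_enet").values[0] == pytest.approx(0.2)
        assert compute_response(res, "lasso_vs_enet").values[0] == pytest.approx(-0.3)

    def test_identical_mse_gives_zero(self):
        res = _results_frame([0.5, 0.7], [0.5, 0.7], [0.5, 0.7])
        for name in ("ridge_vs_lasso", "ridge_vs_enet", "lasso_vs_enet"):
            np.testing.assert_array_equal(compute_response(res, name).values, 0.0)

    def test_absolute_contrast_is_the_mse_column(self):
        res = _results_frame([0.4, 0.8], [0.9, 0.2], [0.6, 0.3])
        np.testing.assert_array_equal(compute_response(res, "abs_lasso").values, [0.9, 0.2])

    def test_unknown_contrast_rejected(self):
        with pytest.raises(ValueError):
            compute_response(_results_frame([1], [1], [1]), "ridge_vs_ols")


class TestBinning:
    def test_boundaries_and_interior(self):
        f = bin_values([100.0, 549.99, 1000.0], 100, 1000, 10)
        assert list(f.labels) == [1, 5, 10]
        assert f.edges[0] == 100 and f.edges[-1] == 1000

    @pytest.mark.parametrize("G", [5, 10, 15])
    def test_equal_widths_any_bin_count(self, G):
        f = bin_values(np.linspace(0, 1, 50), 0, 1, G)
        widths = np.diff(f.edges)
        np.testing.assert_allclose(widths, widths[0])
        assert set(f.labels) <= set(range(1, G + 1))

    @given(
        values=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40),
        G=st.integers(2, 20),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_labels_always_valid_and_consistent(self, values, G):
        f = bin_values(values, 0.0, 1.0, G)
        assert np.all((f.labels >= 1) & (f.labels <= G))
        w = 1.0 / G
        for v, lab in zip(values, f.labels):
            expected = G if v == 1.0 else int(v // w) + 1
            assert lab == min(expected, G)

    def test_values_outside_range_are_an_error(self):
        with pytest.raises(ValueError):
            bin_values([99.0], 100, 1000, 10)
        with pytest.raises(ValueError):
            bin_values([1000.1], 100, 1000, 10)


class TestDisco:
    def test_reduces_to_anova_f_at_exponent_two(self, rng):
        """100 random small instances: alpha-index 2 equals the F statistic."""
        for _ in range(100):
            k = rng.integers(2, 5)
            labels = rng.integers(0, k, 40)
            while np.unique(labels).size < 2:
                labels = rng.integers(0, k, 40)
            y = rng.standard_normal(40)
            F = f_oneway(*[y[labels == g] for g in np.unique(labels)]).statistic
            assert disco_statistic(y, labels, alpha_index=2.0) == pytest.approx(F, abs=1e-10)

    def test_identical_groups_score_zero(self):
        y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert disco_statistic(y, labels, alpha_index=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_two_singletons_diverge_with_warning(self):
        with pytest.warns(UserWarning):
            stat = disco_statistic(np.array([0.0, 2.0]), np.array([0, 1]), alpha_index=1.0)
        assert np.isinf(stat)

    def test_decomposition_matches_energy_between_component(self, rng):
        """T - W equals the between-group energy combination computed
        independently by brute force."""
        y = rng.standard_normal(30)
        labels = rng.integers(0, 3, 30)
        a = 1.0
        N = y.size

        def g(A, B):
            return np.mean(np.abs(A[:, None] - B[None, :]) ** a)

        T = (N / 2) * g(y, y)
        groups = [y[labels == k] for k in np.unique(labels)]
        W = sum((len(A) / 2) * g(A, A) for A in groups)
        S_between = sum(
            ((len(A) * len(B)) / (2 * N)) * (2 * g(A, B) - g(A, A) - g(B, B))
            for A, B in itertools.combinations(groups, 2)
        )
        assert T - W == pytest.approx(S_between, abs=1e-10)
        K = len(groups)
        expected = (S_between / (K - 1)) / (W / (N - K))
        assert disco_statistic(y, labels, a) == pytest.approx(expected, rel=1e-10)

    def test_detects_dispersion_difference(self, rng):
        """Scale-only alternative: N(0,1) vs N(0,9) groups are rejected in
        most seeded reruns (exponent 1 is dispersion-sensitive)."""
        rejections = 0
        reps = 10
        for seed in range(reps):
            r = np.random.default_rng(1000 + seed)
            y = np.concatenate([r.normal(0, 1, 300), r.normal(0, 3, 300)])
            labels = np.repeat([0, 1], 300)
            _, p = permutation_test(
                y, labels, lambda v, lab: disco_statistic(v, lab, 1.0), B=199, rng=r
            )
            rejections += p <= 0.05
        assert rejections >= 0.8 * reps

    def test_location_shift_power(self):
        """Mean shift of one sd with 200 per group: p at the permutation
        floor in essentially every rerun."""
        reps, floor_hits = 10, 0
        for seed in range(reps):
            r = np.random.default_rng(2000 + seed)
            y = np.concatenate([r.normal(0, 1, 200), r.normal(1, 1, 200)])
            labels = np.repeat([0, 1], 200)
            _, p = permutation_test(
                y, labels, lambda v, lab: disco_statistic(v, lab, 1.0), B=199, rng=r
            )
            floor_hits += p == pytest.approx(1 / 200)
        assert floor_hits >= 9


class TestPermutation:
    def test_pvalue_floor_when_observed_dominates(self):
        y = np.concatenate([np.zeros(20), np.ones(20) * 100])
        labels = np.repeat([0, 1], 20)
        stat, p = permutation_test(
            y, labels, lambda v, lab: disco_statistic(v, lab, 2.0),
            B=999, rng=np.random.default_rng(0),
        )
        assert p == pytest.approx(1 / 1000)

    def test_pvalue_one_when_observed_is_minimal(self):
        # constant response: every permuted statistic ties the observed 0
        y = np.ones(20)
        labels = np.repeat([0, 1], 10)
        _, p = permutation_test(
            y, labels, lambda v, lab: disco_statistic(v, lab, 2.0),
            B=99, rng=np.random.default_rng(0),
        )
        assert p == 1.0

    def test_bounds_and_determinism(self, rng):
        y = rng.standard_normal(40)
        labels = rng.integers(0, 4, 40)
        out1 = permutation_test(
            y, labels, lambda v, lab: disco_statistic(v, lab, 1.0),
            B=99, rng=np.random.default_rng(42),
        )
        out2 = permutation_test(
            y, labels, lambda v, lab: disco_statistic(v, lab, 1.0),
            B=99, rng=np.random.default_rng(42),
        )
        assert out1 == out2
        assert 1 / 100 <= out1[1] <= 1.0

    def test_null_pvalues_approximately_uniform(self):
        """Type-I calibration: under a true null the rejection rate at 0.05
        stays within binomial tolerance of 5%."""
        reps, rej = 200, 0
        for seed in range(reps):
            r = np.random.default_rng(3000 + seed)
            y = r.standard_normal(100)
            labels = np.repeat(np.arange(5), 20)
            _, p = permutation_test(
                y, labels, lambda v, lab: disco_statistic(v, lab, 1.0), B=99, rng=r
            )
            rej += p <= 0.05
        # 3.5 binomial sds around 5%
        tol = 3.5 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) < tol


class TestInteractionF:
    def test_parallel_cell_means_give_zero(self, rng):
        A = np.repeat([0, 1], 6)
        B = np.tile(np.repeat([0, 1], 3), 2)
        cell_mean = {(0, 0): 0.0, (0, 1): 1.0, (1, 0): 2.0, (1, 1): 3.0}  # additive
        noise = rng.standard_normal(12) * 0  # exact parallel means, replicate values equal
        y = np.array([cell_mean[(a, b)] for a, b in zip(A, B)]) + noise
        # add within-cell spread that is identical across cells to keep RSS_full > 0
        y = y + np.tile([-0.5, 0.0, 0.5], 4)
        assert interaction_f_statistic(y, A, B) == pytest.approx(0.0, abs=1e-20)

    def test_matches_balanced_two_way_anova(self, rng):
        """Balanced 3x3: agrees with the textbook ANOVA interaction F."""
        for _ in range(5):
            A = np.repeat([0, 1, 2], 12)
            B = np.tile(np.repeat([0, 1, 2], 4), 3)
            y = rng.standard_normal(36) + 0.5 * A * B
            mine = interaction_f_statistic(y, A, B)
            df = pd.DataFrame({"y": y, "A": A.astype(str), "B": B.astype(str)})
            fit = smf.ols("y ~ C(A)*C(B)", df).fit()
            ref = sm.stats.anova_lm(fit, typ=2).loc["C(A):C(B)", "F"]
            assert mine == pytest.approx(ref, abs=1e-8)

    def test_zero_within_cell_noise_diverges(self):
        A = np.repeat([0, 1], 6)
        B = np.tile(np.repeat([0, 1], 3), 2)
        cell_mean = {(0, 0): 0.0, (0, 1): 1.0, (1, 0): 2.0, (1, 1): 5.0}  # non-additive
        y = np.array([cell_mean[(a, b)] for a, b in zip(A, B)])
        with pytest.warns(UserWarning):
            stat = interaction_f_statistic(y, A, B)
        assert np.isinf(stat)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError):
            interaction_f_statistic(np.arange(4.0), [0, 0, 1, 1], [0, 1, 0, 1])  # df_resid = 0

    def test_unbalanced_cells_supported(self, rng):
        A = np.array([0] * 7 + [1] * 5)
        B = np.array([0, 0, 0, 1, 1, 1, 1, 0, 0, 1, 1, 1])
        y = rng.standard_normal(12)
        df = pd.DataFrame({"y": y, "A": A.astype(str), "B": B.astype(str)})
        full = smf.ols("y ~ C(A)*C(B)", df).fit()
        add = smf.ols("y ~ C(A)+C(B)", df).fit()
        df_int, df_resid = 1, 12 - 4
        ref = ((add.ssr - full.ssr) / df_int) / (full.ssr / df_resid)
        assert interaction_f_statistic(y, A, B) == pytest.approx(ref, abs=1e-8)


class TestPlotDataAndTables:
    def test_cell_means_match_brute_force(self, rng):
        y = rng.standard_normal(60)
        fx = bin_values(rng.random(60), 0, 1, 4)
        fz = bin_values(rng.random(60), 0, 1, 3)
        table = interaction_plot_data(y, fx, fz)
        assert len(table) == 12
        for _, row in table.iterrows():
            mask = (fx.labels == row["x"]) & (fz.labels == row["z"])
            if mask.any():
                assert row["mean"] == pytest.approx(y[mask].mean())
                assert row["count"] == mask.sum()
            else:
                assert np.isnan(row["mean"]) and row["count"] == 0

    def test_analyze_contrast_structure_and_determinism(self, rng):
        n_scen = 80
        scen = pd.DataFrame({
            "scenario_id": np.arange(1, n_scen + 1),
            "n": rng.integers(100, 1001, n_scen),
            "p": rng.integers(1001, 40001, n_scen),
            "psi": rng.uniform(1e-6, 1 - 1e-6, n_scen),
            "delta": rng.uniform(0.1, 10, n_scen),
            "rho": rng.uniform(0, 0.95, n_scen),
        })
        res = scen[["scenario_id"]].copy()
        for m in ("ridge", "lasso", "enet"):
            res[f"mse_{m}"] = rng.uniform(0.2, 1.2, n_scen)
        t1 = analyze_contrast(res, scen, "ridge_vs_lasso", G=4, B=19,
                              rng=np.random.default_rng(5))
        t2 = analyze_contrast(res, scen, "ridge_vs_lasso", G=4, B=19,
                              rng=np.random.default_rng(5))
        pd.testing.assert_frame_equal(t1, t2)
        assert (t1["type"] == "main").sum() == 5
        assert (t1["type"] == "interaction").sum() == 10
        assert t1["p_value"].between(1 / 20, 1).all()
        assert list(t1["term"][:5]) == ["n", "p", "psi", "delta", "rho"]

    def test_contrast_names_cover_tables(self):
        assert len(CONTRAST_NAMES) == 6
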