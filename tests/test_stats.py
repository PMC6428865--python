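"""Unit and oracle tests for the statistical primitives."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom as scipy_hypergeom
from scipy.stats import mannwhitneyu, nbinom

from ribodelta import stats
from ribodelta.datatypes import GlmFit


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        mat = np.array([[10, 10], [50, 50], [7, 7]])
        np.testing.assert_allclose(stats.size_factors(mat), [1.0, 1.0])

    def test_doubled_sample_median_of_ratios(self):
        # B = 2*A: geometric mean is A*sqrt(2); ratios are 1/sqrt2 and sqrt2
        a = np.array([10.0, 40.0, 100.0])
        mat = np.column_stack([a, 2 * a]).astype(int)
        np.testing.assert_allclose(
            stats.size_factors(mat), [1 / math.sqrt(2), math.sqrt(2)], rtol=1e-12
        )

    def test_gene_with_zero_excluded_from_reference(self):
        mat = np.array([[10, 20], [30, 60], [5, 10]])
        base = stats.size_factors(mat)
        with_zero = stats.size_factors(np.vstack([mat, [0, 1000]]))
        np.testing.assert_allclose(base, with_zero)

    def test_all_genes_contain_zero_is_error(self):
        with pytest.raises(ValueError, match="reference"):
            stats.size_factors(np.array([[0, 5], [3, 0]]))


class TestEstimateDispersion:
    CELLS = ["a", "a", "b", "b", "c", "c", "d", "d"]

    def test_constant_counts_hit_floor(self):
        row = np.full(8, 100)
        assert stats.estimate_dispersion(row, self.CELLS, np.ones(8)) == stats.DISPERSION_FLOOR

    def test_poisson_counts_give_near_zero_dispersion(self):
        rng = np.random.default_rng(5)
        row = rng.poisson(500.0, size=400)
        cells = ["x"] * 400
        assert stats.estimate_dispersion(row, cells, np.ones(400)) < 0.01

    def test_nb_moment_consistency(self):
        # alpha=0.2, mean 500, n=200 -> estimate in [0.1, 0.3]
        rng = np.random.default_rng(7)
        r = 1 / 0.2
        row = rng.negative_binomial(r, r / (r + 500.0), size=200)
        est = stats.estimate_dispersion(row, ["x"] * 200, np.ones(200))
        assert 0.1 <= est <= 0.3

    def test_requires_a_replicated_cell(self):
        with pytest.raises(ValueError, match="cell"):
            stats.estimate_dispersion(np.array([1, 2]), ["a", "b"], np.ones(2))


def _nb_loglik_oracle(y, mu, alpha):
    """Independent log-likelihood via scipy's nbinom mass function."""
    r = 1.0 / alpha
    p = r / (r + mu)
    return float(np.sum(nbinom.logpmf(y, r, p)))


def _grid_search_mle(y, design, alpha, beta0, half_width=0.5):
    """Brute-force coordinate grid search of the NB likelihood."""
    beta = np.array(beta0, dtype=float)
    width = half_width
    while width >= 1e-6:
        for _ in range(200):  # cycle coordinates until stable at this width
            moved = False
            for j in range(len(beta)):
                grid = beta[j] + np.linspace(-width, width, 41)
                lls = [
                    _nb_loglik_oracle(
                        y, np.exp(design @ np.r_[beta[:j], g, beta[j + 1 :]]), alpha
                    )
                    for g in grid
                ]
                best = grid[int(np.argmax(lls))]
                if best != beta[j]:
                    beta[j] = best
                    moved = True
            if not moved:
                break
        width *= 0.25
    return beta


class TestNbGlmFit:
    def test_intercept_only_closed_form(self):
        y = np.array([10, 10, 10, 10])
        fit = stats.nb_glm_fit(y, np.ones((4, 1)), None, alpha=0.1)
        assert fit.converged
        np.testing.assert_allclose(fit.coefficients[0], math.log(10), atol=1e-8)

    def test_matches_grid_search_oracle(self, design_matrix):
        rng = np.random.default_rng(11)
        for alpha in (0.05, 0.2):
            mu = np.repeat([200.0, 150.0, 220.0, 90.0], 2)
            r = 1 / alpha
            y = rng.negative_binomial(r, r / (r + mu))
            fit = stats.nb_glm_fit(y, design_matrix, None, alpha)
            assert fit.converged
            oracle = _grid_search_mle(y, design_matrix, alpha, fit.coefficients + 0.3)
            np.testing.assert_allclose(fit.coefficients, oracle, atol=1e-3)

    def test_saturated_design_mle_is_cell_log_means(self, design_matrix):
        # for a saturated 2x2 design the NB score equations are solved by the
        # raw cell means regardless of alpha
        y = np.array([180, 220, 90, 110, 300, 340, 55, 65])
        fit = stats.nb_glm_fit(y, design_matrix, None, alpha=0.1)
        cell_means = y.reshape(4, 2).mean(axis=1)  # mRNA t0, mRNA t30, RPF t0, RPF t30
        b0 = math.log(cell_means[0])
        ba = math.log(cell_means[2] / cell_means[0])
        bc = math.log(cell_means[1] / cell_means[0])
        bi = math.log(cell_means[3] * cell_means[0] / (cell_means[1] * cell_means[2]))
        np.testing.assert_allclose(fit.coefficients, [b0, ba, bc, bi], atol=1e-7)

    def test_offsets_shift_intercept_only(self, design_matrix):
        y = np.array([180, 220, 90, 110, 300, 340, 55, 65])
        f0 = stats.nb_glm_fit(y, design_matrix, None, 0.1)
        f1 = stats.nb_glm_fit(y, design_matrix, np.full(8, 0.7), 0.1)
        np.testing.assert_allclose(f0.coefficients[0] - 0.7, f1.coefficients[0], atol=1e-7)
        np.testing.assert_allclose(f0.coefficients[1:], f1.coefficients[1:], atol=1e-7)

    def test_all_zero_response_flagged(self, design_matrix):
        fit = stats.nb_glm_fit(np.zeros(8, dtype=int), design_matrix, None, 0.1)
        assert not fit.converged

    def test_rank_deficient_design_rejected(self):
        bad = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="rank"):
            stats.nb_glm_fit(np.arange(6) + 1, bad, None, 0.1)


class TestWaldTest:
    def _fit(self, coef, se):
        return GlmFit(np.array([coef]), np.array([se]), True, 5, 0.1)

    def test_zero_coefficient_gives_p_one(self):
        _, p = stats.wald_test(self._fit(0.0, 1.0), 0)
        assert p == 1.0

    def test_critical_value_gives_p_005(self):
        _, p = stats.wald_test(self._fit(1.959964, 1.0), 0)
        assert abs(p - 0.05) < 1e-6

    def test_zero_se_is_error(self):
        with pytest.raises(ValueError):
            stats.wald_test(self._fit(1.0, 0.0), 0)

    def test_non_converged_fit_gives_missing(self):
        fit = GlmFit(np.array([np.nan]), np.array([np.nan]), False, 100, 0.1)
        z, p = stats.wald_test(fit, 0)
        assert math.isnan(z) and math.isnan(p)


class TestBhFdr:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            stats.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_is_identity(self):
        np.testing.assert_allclose(stats.bh_fdr([0.3]), [0.3])

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        np.testing.assert_allclose(
            stats.bh_fdr(p), sm.multipletests(p, method="fdr_bh")[1], rtol=1e-12
        )

    def test_missing_values_propagate(self):
        q = stats.bh_fdr([0.01, np.nan, 0.04])
        assert math.isnan(q[1])
        # m counts only the finite entries
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.bh_fdr([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_sorted_q_non_decreasing_and_idempotent_envelope(self, p):
        q = stats.bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= 0) & (q <= 1))


class TestMannWhitney:
    def test_exact_separated_samples(self):
        u, p = stats.mann_whitney([1, 2, 3], [4, 5, 6], "two-sided", "exact")
        assert u == 0.0
        assert abs(p - 0.1) < 1e-12  # 2 extreme assignments out of C(6,3)=20

    def test_complete_ties_give_central_u(self):
        u, _ = stats.mann_whitney([1, 2], [1, 2])
        assert u == 2.0  # n1*n2/2

    def test_normal_mode_close_to_exact(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            x, y = rng.normal(size=6), rng.normal(0.5, 1, size=6)
            _, p_ex = stats.mann_whitney(x, y, "two-sided", "exact")
            _, p_no = stats.mann_whitney(x, y, "two-sided", "normal")
            assert abs(p_ex - p_no) < 0.02

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(9)
        for n1, n2 in [(3, 4), (5, 5), (4, 6)]:
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            for alt in ("two-sided", "greater", "less"):
                u, p = stats.mann_whitney(x, y, alt, "exact")
                ref = mannwhitneyu(x, y, alternative=alt, method="exact")
                assert u == ref.statistic
                assert abs(p - ref.pvalue) < 1e-10

    def test_normal_mode_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=30), rng.normal(0.3, 1, size=25)
        _, p = stats.mann_whitney(x, y, "two-sided", "normal")
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert abs(p - ref.pvalue) < 1e-10

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            stats.mann_whitney([], [1.0])


def _hypergeom_enumeration(k, n_a, n_b, n_universe):
    """P(|A & B| >= k) by enumerating every draw of B."""
    universe = range(n_universe)
    a = set(range(n_a))
    hits = total = 0
    for b in itertools.combinations(universe, n_b):
        total += 1
        hits += len(a & set(b)) >= k
    return hits / total


class TestHypergeomOverlap:
    def test_zero_overlap_is_certain(self):
        assert stats.hypergeom_overlap_p(0, 5, 5, 20) == 1.0

    def test_small_exact_value(self):
        # N=4, two sets of 2: P(overlap=2) = 1/C(4,2) = 1/6
        assert abs(stats.hypergeom_overlap_p(2, 2, 2, 4) - 1 / 6) < 1e-12

    @pytest.mark.parametrize("n_universe", [4, 7, 10, 12])
    def test_matches_enumeration(self, n_universe):
        rng = np.random.default_rng(n_universe)
        for _ in range(8):
            n_a = int(rng.integers(1, n_universe + 1))
            n_b = int(rng.integers(1, n_universe + 1))
            k = int(rng.integers(0, min(n_a, n_b) + 1))
            got = stats.hypergeom_overlap_p(k, n_a, n_b, n_universe)
            want = _hypergeom_enumeration(k, n_a, n_b, n_universe)
            assert abs(got - want) < 1e-10

    def test_matches_scipy_tail_in_extreme_regime(self):
        got = stats.hypergeom_overlap_p(150, 200, 300, 6000)
        want = float(scipy_hypergeom.sf(149, 6000, 200, 300))
        assert got == pytest.approx(want, rel=1e-9)
        assert got > 0  # no underflow

    def test_inconsistent_arguments_rejected(self):
        with pytest.raises(ValueError):
            stats.hypergeom_overlap_p(3, 2, 5, 10)
        with pytest.raises(ValueError):
            stats.hypergeom_overlap_p(1, 11, 5, 10)


class TestRelativeEnrichment:
    def test_balanced_table_is_one(self):
        assert stats.relative_enrichment(10, 10, 10, 10) == 1.0

    def test_hand_arithmetic(self):
        assert stats.relative_enrichment(50, 50, 25, 75) == 2.0

    def test_zero_comparison_numerator_rejected(self):
        with pytest.raises(ValueError):
            stats.relative_enrichment(5, 5, 0, 10)
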