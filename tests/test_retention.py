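import numpy as np
import pandas as pd
import pytest

from egadim import (
    FactorDesign,
    efa_fit,
    eigenvalues,
    information_retention,
    kaiser_rule,
    parallel_analysis,
    simulate_binary,
    velicer_map,
    vss,
)
from egadim.polychoric import CorrelationMatrix
from egadim.retention import consecutive_exceedance

# Printed per-k statistic columns of a published 56-item worked example;
# used to exercise each method's decision rule on known traces.
VSS_TRACE = [0.63, 0.68, 0.68, 0.64, 0.66, 0.58, 0.58, 0.59, 0.58, 0.58]
MAP_TRACE = [0.0403, 0.0289, 0.0192, 0.0142, 0.0083, 0.0078, 0.0056,
             0.006, 0.0065, 0.0071]
BIC_TRACE = [36739, 23717, 13721, 8245, 5326, 2565, 1646, 1340, 1036, 866]
EBIC_TRACE = [110227, 45380, 19638, 10762, -1422, -4205, -6297, -6115,
              -6011, -5903]
OBSERVED_EIGS = [23.17, 7.29, 3.94, 3.02, 1.24, 1.07, 0.85, 0.40, 0.33, 0.22]
REFERENCE_EIGS = [2.69, 2.27, 2.06, 1.80, 1.60, 1.41, 1.22, 1.12, 0.98, 0.86]


def equicorrelation(p, r):
    R = np.full((p, p), r)
    np.fill_diagonal(R, 1.0)
    return R


class TestEigenvaluesAndKaiser:
    def test_identity(self):
        assert np.allclose(eigenvalues(np.eye(5)), 1.0)

    def test_two_by_two_closed_form(self):
        assert eigenvalues(equicorrelation(2, 0.5)) == pytest.approx([1.5, 0.5])

    def test_equicorrelation_closed_form(self):
        assert eigenvalues(equicorrelation(4, 0.5)) == pytest.approx(
            [2.5, 0.5, 0.5, 0.5]
        )

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            eigenvalues(np.array([[1.0, 0.5], [0.2, 1.0]]))

    def test_kaiser_on_printed_eigenvalues(self):
        assert kaiser_rule(OBSERVED_EIGS) == 6

    def test_kaiser_strict_inequality(self):
        assert kaiser_rule(np.ones(5)) == 0
        assert kaiser_rule([2.5, 0.5, 0.5, 0.5]) == 1

    def test_kaiser_monotone_under_added_large_eigenvalue(self):
        base = [2.0, 0.8, 0.5]
        assert kaiser_rule([3.0] + base) == kaiser_rule(base) + 1


class TestParallelAnalysisRule:
    def test_printed_example_retains_four(self):
        assert consecutive_exceedance(OBSERVED_EIGS, REFERENCE_EIGS) == 4

    def test_first_below_reference_gives_zero(self):
        assert consecutive_exceedance([0.9, 2.0], [1.0, 1.0]) == 0

    def test_gap_in_run_stops_count(self):
        assert consecutive_exceedance([2.0, 0.9, 1.5], [1.0, 1.0, 1.0]) == 1


class TestParallelAnalysisMonteCarlo:
    def test_two_factor_recovery(self):
        design = FactorDesign(2, 5, 0.0, 1000, seed=31)
        data = simulate_binary(design)
        est = parallel_analysis(data, seed=0)
        assert est.k_hat == 2

    def test_reference_eigenvalues_average_one(self):
        """Permutation reference matrices keep trace p, so reference
        eigenvalues average about 1."""
        design = FactorDesign(2, 5, 0.5, 500, seed=8)
        data = simulate_binary(design)
        est = parallel_analysis(data, seed=1)
        assert est.trace["reference_eigenvalue"].mean() == pytest.approx(
            1.0, abs=0.05
        )

    def test_self_consistency_of_trace(self):
        design = FactorDesign(2, 5, 0.2, 500, seed=12)
        est = parallel_analysis(simulate_binary(design), seed=2)
        rule = consecutive_exceedance(
            est.trace["observed_eigenvalue"].to_numpy(),
            est.trace["reference_eigenvalue"].to_numpy(),
        )
        assert est.k_hat == rule

    def test_deterministic_given_seed(self):
        design = FactorDesign(2, 5, 0.2, 300, seed=5)
        data = simulate_binary(design)
        a = parallel_analysis(data, seed=9)
        b = parallel_analysis(data, seed=9)
        assert a.k_hat == b.k_hat
        pd.testing.assert_frame_equal(a.trace, b.trace)


class TestVelicerMap:
    def test_printed_trace_argmin(self):
        assert int(np.argmin(MAP_TRACE)) + 1 == 7

    def test_population_two_factor(self, two_factor_orthogonal):
        _, model = two_factor_orthogonal
        est = velicer_map(model.correlation)
        assert est.k_hat == 2

    def test_equicorrelation_single_factor(self):
        est = velicer_map(equicorrelation(6, 0.5))
        assert est.k_hat == 1

    def test_trace_self_consistency(self, two_factor_orthogonal):
        _, model = two_factor_orthogonal
        est = velicer_map(model.correlation)
        t = est.trace
        assert est.k_hat == int(t.loc[t["map_statistic"].idxmin(), "k"])


class TestVSS:
    def test_printed_trace_smallest_argmax(self):
        arr = np.asarray(VSS_TRACE)
        assert int(np.flatnonzero(arr == arr.max())[0]) + 1 == 2

    def test_single_factor_population(self):
        p = 8
        L = np.full((p, 1), 0.7)
        R = L @ L.T
        np.fill_diagonal(R, 1.0)
        est = vss(R, n=500, k_max=4)
        assert est.k_hat == 1
        assert est.trace["vss_statistic"].iloc[0] == pytest.approx(1.0, abs=1e-5)

    def test_statistic_bounded_by_one(self, two_factor_orthogonal):
        _, model = two_factor_orthogonal
        est = vss(model.correlation, n=1000, k_max=4)
        assert np.all(est.trace["vss_statistic"] <= 1.0 + 1e-10)


class TestEfaFit:
    def test_degrees_of_freedom_formula(self):
        fit = efa_fit(equicorrelation(4, 0.3), n=500, k=1)
        assert fit.df == 2

    def test_single_factor_recovery(self):
        p = 6
        L = np.full((p, 1), 0.7)
        R = L @ L.T
        np.fill_diagonal(R, 1.0)
        fit = efa_fit(R, n=1000, k=1)
        assert np.allclose(np.abs(fit.loadings[:, 0]), 0.7, atol=1e-4)
        assert fit.f_ml == pytest.approx(0.0, abs=1e-8)

    def test_saturated_model_zero_chi_square(self):
        # p=3, k=1 has df = 0: the single-factor model is saturated
        rng = np.random.default_rng(3)
        R = np.corrcoef(rng.multivariate_normal(
            np.zeros(3), equicorrelation(3, 0.4), size=500).T)
        fit = efa_fit(R, n=500, k=1)
        assert fit.df == 0
        assert fit.chi_square == pytest.approx(0.0, abs=1e-4)

    def test_inadmissible_k_rejected(self):
        with pytest.raises(ValueError):
            efa_fit(equicorrelation(5, 0.3), n=500, k=4)


class TestInformationRetention:
    def test_bic_arithmetic(self):
        assert 100 - 10 * np.log(1000) == pytest.approx(30.92, abs=0.01)

    def test_printed_bic_trace_argmin(self):
        assert int(np.argmin(BIC_TRACE)) + 1 == 10

    def test_printed_ebic_trace_argmin(self):
        # the stated argmin rule picks 7 on the printed extended-BIC column
        assert int(np.argmin(EBIC_TRACE)) + 1 == 7

    def test_gamma_zero_collapses_to_bic(self, two_factor_orthogonal):
        _, model = two_factor_orthogonal
        R = CorrelationMatrix(values=model.correlation, method="tetrachoric",
                              n_obs=1000)
        bic, ebic = information_retention(R, n=1000, k_max=4, gamma=0.0)
        assert np.allclose(bic.trace["bic"], ebic.trace["ebic"])
        assert bic.k_hat == ebic.k_hat

    def test_population_two_factor_selected(self, two_factor_orthogonal):
        _, model = two_factor_orthogonal
        R = CorrelationMatrix(values=model.correlation, method="tetrachoric",
                              n_obs=1000)
        bic, ebic = information_retention(R, n=1000, k_max=4)
        assert bic.k_hat == 2
        assert ebic.k_hat == 2
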