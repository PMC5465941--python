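import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal, norm

from egadim import (
    FactorDesign,
    correlation_matrix,
    estimate_thresholds,
    simulate_binary,
    tetrachoric_pair,
)
from egadim.polychoric import (
    ConstantColumnError,
    bivariate_normal_cdf,
    nearest_positive_definite,
    polychoric_pair,
)


class TestBivariateNormalCdf:
    @pytest.mark.parametrize("h,k,rho", [
        (0.0, 0.0, 0.5), (1.0, -0.5, 0.3), (-1.5, 2.0, -0.8),
        (0.3, 0.3, 0.95), (2.0, 2.0, -0.99),
    ])
    def test_against_scipy(self, h, k, rho):
        expected = multivariate_normal(
            mean=[0, 0], cov=[[1, rho], [rho, 1]]
        ).cdf([h, k])
        assert bivariate_normal_cdf(h, k, rho) == pytest.approx(
            expected, abs=1e-8
        )


class TestThresholds:
    def test_binary_half(self):
        col = np.array([0] * 50 + [1] * 50)
        assert estimate_thresholds(col) == pytest.approx([0.0])

    def test_binary_8413(self):
        col = np.array([0] * 8413 + [1] * 1587)
        assert estimate_thresholds(col)[0] == pytest.approx(1.0, abs=1e-3)

    def test_three_category(self):
        col = np.repeat([0, 1, 2], [25, 50, 25])
        t = estimate_thresholds(col)
        assert t == pytest.approx([-0.6745, 0.6745], abs=1e-4)

    def test_constant_column(self):
        with pytest.raises(ConstantColumnError):
            estimate_thresholds(np.zeros(10))


def _tetrachoric_oracle(table):
    """1-D likelihood maximization with scipy's bivariate normal CDF."""
    t = np.asarray(table, float)
    if np.any(t == 0):
        t = t + 0.5
    n = t.sum()
    h = norm.ppf((t[1, 0] + t[1, 1]) / n)
    k = norm.ppf((t[0, 1] + t[1, 1]) / n)

    def neg_ll(rho):
        bvn = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
        p11 = bvn.cdf([h, k])
        p1x, p1y = norm.cdf(h), norm.cdf(k)
        probs = np.array([
            1 - p1x - p1y + p11, p1y - p11, p1x - p11, p11,
        ])
        probs = np.clip(probs, 1e-12, None)
        return -np.sum(t.ravel() * np.log(probs))

    res = minimize_scalar(neg_ll, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-10})
    return res.x


class TestTetrachoricPair:
    def test_independence(self):
        assert tetrachoric_pair([[25, 25], [25, 25]]) == pytest.approx(0.0,
                                                                       abs=1e-8)

    def test_symmetric_table_closed_form(self):
        # both thresholds zero: ML solution is sin(2 pi (p11 - 1/4))
        est = tetrachoric_pair([[30, 20], [20, 30]])
        assert est == pytest.approx(np.sin(2 * np.pi * 0.05), abs=1e-6)
        assert est == pytest.approx(0.309, abs=1e-3)

    def test_perfect_association_with_continuity_correction(self):
        est = tetrachoric_pair([[50, 0], [0, 50]])
        assert 0.9 < est <= 0.999
        assert est == pytest.approx(_tetrachoric_oracle([[50, 0], [0, 50]]),
                                    abs=1e-4)

    @pytest.mark.parametrize("table", [
        [[40, 10], [15, 35]], [[5, 20], [30, 45]], [[70, 10], [5, 15]],
    ])
    def test_matches_likelihood_oracle(self, table):
        assert tetrachoric_pair(table) == pytest.approx(
            _tetrachoric_oracle(table), abs=1e-5
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ConstantColumnError):
            tetrachoric_pair([[50, 50], [0, 0]])

    @given(st.lists(st.integers(1, 200), min_size=4, max_size=4))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_sign_equivariance(self, cells):
        """Negating one variable's coding negates the correlation."""
        table = np.array(cells, float).reshape(2, 2)
        flipped = table[:, ::-1]  # recode y -> 1 - y
        assert tetrachoric_pair(flipped) == pytest.approx(
            -tetrachoric_pair(table), abs=1e-6
        )


class TestConsistency:
    @pytest.mark.parametrize("rho", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_large_sample_recovery(self, rho):
        """Monte Carlo consistency of the two-step estimator at n = 1e5."""
        rng = np.random.default_rng(int(rho * 100))
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=100_000)
        x = (z > 0).astype(int)
        R = correlation_matrix(x)
        assert abs(R.values[0, 1] - rho) < 0.02

    def test_pearson_attenuated_on_binary_data(self):
        rho = 0.6
        rng = np.random.default_rng(1)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=50_000)
        x = (z > 0).astype(int)
        phi = np.corrcoef(x.T)[0, 1]
        tetra = correlation_matrix(x).values[0, 1]
        assert abs(phi) < abs(tetra)


class TestCorrelationMatrix:
    def test_population_recovery_two_factor(self):
        d = FactorDesign(2, 5, 0.0, 100_000, seed=2)
        data = simulate_binary(d)
        R = correlation_matrix(data)
        within = R.values[0, 1]
        cross = R.values[0, 7]
        assert within == pytest.approx(0.5, abs=0.02)
        assert cross == pytest.approx(0.0, abs=0.02)

    def test_contract_symmetric_unit_diagonal(self, binary_sample_2f):
        _, data = binary_sample_2f
        R = correlation_matrix(data)
        assert np.allclose(R.values, R.values.T)
        assert np.allclose(np.diag(R.values), 1.0)
        assert np.all(np.abs(R.values) <= 1.0)

    def test_csv_roundtrip(self, binary_sample_2f, tmp_path):
        import pandas as pd

        _, data = binary_sample_2f
        R = correlation_matrix(data)
        out = tmp_path / "corr.csv"
        R.to_csv(out)
        back = pd.read_csv(out, index_col=0)
        assert np.allclose(back.to_numpy(), R.values)
        assert list(back.columns) == list(data.item_labels)

    def test_duplicated_column_clipped(self, rng):
        col = (rng.random(300) > 0.5).astype(int)
        other = (rng.random(300) > 0.5).astype(int)
        x = np.column_stack([col, col, other])
        R = correlation_matrix(x)
        assert R.values[0, 1] == pytest.approx(0.999, abs=1e-9)

    def test_constant_column_names_item(self):
        x = np.column_stack([np.zeros(10), np.ones(10), np.arange(10) % 2])
        with pytest.raises(ConstantColumnError, match="item_1"):
            correlation_matrix(x)

    def test_smoothing_produces_psd(self, rng):
        raw = np.array([[1.0, 0.95, 0.1], [0.95, 1.0, 0.9], [0.1, 0.9, 1.0]])
        fixed = nearest_positive_definite(raw)
        assert np.linalg.eigvalsh(fixed)[0] >= 0
        assert np.allclose(np.diag(fixed), 1.0)

    def test_polychoric_pair_recovers_latent_correlation(self):
        rho = 0.5
        rng = np.random.default_rng(7)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=20_000)
        cuts = norm.ppf([0.25, 0.5, 0.75])
        x = np.digitize(z[:, 0], cuts)
        y = np.digitize(z[:, 1], cuts)
        assert polychoric_pair(x, y) == pytest.approx(rho, abs=0.03)
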