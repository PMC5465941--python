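"""Tetrachoric and polychoric correlation estimation.

Two-step maximum likelihood: thresholds are fixed at the normal quantiles of
the observed category margins, then the latent correlation of each pair is
found by maximizing the bivariate-normal likelihood of the contingency
table.  For dichotomous items this reduces to solving

    Phi2(h_i, h_j; rho) = p11

for rho, where h = Phi^{-1}(P(item = 1)) and p11 is the joint proportion of
(1, 1) responses.  Phi2 is monotone increasing in rho, so a safeguarded
Newton iteration (with the bivariate-normal density as exact derivative)
converges for every admissible table; all item pairs are solved
simultaneously with vectorized quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

__all__ = [
    "CorrelationMatrix",
    "ConstantColumnError",
    "estimate_thresholds",
    "tetrachoric_pair",
    "polychoric_pair",
    "correlation_matrix",
    "bivariate_normal_cdf",
    "nearest_positive_definite",
]

#: Clip for latent correlation estimates (degenerate tables hit the bound).
RHO_BOUND = 0.999
#: Eigenvalue floor used by the positive-definiteness repair.
PSD_FLOOR = 1e-6

# Gauss-Legendre nodes/weights on [0, 1]; 48 points give ~1e-12 accuracy in
# the correlation integral away from |rho| = 1.
_GL_X, _GL_W = np.polynomial.legendre.leggauss(48)
_GL_X = (_GL_X + 1.0) / 2.0
_GL_W = _GL_W / 2.0


class ConstantColumnError(ValueError):
    """A constant item has an undefined latent correlation."""


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric unit-diagonal item correlation matrix with metadata.

    ``smoothed`` records whether a nearest-positive-definite repair
    (eigenvalue clipping followed by rescaling to unit diagonal) was
    applied to the raw pairwise estimates.
    """

    values: np.ndarray
    method: str
    n_obs: int
    smoothed: bool = False
    item_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(v) > 1 + 1e-12):
            raise ValueError("correlation entries must lie in [-1, 1]")

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    def to_frame(self):
        import pandas as pd

        labels = self.item_labels or tuple(
            f"item_{i + 1}" for i in range(self.n_items)
        )
        return pd.DataFrame(self.values, index=list(labels),
                            columns=list(labels))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def _phi2_density(h: np.ndarray, k: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Standard bivariate normal density at (h, k) with correlation r."""
    om = 1.0 - r * r
    z = (h * h - 2.0 * r * h * k + k * k) / (2.0 * om)
    return np.exp(-z) / (2.0 * np.pi * np.sqrt(om))


def bivariate_normal_cdf(h, k, rho):
    """P(Z1 <= h, Z2 <= k) for standard bivariate normals, vectorized.

    Uses the identity Phi2(h, k; rho) = Phi(h) Phi(k) + int_0^rho
    phi2(h, k; r) dr evaluated with fixed Gauss-Legendre quadrature.
    """
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, float), np.asarray(k, float), np.asarray(rho, float)
    )
    base = norm.cdf(h) * norm.cdf(k)
    finite = np.isfinite(h) & np.isfinite(k)
    # infinite bounds: the correlation term vanishes, Phi2 -> Phi(h) Phi(k)
    hf = np.where(finite, h, 0.0)
    kf = np.where(finite, k, 0.0)
    # nodes r = rho * x for x in (0, 1); integrand vectorized over pairs
    r = rho[..., None] * _GL_X
    dens = _phi2_density(hf[..., None], kf[..., None], r)
    integral = np.where(finite, rho * (dens * _GL_W).sum(axis=-1), 0.0)
    return base + integral


def estimate_thresholds(column: np.ndarray) -> np.ndarray:
    """Normal-quantile thresholds from the cumulative category proportions.

    For c observed categories returns c-1 strictly increasing thresholds;
    a constant column raises :class:`ConstantColumnError`.
    """
    col = np.asarray(column)
    col = col[~np.isnan(col.astype(float))]
    if col.size == 0:
        raise ConstantColumnError("column has no observed values")
    _, counts = np.unique(col, return_counts=True)
    if counts.size < 2:
        raise ConstantColumnError(
            "constant column: latent correlation is undefined"
        )
    cum = np.cumsum(counts)[:-1] / col.size
    return norm.ppf(cum)


def _solve_rho(h: np.ndarray, k: np.ndarray, p11: np.ndarray,
               tol: float = 1e-8, max_iter: int = 60) -> np.ndarray:
    """Vectorized safeguarded Newton for Phi2(h, k; rho) = p11."""
    lo = np.full(h.shape, -RHO_BOUND)
    hi = np.full(h.shape, RHO_BOUND)
    rho = np.clip(
        np.sin(2.0 * np.pi * (p11 - norm.cdf(h) * norm.cdf(k))), -0.95, 0.95
    )
    for _ in range(max_iter):
        f = bivariate_normal_cdf(h, k, rho) - p11
        # Phi2 is increasing in rho, so f's sign brackets the root
        hi = np.where(f > 0, np.minimum(hi, rho), hi)
        lo = np.where(f < 0, np.maximum(lo, rho), lo)
        if np.all(np.abs(f) < tol * 1e-2):
            break
        step = f / np.maximum(_phi2_density(h, k, rho), 1e-300)
        cand = rho - step
        outside = (cand <= lo) | (cand >= hi)
        rho = np.where(outside, 0.5 * (lo + hi), cand)
        if np.all(hi - lo < tol):
            break
    return np.clip(rho, -RHO_BOUND, RHO_BOUND)


def tetrachoric_pair(table: np.ndarray) -> float:
    """Two-step ML tetrachoric correlation from a 2x2 contingency table.

    ``table[i, j]`` counts responses (x = i, y = j) for i, j in {0, 1}.
    Any zero cell triggers a +0.5 continuity correction applied to every
    cell.  A zero margin (constant variable) raises
    :class:`ConstantColumnError`.  The estimate is clipped to
    [-0.999, 0.999].
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or t.sum() <= 0 or np.any(t < 0):
        raise ValueError("table must be 2x2 with positive total count")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ConstantColumnError("zero margin: tetrachoric correlation undefined")
    if np.any(t == 0):
        t = t + 0.5
    n = t.sum()
    p1x = (t[1, 0] + t[1, 1]) / n
    p1y = (t[0, 1] + t[1, 1]) / n
    p11 = t[1, 1] / n
    h = norm.ppf(p1x)
    k = norm.ppf(p1y)
    return float(_solve_rho(np.array(h), np.array(k), np.array(p11)))


def polychoric_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step ML polychoric correlation for a pair of ordinal columns.

    Thresholds come from the margins; rho maximizes the multinomial
    log-likelihood with bivariate-normal rectangle probabilities.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    tx = np.concatenate(([-np.inf], estimate_thresholds(x), [np.inf]))
    ty = np.concatenate(([-np.inf], estimate_thresholds(y), [np.inf]))
    xu = np.unique(x)
    yu = np.unique(y)
    counts = np.zeros((xu.size, yu.size))
    for a, xv in enumerate(xu):
        for b, yv in enumerate(yu):
            counts[a, b] = np.sum((x == xv) & (y == yv))
    if np.any(counts == 0):
        counts = counts + 0.5

    def neg_ll(rho: float) -> float:
        ll = 0.0
        for a in range(xu.size):
            for b in range(yu.size):
                pr = (
                    bivariate_normal_cdf(tx[a + 1], ty[b + 1], rho)
                    - bivariate_normal_cdf(tx[a], ty[b + 1], rho)
                    - bivariate_normal_cdf(tx[a + 1], ty[b], rho)
                    + bivariate_normal_cdf(tx[a], ty[b], rho)
                )
                ll += counts[a, b] * np.log(max(float(pr), 1e-300))
        return -ll

    res = minimize_scalar(neg_ll, bounds=(-RHO_BOUND, RHO_BOUND),
                          method="bounded", options={"xatol": 1e-8})
    return float(np.clip(res.x, -RHO_BOUND, RHO_BOUND))


def _tetrachoric_matrix(values: np.ndarray) -> np.ndarray:
    """All pairwise tetrachoric correlations of a 0/1 matrix at once.

    Pairwise-complete counts are accumulated by matrix products; pairs with
    an empty cell get the +0.5 continuity correction.  Margins (and hence
    thresholds) are therefore pair-specific.
    """
    x = np.asarray(values, dtype=float)
    n, p = x.shape
    valid = (~np.isnan(x)).astype(float)
    ones = np.nan_to_num(x) * valid
    zeros = (1.0 - np.nan_to_num(x)) * valid
    n11 = ones.T @ ones
    n10 = ones.T @ zeros
    n01 = zeros.T @ ones
    n00 = zeros.T @ zeros
    iu = np.triu_indices(p, k=1)
    cells = np.stack([n00[iu], n01[iu], n10[iu], n11[iu]])
    correct = (cells == 0).any(axis=0)
    cells = cells + 0.5 * correct
    total = cells.sum(axis=0)
    p11 = cells[3] / total
    p1x = (cells[2] + cells[3]) / total
    p1y = (cells[1] + cells[3]) / total
    rho = _solve_rho(norm.ppf(p1x), norm.ppf(p1y), p11)
    out = np.eye(p)
    out[iu] = rho
    out.T[iu] = rho
    return out


def nearest_positive_definite(R: np.ndarray, floor: float = PSD_FLOOR,
                              max_iter: int = 100,
                              conv_tol: float = 1e-7) -> np.ndarray:
    """Nearest correlation matrix by Higham alternating projections.

    Dykstra-corrected projections alternate between the PSD cone and the
    unit-diagonal affine set; a final eigenvalue floor of ``floor`` times
    the largest eigenvalue guards strict positive definiteness.  Unlike a
    plain eigenvalue clip followed by rescaling, this does not attenuate
    the off-diagonal structure, which matters for near-singular matrices
    estimated from small samples.
    """
    Y = np.asarray(R, dtype=float).copy()
    DS = np.zeros_like(Y)
    for _ in range(max_iter):
        Rk = Y - DS
        w, v = np.linalg.eigh(Rk)
        X = (v * np.maximum(w, 0.0)) @ v.T
        DS = X - Rk
        Y_old = Y
        Y = X.copy()
        np.fill_diagonal(Y, 1.0)
        denom = max(np.linalg.norm(Y, "fro"), 1e-12)
        if np.linalg.norm(Y - Y_old, "fro") / denom < conv_tol:
            break
    w, v = np.linalg.eigh(Y)
    eps = floor * w.max()
    if w.min() < eps:
        w = np.maximum(w, eps)
        Y = (v * w) @ v.T
        d = np.sqrt(np.diag(Y))
        Y = Y / np.outer(d, d)
    Y = (Y + Y.T) / 2.0
    np.fill_diagonal(Y, 1.0)
    return Y


def _is_binary(values: np.ndarray) -> bool:
    u = np.unique(values[~np.isnan(values)])
    return u.size <= 2 and np.all(np.isin(u, (0.0, 1.0)))


def _is_ordinal(values: np.ndarray, max_categories: int = 10) -> bool:
    u = np.unique(values[~np.isnan(values)])
    return u.size <= max_categories and np.allclose(u, np.round(u))


def correlation_matrix(data, method: str = "auto", strict: bool = False) -> CorrelationMatrix:
    """Estimate the item correlation matrix, choosing the estimator by data
    type: tetrachoric for dichotomous items, polychoric for small ordinal
    scales, Pearson otherwise.

    Parameters
    ----------
    data : ItemResponseMatrix, DataFrame or 2-D array
        Respondents by items.
    method : {"auto", "tetrachoric", "polychoric", "pearson"}
        Force a particular estimator, or detect from the data.
    strict : bool
        If true, reject missing values instead of using pairwise-complete
        observations.

    Raises
    ------
    ConstantColumnError
        Naming every constant item.
    """
    labels = None
    if hasattr(data, "item_labels"):
        labels = tuple(data.item_labels)
        values = np.asarray(data.values, dtype=float)
    elif hasattr(data, "columns"):
        labels = tuple(map(str, data.columns))
        values = data.to_numpy(dtype=float)
    else:
        values = np.asarray(data, dtype=float)
    if values.ndim != 2 or values.shape[0] < 3:
        raise ValueError("need a 2-D table with at least 3 observations")
    if strict and np.isnan(values).any():
        raise ValueError("missing values present and strict mode requested")
    if labels is None:
        labels = tuple(f"item_{i + 1}" for i in range(values.shape[1]))

    constant = [
        labels[j]
        for j in range(values.shape[1])
        if np.unique(values[~np.isnan(values[:, j]), j]).size < 2
    ]
    if constant:
        raise ConstantColumnError(
            "constant column(s): " + ", ".join(constant)
        )

    if method == "auto":
        if _is_binary(values):
            method = "tetrachoric"
        elif _is_ordinal(values):
            method = "polychoric"
        else:
            method = "pearson"

    p = values.shape[1]
    if method == "tetrachoric":
        if not _is_binary(values):
            raise ValueError("tetrachoric estimation requires 0/1 data")
        R = _tetrachoric_matrix(values)
    elif method == "polychoric":
        R = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                R[i, j] = R[j, i] = polychoric_pair(values[:, i], values[:, j])
    elif method == "pearson":
        frame_mask = ~np.isnan(values)
        if frame_mask.all():
            R = np.corrcoef(values, rowvar=False)
        else:  # pairwise-complete Pearson
            import pandas as pd

            R = pd.DataFrame(values).corr().to_numpy()
        np.fill_diagonal(R, 1.0)
    else:
        raise ValueError(f"unknown correlation method {method!r}")

    R = (R + R.T) / 2.0
    smoothed = False
    if np.linalg.eigvalsh(R)[0] < -1e-8:
        R = nearest_positive_definite(R)
        smoothed = True
    return CorrelationMatrix(
        values=R,
        method=method,
        n_obs=int(np.sum(~np.isnan(values).any(axis=1))),
        smoothed=smoothed,
        item_labels=labels,
    )
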