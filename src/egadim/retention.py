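"""Classical factor-retention methods.

Implements the six comparison estimators used alongside EGA: the
Kaiser-Guttman eigenvalue-greater-than-one rule, Horn's parallel analysis
(permutation reference on tetrachoric correlations), Velicer's minimum
average partial (MAP) procedure, the very simple structure (VSS)
criterion at complexity one, and BIC / extended-BIC comparison of
maximum-likelihood factor models with 1..k_max factors.

All methods operate on the same latent correlation matrix the EGA
pipeline uses (tetrachoric for dichotomous items), and every estimate
retains its per-k statistic trace so the decision rule can be re-applied
and audited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .polychoric import (
    CorrelationMatrix,
    correlation_matrix,
    nearest_positive_definite,
)

__all__ = [
    "RetentionEstimate",
    "EFAFit",
    "eigenvalues",
    "kaiser_rule",
    "parallel_analysis",
    "velicer_map",
    "vss",
    "efa_fit",
    "information_retention",
    "consecutive_exceedance",
]


@dataclass(frozen=True)
class RetentionEstimate:
    """A method's dimension estimate plus the statistics it decided on."""

    method: str
    k_hat: int
    trace: pd.DataFrame


@dataclass(frozen=True)
class EFAFit:
    """Maximum-likelihood common-factor solution for a fixed k."""

    k: int
    loadings: np.ndarray
    communalities: np.ndarray
    chi_square: float
    df: int
    n_params: int
    f_ml: float
    converged: bool
    heywood: bool


def _as_corr(R) -> tuple[np.ndarray, int | None]:
    if isinstance(R, CorrelationMatrix):
        return np.asarray(R.values, float), R.n_obs
    return np.asarray(R, float), None


def eigenvalues(R) -> np.ndarray:
    """Eigenvalues of the (unreduced) correlation matrix, descending."""
    Rm, _ = _as_corr(R)
    if not np.allclose(Rm, Rm.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    return np.sort(np.linalg.eigvalsh(Rm))[::-1]


def kaiser_rule(eigs: np.ndarray) -> int:
    """Number of eigenvalues strictly greater than one."""
    return int(np.sum(np.asarray(eigs) > 1.0))


def consecutive_exceedance(observed: np.ndarray, reference: np.ndarray) -> int:
    """Largest k such that observed_j > reference_j for all j <= k.

    This is the parallel-analysis decision rule: retain up to the last
    observed eigenvalue (in an unbroken initial run) that exceeds its
    reference eigenvalue.
    """
    observed = np.asarray(observed, float)
    reference = np.asarray(reference, float)
    exceeds = observed > reference
    if not exceeds[0]:
        return 0
    breaks = np.flatnonzero(~exceeds)
    return int(breaks[0]) if breaks.size else int(exceeds.size)


def parallel_analysis(data, n_iter: int = 20, seed: int | None = 0,
                      corr_method: str = "auto") -> RetentionEstimate:
    """Horn's parallel analysis with a column-permutation reference.

    Observed eigenvalues come from the data's tetrachoric (or polychoric /
    Pearson) correlation matrix; the reference eigenvalues are the mean
    over ``n_iter`` datasets obtained by independently permuting each
    column, which preserves the item margins while destroying inter-item
    correlation.  The correlation matrix is re-estimated on every
    permuted copy.
    """
    R = correlation_matrix(data, method=corr_method)
    observed = eigenvalues(R)
    if hasattr(data, "to_numpy"):
        values = data.to_numpy(dtype=float)
    elif hasattr(data, "item_labels"):
        values = np.asarray(data.values, float)
    else:
        values = np.asarray(data, float)
    n, p = values.shape
    rng = np.random.default_rng(seed)
    ref = np.zeros((n_iter, p))
    for it in range(n_iter):
        perm = np.column_stack(
            [values[rng.permutation(n), j] for j in range(p)]
        )
        Rp = correlation_matrix(perm, method=R.method)
        ref[it] = eigenvalues(Rp)
    reference = ref.mean(axis=0)
    k_hat = consecutive_exceedance(observed, reference)
    trace = pd.DataFrame(
        {
            "k": np.arange(1, p + 1),
            "observed_eigenvalue": observed,
            "reference_eigenvalue": reference,
        }
    )
    return RetentionEstimate("pa", k_hat, trace)


def velicer_map(R, k_max: int | None = None) -> RetentionEstimate:
    """Velicer's minimum average partial procedure.

    For m = 0..k_max, partial the first m principal components out of R
    and record the average squared off-diagonal partial correlation; the
    estimate is the m minimizing that average (ties to the smallest m).
    """
    Rm, _ = _as_corr(R)
    p = Rm.shape[0]
    if np.linalg.eigvalsh(Rm)[0] < -1e-8:
        Rm = nearest_positive_definite(Rm)
    if k_max is None:
        k_max = p - 2
    k_max = min(k_max, p - 2)
    w, v = np.linalg.eigh(Rm)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    offmask = ~np.eye(p, dtype=bool)
    stats: list[float] = []
    ks: list[int] = []
    for m in range(k_max + 1):
        if m == 0:
            C = Rm
        else:
            A = v[:, :m] * np.sqrt(np.maximum(w[:m], 0.0))
            C = Rm - A @ A.T
        dgs = np.diag(C).copy()
        if np.any(dgs <= 1e-12):
            continue  # inadmissible partialing at this m
        D = np.sqrt(dgs)
        partial = C / np.outer(D, D)
        stats.append(float(np.mean(partial[offmask] ** 2)))
        ks.append(m)
    stats_arr = np.asarray(stats)
    k_hat = int(ks[int(np.argmin(stats_arr))])
    trace = pd.DataFrame({"k": ks, "map_statistic": stats})
    return RetentionEstimate("map", k_hat, trace)


def _fml(R: np.ndarray, L: np.ndarray, uniq: np.ndarray) -> float:
    """ML discrepancy F = log|Rhat| + tr(R Rhat^-1) - log|R| - p."""
    p = R.shape[0]
    Rhat = L @ L.T + np.diag(uniq)
    sign_h, ld_h = np.linalg.slogdet(Rhat)
    sign_r, ld_r = np.linalg.slogdet(R)
    if sign_h <= 0 or sign_r <= 0:
        return np.inf
    return float(ld_h + np.trace(R @ np.linalg.inv(Rhat)) - ld_r - p)


def efa_fit(R, n: int, k: int) -> EFAFit:
    """Maximum-likelihood exploratory factor fit with Bartlett-corrected
    chi-square.

    df = ((p-k)^2 - (p+k)) / 2 must be nonnegative; Heywood cases
    (communalities at 1) are flagged, as is optimizer nonconvergence.
    """
    from statsmodels.multivariate.factor import Factor

    Rm, _ = _as_corr(R)
    p = Rm.shape[0]
    df = ((p - k) ** 2 - (p + k)) // 2
    if df < 0:
        raise ValueError(f"k={k} inadmissible for p={p}: negative df")
    if np.linalg.eigvalsh(Rm)[0] < 1e-10:
        Rm = nearest_positive_definite(Rm)
    n_params = p * (k + 1) - k * (k - 1) // 2
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = Factor(corr=Rm, n_factor=k, method="ml", nobs=n).fit()
            L = np.asarray(res.loadings)
            uniq = np.asarray(res.uniqueness)
            converged = bool(getattr(res, "mle_retvals", {}).get("success", True))
        except Exception:
            return EFAFit(k, np.zeros((p, k)), np.zeros(p), np.nan, df,
                          n_params, np.nan, False, False)
    comm = np.sum(L * L, axis=1)
    heywood = bool(np.any(comm > 1 + 1e-6))
    comm = np.clip(comm, 0.0, 1.0)
    f = _fml(Rm, L, np.clip(uniq, 1e-8, None))
    bartlett = n - 1 - (2 * p + 5) / 6.0 - 2.0 * k / 3.0
    chi2 = bartlett * f
    if df == 0:
        chi2 = max(chi2, 0.0)
    return EFAFit(k, L, comm, float(chi2), int(df), int(n_params), float(f),
                  converged, heywood)


def _max_admissible_k(p: int, k_max: int) -> int:
    k = 0
    for kk in range(1, k_max + 1):
        if ((p - kk) ** 2 - (p + kk)) // 2 >= 0:
            k = kk
    return k


def vss(data_or_R, n: int | None = None, k_max: int = 10,
        complexity: int = 1) -> RetentionEstimate:
    """Very simple structure criterion at complexity one.

    Each candidate solution is varimax-rotated and simplified to its
    single largest-magnitude loading per item; the VSS statistic is the
    proportion of the off-diagonal correlation sum of squares that the
    simplified model reproduces.  The estimate is the smallest k
    attaining the maximum.
    """
    from statsmodels.multivariate.factor_rotation import rotate_factors

    if complexity != 1:
        raise NotImplementedError("only complexity-1 VSS is provided")
    Rm, n_obs = _prepare(data_or_R, n)
    p = Rm.shape[0]
    k_max = min(_max_admissible_k(p, k_max), p // 2)
    offmask = np.triu(np.ones((p, p), dtype=bool), k=1)
    denom = float(np.sum(Rm[offmask] ** 2))
    ks, stats = [], []
    for k in range(1, k_max + 1):
        fit = efa_fit(Rm, n_obs, k)
        if not fit.converged:
            warnings.warn(f"VSS: EFA with k={k} did not converge; skipped",
                          stacklevel=2)
            continue
        L = fit.loadings
        if k > 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                L, _ = rotate_factors(L, "varimax")
        simple = np.zeros_like(L)
        best = np.argmax(np.abs(L), axis=1)
        simple[np.arange(p), best] = L[np.arange(p), best]
        Rhat = simple @ simple.T
        resid = float(np.sum((Rm[offmask] - Rhat[offmask]) ** 2))
        ks.append(k)
        stats.append(1.0 - resid / denom)
    stats_arr = np.asarray(stats)
    k_hat = int(ks[int(np.argmax(stats_arr))])
    trace = pd.DataFrame({"k": ks, "vss_statistic": stats})
    return RetentionEstimate("vss", k_hat, trace)


def information_retention(data_or_R, n: int | None = None, k_max: int = 10,
                          gamma: float = 0.5
                          ) -> tuple[RetentionEstimate, RetentionEstimate]:
    """Dimension selection by BIC and extended BIC over 1..k_max factor fits.

    BIC(k) = chi2(k) - df(k) log n; EBIC(k) adds 2 gamma q_k log p, where
    q_k is the number of free model parameters.  Both pick the argmin over
    converged fits, ties to the smallest k.
    """
    Rm, n_obs = _prepare(data_or_R, n)
    p = Rm.shape[0]
    k_max = _max_admissible_k(p, k_max)
    rows = []
    for k in range(1, k_max + 1):
        fit = efa_fit(Rm, n_obs, k)
        if not np.isfinite(fit.chi_square):
            continue
        bic = fit.chi_square - fit.df * np.log(n_obs)
        ebic = bic + 2.0 * gamma * fit.n_params * np.log(p)
        rows.append(
            {"k": k, "chi_square": fit.chi_square, "df": fit.df,
             "bic": bic, "ebic": ebic, "converged": fit.converged}
        )
    if not rows:
        raise RuntimeError("all factor fits failed")
    trace = pd.DataFrame(rows)
    ok = trace[trace["converged"]]
    pool = ok if len(ok) else trace
    k_bic = int(pool.loc[pool["bic"].idxmin(), "k"])
    k_ebic = int(pool.loc[pool["ebic"].idxmin(), "k"])
    return (
        RetentionEstimate("bic", k_bic, trace),
        RetentionEstimate("ebic", k_ebic, trace),
    )


def _prepare(data_or_R, n: int | None) -> tuple[np.ndarray, int]:
    """Accept raw data or a correlation matrix; return (R, n)."""
    if isinstance(data_or_R, CorrelationMatrix):
        Rm = np.asarray(data_or_R.values, float)
        n_obs = n if n is not None else data_or_R.n_obs
    else:
        arr = np.asarray(
            data_or_R.values if hasattr(data_or_R, "item_labels")
            else data_or_R, dtype=float
        )
        if arr.ndim == 2 and arr.shape[0] == arr.shape[1] and np.allclose(
            np.diag(arr), 1.0
        ) and np.allclose(arr, arr.T, atol=1e-10) and n is not None:
            Rm, n_obs = arr, n
        else:
            R = correlation_matrix(arr)
            Rm, n_obs = np.asarray(R.values), R.n_obs
    if n_obs is None:
        raise ValueError("a sample size n is required with a bare matrix")
    return Rm, int(n_obs)
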