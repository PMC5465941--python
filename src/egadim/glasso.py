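"""L1-penalized Gaussian graphical model estimation with EBIC selection.

The penalized problem is

    maximize  log det K - tr(S K) - lambda * sum_{i != j} |k_ij|

over positive-definite K, with the diagonal unpenalized.  It is solved by
an alternating-direction method of multipliers (ADMM) splitting: the
smooth update is an eigenvalue shrinkage, the penalty update an
element-wise soft threshold, so the returned precision matrix carries
exact zeros.  Warm starts make the 100-value regularization path cheap.

Model selection follows the extended BIC for graphs,

    EBIC = -2 l + E log n + 4 gamma E log p,

with l = (n/2)(log det K - tr(S K)) and E the number of edges; the path
runs from lambda_max (the largest absolute off-diagonal of S, where the
graph is empty) down to ``lambda_min_ratio * lambda_max`` and the fit
with the smallest EBIC is selected, ties resolved toward the sparser
(larger lambda) fit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .polychoric import CorrelationMatrix

__all__ = [
    "GlassoFit",
    "GlassoError",
    "glasso_fit",
    "partial_correlations",
    "ebic_score",
    "select_network",
    "write_edge_list",
    "write_graphml",
]

#: Entries of the ADMM solution below this magnitude count as structural zeros.
ZERO_TOL = 1e-10


class GlassoError(RuntimeError):
    """Estimation failure; carries the offending penalty value."""

    def __init__(self, message: str, lam: float | None = None):
        super().__init__(message)
        self.lam = lam


@dataclass(frozen=True)
class GlassoFit:
    """One penalized precision-matrix solution along the path."""

    lam: float
    precision: np.ndarray
    partial_corr: np.ndarray
    n_edges: int
    loglik: float
    ebic: float
    gamma: float
    n_obs: int

    @property
    def edges(self) -> list[tuple[int, int, float]]:
        iu = np.triu_indices_from(self.partial_corr, k=1)
        out = []
        for i, j in zip(*iu):
            w = self.partial_corr[i, j]
            if w != 0.0:
                out.append((int(i), int(j), float(w)))
        return out


def partial_correlations(K: np.ndarray) -> np.ndarray:
    """Standardize a precision matrix to partial correlations.

    rho_ij = -k_ij / sqrt(k_ii k_jj) off the diagonal, zero on it.
    """
    K = np.asarray(K, dtype=float)
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("precision matrix must be symmetric")
    d = np.diag(K)
    if np.any(d <= 0):
        raise ValueError("precision matrix must have positive diagonal")
    s = np.sqrt(d)
    P = -K / np.outer(s, s)
    np.fill_diagonal(P, 0.0)
    return P


def ebic_score(loglik: float, n_edges: int, n: int, p: int, gamma: float) -> float:
    """Extended BIC for a Gaussian graphical model with E edges."""
    if n < 2:
        raise ValueError("n must be at least 2")
    return -2.0 * loglik + n_edges * np.log(n) + 4.0 * gamma * n_edges * np.log(p)


def _admm(S: np.ndarray, lam: float, rho: float = 1.0, tol: float = 1e-6,
          max_iter: int = 2000, Z: np.ndarray | None = None,
          U: np.ndarray | None = None):
    """ADMM iterations for the off-diagonal-penalized graphical lasso."""
    p = S.shape[0]
    if Z is None:
        Z = np.eye(p)
    if U is None:
        U = np.zeros((p, p))
    pen = np.full((p, p), lam / rho)
    np.fill_diagonal(pen, 0.0)
    for it in range(max_iter):
        d, Q = np.linalg.eigh(rho * (Z - U) - S)
        xd = (d + np.sqrt(d * d + 4.0 * rho)) / (2.0 * rho)
        X = (Q * xd) @ Q.T
        Z_old = Z
        A = X + U
        Z = np.sign(A) * np.maximum(np.abs(A) - pen, 0.0)
        U = U + X - Z
        r_norm = np.linalg.norm(X - Z)
        s_norm = rho * np.linalg.norm(Z - Z_old)
        eps = tol * p + tol * max(np.linalg.norm(X), np.linalg.norm(Z))
        if r_norm < eps and s_norm < 10.0 * eps:
            return Z, U, True
    return Z, U, False


def glasso_fit(S: CorrelationMatrix | np.ndarray, lam: float, n: int,
               gamma: float = 0.5, tol: float = 1e-6,
               warm: tuple[np.ndarray, np.ndarray] | None = None) -> GlassoFit:
    """Fit the graphical lasso at a single penalty value.

    At ``lam = 0`` the solution is the unpenalized MLE ``inv(S)``.  The
    ``warm`` pair (Z, U) carries ADMM state between neighbouring penalty
    values on a path.
    """
    Sm = S.values if isinstance(S, CorrelationMatrix) else np.asarray(S, float)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if n < 2:
        raise ValueError("n must be at least 2")
    p = Sm.shape[0]
    if lam == 0.0:
        try:
            K = np.linalg.inv(Sm)
        except np.linalg.LinAlgError as exc:
            raise GlassoError(f"singular input at lambda=0: {exc}", 0.0) from exc
        K = (K + K.T) / 2.0
        state = None
    else:
        Z0, U0 = warm if warm is not None else (None, None)
        K, U, converged = _admm(Sm, lam, tol=tol, Z=Z0, U=U0)
        if not converged:
            raise GlassoError(f"ADMM did not converge at lambda={lam:g}", lam)
        state = (K, U)
    K = np.where(np.abs(K) < ZERO_TOL, 0.0, K)
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise GlassoError(f"estimated precision not PD at lambda={lam:g}", lam)
    loglik = 0.5 * n * (logdet - np.trace(Sm @ K))
    pcor = partial_correlations(K)
    iu = np.triu_indices(p, k=1)
    n_edges = int(np.count_nonzero(pcor[iu]))
    fit = GlassoFit(
        lam=float(lam), precision=K, partial_corr=pcor, n_edges=n_edges,
        loglik=float(loglik),
        ebic=float(ebic_score(loglik, n_edges, n, p, gamma)),
        gamma=gamma, n_obs=n,
    )
    fit.__dict__["_warm"] = state  # path plumbing, not part of the API
    return fit


def select_network(S: CorrelationMatrix | np.ndarray, n: int,
                   n_lambda: int = 100, gamma: float = 0.5,
                   lambda_min_ratio: float = 0.01) -> GlassoFit:
    """Fit a logarithmic path of penalties and return the minimum-EBIC fit.

    The path has ``n_lambda`` values from lambda_max = max |S_offdiag| down
    to ``lambda_min_ratio * lambda_max``.  Ties on EBIC resolve to the
    larger penalty (sparser network).  Individual penalty values that fail
    to converge are skipped; if every value fails a :class:`GlassoError`
    aggregating the failures is raised.
    """
    Sm = S.values if isinstance(S, CorrelationMatrix) else np.asarray(S, float)
    p = Sm.shape[0]
    off = np.abs(Sm - np.diag(np.diag(Sm)))
    lam_max = float(off.max())
    if lam_max == 0.0:
        return glasso_fit(Sm, 0.0, n, gamma=gamma)
    path = np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambda)
    best: GlassoFit | None = None
    warm = None
    failures: list[str] = []
    for lam in path:
        try:
            fit = glasso_fit(Sm, float(lam), n, gamma=gamma, warm=warm)
        except GlassoError as exc:
            failures.append(str(exc))
            continue
        warm = fit.__dict__.get("_warm")
        if best is None or fit.ebic < best.ebic:
            best = fit
    if best is None:
        raise GlassoError(
            "all penalty values failed: " + "; ".join(failures[:5])
        )
    return best


def write_edge_list(fit: GlassoFit, path: str | Path,
                    labels: tuple[str, ...] | None = None) -> None:
    """Write the selected network as a weighted edge-list CSV."""
    p = fit.partial_corr.shape[0]
    labels = labels or tuple(f"item_{i + 1}" for i in range(p))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["item_i", "item_j", "partial_correlation"])
        for i, j, weight in fit.edges:
            w.writerow([labels[i], labels[j], f"{weight:.10g}"])


def write_graphml(fit: GlassoFit, path: str | Path,
                  labels: tuple[str, ...] | None = None) -> None:
    """Minimal GraphML export of the weighted selected network."""
    p = fit.partial_corr.shape[0]
    labels = labels or tuple(f"item_{i + 1}" for i in range(p))
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<graphml xmlns="http://graphml.graphdrawing.org/xmlns">',
        '  <key id="w" for="edge" attr.name="weight" attr.type="double"/>',
        '  <graph edgedefault="undirected">',
    ]
    for lab in labels:
        lines.append(f'    <node id="{lab}"/>')
    for i, j, weight in fit.edges:
        lines.append(
            f'    <edge source="{labels[i]}" target="{labels[j]}">'
            f'<data key="w">{weight:.10g}</data></edge>'
        )
    lines += ["  </graph>", "</graphml>", ""]
    Path(path).write_text("\n".join(lines))
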