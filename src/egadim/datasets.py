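"""Synthetic item-response data from block simple-structure factor models.

The generating model is the common-factor model Sigma = Lambda Psi Lambda' +
Theta with one nonzero loading per item (simple structure), equicorrelated
factors (Psi = (1 - rho) I + rho J), and diagonal residual covariance
(local independence).  Latent multivariate-normal responses are dichotomized
at their theoretical mean of zero, giving Bernoulli(1/2) items whose latent
(tetrachoric) correlation is loading^2 * rho_between / item variance.

At the default unit loadings and unit variances, two items of the same
factor have latent correlation 1/2 and items of different factors have
latent correlation rho/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FactorDesign",
    "PopulationModel",
    "ItemResponseMatrix",
    "population_model",
    "simulate_binary",
    "simulate_ordinal",
    "condition_grid",
    "write_dataset",
]

#: Levels of the 2 x 2 x 4 x 4 simulation grid.
GRID_FACTORS = (2, 4)
GRID_ITEMS_PER_FACTOR = (5, 10)
GRID_SAMPLE_SIZES = (100, 500, 1000, 5000)
GRID_FACTOR_CORRELATIONS = (0.0, 0.2, 0.5, 0.7)


class InvalidDesignError(ValueError):
    """Raised when a factor design implies a non-positive-definite model."""


@dataclass(frozen=True)
class FactorDesign:
    """Parameters of one simulation condition.

    Parameters
    ----------
    n_factors : int
        Number of latent factors M.
    items_per_factor : int
        Items loading on each factor; total items p = M * items_per_factor.
    factor_corr : float
        Common inter-factor correlation rho.  Must exceed -1/(M-1) for the
        equicorrelation matrix to be positive definite.
    loading : float
        Factor loading shared by every item (default 1.0).
    residual_var : float
        Residual (uniqueness) variance of every item (default 1.0).
    n_obs : int
        Number of respondents to simulate.
    seed : int
        Seed for the dataset-level random generator.
    """

    n_factors: int
    items_per_factor: int
    factor_corr: float
    n_obs: int
    loading: float = 1.0
    residual_var: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_factors < 1:
            raise InvalidDesignError("n_factors must be a positive integer")
        if self.items_per_factor < 1:
            raise InvalidDesignError("items_per_factor must be a positive integer")
        if self.residual_var <= 0:
            raise InvalidDesignError("residual_var must be positive")
        if self.n_factors > 1:
            lower = -1.0 / (self.n_factors - 1)
            if not (lower < self.factor_corr < 1.0):
                raise InvalidDesignError(
                    f"factor_corr={self.factor_corr} outside ({lower:.4f}, 1) "
                    f"for {self.n_factors} factors"
                )
        elif not (-1.0 < self.factor_corr < 1.0):
            raise InvalidDesignError("factor_corr must lie in (-1, 1)")

    @property
    def n_items(self) -> int:
        return self.n_factors * self.items_per_factor

    def with_seed(self, seed: int) -> "FactorDesign":
        return replace(self, seed=seed)

    def to_dict(self) -> dict:
        return {
            "n_factors": self.n_factors,
            "items_per_factor": self.items_per_factor,
            "factor_corr": self.factor_corr,
            "n_obs": self.n_obs,
            "loading": self.loading,
            "residual_var": self.residual_var,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class PopulationModel:
    """Population matrices implied by a :class:`FactorDesign`.

    ``Sigma = Lambda @ Psi @ Lambda.T + Theta`` and ``Precision`` is its
    inverse.  When the factors are orthogonal the precision matrix is block
    diagonal, so the implied Gaussian graphical model consists of
    unconnected clusters, one per factor.
    """

    Lambda: np.ndarray
    Psi: np.ndarray
    Theta: np.ndarray
    Sigma: np.ndarray
    Precision: np.ndarray

    @property
    def correlation(self) -> np.ndarray:
        """Sigma rescaled to unit diagonal (the population latent correlation)."""
        d = np.sqrt(np.diag(self.Sigma))
        return self.Sigma / np.outer(d, d)


@dataclass(frozen=True)
class ItemResponseMatrix:
    """Integer-coded respondents-by-items table.

    Entries are 0/1 for dichotomous items, 0..c-1 for ordinal ones.  Columns
    may be constant for small n; downstream estimators must reject those
    explicitly rather than silently produce undefined correlations.
    """

    values: np.ndarray
    item_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if len(self.item_labels) != v.shape[1]:
            raise ValueError("item_labels length must match the number of columns")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.item_labels))


def _default_labels(p: int) -> tuple[str, ...]:
    return tuple(f"item_{i + 1}" for i in range(p))


def population_model(design: FactorDesign) -> PopulationModel:
    """Build Lambda, Psi, Theta, Sigma and the precision matrix for a design.

    Raises
    ------
    InvalidDesignError
        If the implied Psi or Sigma is not positive definite.
    """
    m, q = design.n_factors, design.items_per_factor
    p = design.n_items
    Lambda = np.zeros((p, m))
    for j in range(m):
        Lambda[j * q : (j + 1) * q, j] = design.loading
    Psi = np.full((m, m), design.factor_corr)
    np.fill_diagonal(Psi, 1.0)
    if np.linalg.eigvalsh(Psi)[0] <= 0:
        raise InvalidDesignError("factor covariance Psi is not positive definite")
    Theta = np.eye(p) * design.residual_var
    Sigma = Lambda @ Psi @ Lambda.T + Theta
    if np.linalg.eigvalsh(Sigma)[0] <= 0:
        raise InvalidDesignError("implied Sigma is not positive definite")
    Precision = np.linalg.inv(Sigma)
    return PopulationModel(Lambda, Psi, Theta, Sigma, Precision)


def simulate_binary(design: FactorDesign) -> ItemResponseMatrix:
    """Draw n_obs latent multivariate-normal rows and dichotomize at zero.

    A response is 1 iff the latent item value exceeds its theoretical mean
    of zero; since the latent distribution is centered, each item is
    Bernoulli(1/2) in the population.  Reproducible given ``design.seed``.
    """
    if design.n_obs < 2:
        raise ValueError("n_obs must be at least 2")
    model = population_model(design)
    rng = np.random.default_rng(design.seed)
    chol = np.linalg.cholesky(model.Sigma)
    latent = rng.standard_normal((design.n_obs, design.n_items)) @ chol.T
    values = (latent > 0).astype(np.int8)
    return ItemResponseMatrix(values, _default_labels(design.n_items))


def simulate_ordinal(design: FactorDesign, n_categories: int) -> ItemResponseMatrix:
    """Ordinal extension: cut the latent normals at equally spaced normal
    quantiles into ``n_categories`` codes 0..c-1.

    Provided for completeness; the dichotomous generator above is the one
    matching the study conditions.
    """
    from scipy.stats import norm

    if n_categories < 2:
        raise ValueError("n_categories must be >= 2")
    if design.n_obs < 2:
        raise ValueError("n_obs must be at least 2")
    model = population_model(design)
    rng = np.random.default_rng(design.seed)
    chol = np.linalg.cholesky(model.Sigma)
    latent = rng.standard_normal((design.n_obs, design.n_items)) @ chol.T
    sd = np.sqrt(np.diag(model.Sigma))
    cuts = norm.ppf(np.linspace(0, 1, n_categories + 1)[1:-1])
    values = np.zeros(latent.shape, dtype=np.int8)
    for c in cuts:
        values += (latent / sd > c).astype(np.int8)
    return ItemResponseMatrix(values, _default_labels(design.n_items))


def condition_grid() -> list[FactorDesign]:
    """Enumerate the 64 = 2 x 2 x 4 x 4 simulation conditions.

    Ordering is stable: factors, then items per factor, then sample size,
    then factor correlation, each in increasing order.
    """
    grid = []
    for m in GRID_FACTORS:
        for q in GRID_ITEMS_PER_FACTOR:
            for n in GRID_SAMPLE_SIZES:
                for rho in GRID_FACTOR_CORRELATIONS:
                    grid.append(
                        FactorDesign(
                            n_factors=m,
                            items_per_factor=q,
                            factor_corr=rho,
                            n_obs=n,
                        )
                    )
    return grid


def write_dataset(data: ItemResponseMatrix, path: str | Path,
                  design: FactorDesign | None = None) -> None:
    """Write responses as headered CSV; if a design is given, write a JSON
    sidecar ``<path>.json`` with its parameters and seed."""
    path = Path(path)
    data.to_frame().to_csv(path, index=False)
    if design is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(design.to_dict(), indent=2) + "\n")
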