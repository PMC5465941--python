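"""Exploratory graph analysis: dimensionality from network communities.

EGA estimates the number of latent dimensions of an item pool in three
steps: (1) estimate the latent item correlation matrix (tetrachoric /
polychoric for categorical items), (2) fit a sparse Gaussian graphical
model by the graphical lasso with the penalty chosen by EBIC over a
100-value path, (3) count the walktrap communities of the resulting
partial-correlation network.  Under a simple-structure factor model each
factor appears as a densely connected cluster, so the community count
estimates the number of factors and the community assignment indicates
which items measure which dimension.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .community import CommunityPartition, walktrap_partition
from .glasso import GlassoFit, select_network
from .polychoric import ConstantColumnError, CorrelationMatrix, correlation_matrix

__all__ = ["EGAResult", "ega", "ega_from_correlation"]


@dataclass(frozen=True)
class EGAResult:
    """Full record of one EGA run.

    ``ndim`` is the walktrap community count of the selected network;
    ``dim_variables`` maps every item to its estimated dimension.
    """

    ndim: int
    correlation: CorrelationMatrix
    network: GlassoFit
    membership: CommunityPartition
    dim_variables: pd.DataFrame

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "ndim": self.ndim,
            "lambda": self.network.lam,
            "ebic": self.network.ebic,
            "n_edges": self.network.n_edges,
            "membership": self.membership.membership.tolist(),
            "items": self.dim_variables["item"].tolist(),
            "dimensions": self.dim_variables["dimension"].tolist(),
            "edges": [
                {"i": i, "j": j, "weight": w} for i, j, w in self.network.edges
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def ega_from_correlation(R: CorrelationMatrix, n: int | None = None,
                         gamma: float = 0.5, steps: int = 4,
                         n_lambda: int = 100,
                         lambda_min_ratio: float = 0.01) -> EGAResult:
    """Run the network and community stages on a ready correlation matrix.

    Useful for population-level analyses where the correlation matrix is
    known exactly; ``n`` is the (nominal) sample size entering the EBIC.
    """
    n = int(n if n is not None else R.n_obs)
    fit = select_network(R, n, n_lambda=n_lambda, gamma=gamma,
                         lambda_min_ratio=lambda_min_ratio)
    partition = walktrap_partition(np.abs(fit.partial_corr), steps=steps)
    labels = R.item_labels or tuple(
        f"item_{i + 1}" for i in range(R.n_items)
    )
    dim_variables = pd.DataFrame(
        {"item": list(labels), "dimension": partition.membership}
    )
    return EGAResult(
        ndim=partition.n_communities,
        correlation=R,
        network=fit,
        membership=partition,
        dim_variables=dim_variables,
    )


def ega(data, gamma: float = 0.5, steps: int = 4, n_lambda: int = 100,
        lambda_min_ratio: float = 0.01, corr_method: str = "auto") -> EGAResult:
    """Estimate the number of dimensions of an item-response table.

    Parameters
    ----------
    data : ItemResponseMatrix, DataFrame or array
        Respondents by items; at least 3 rows and 3 non-constant columns.
    gamma : float
        EBIC hyperparameter (0.5 default; 0 gives plain BIC).
    steps : int
        Walktrap random-walk length.
    corr_method : str
        Correlation estimator, "auto" detects binary/ordinal/continuous.

    Raises
    ------
    ConstantColumnError
        If any item is constant (stage and items are named).
    """
    try:
        R = correlation_matrix(data, method=corr_method)
    except ConstantColumnError as exc:
        raise ConstantColumnError(f"correlation stage failed: {exc}") from exc
    if R.n_items < 3:
        raise ValueError("EGA needs at least 3 items")
    return ega_from_correlation(
        R, n=R.n_obs, gamma=gamma, steps=steps, n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio,
    )
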