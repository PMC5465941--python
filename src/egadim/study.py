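"""Monte Carlo comparison of dimension-retention methods.

For every condition of the factorial grid (number of factors x items per
factor x sample size x inter-factor correlation), replicate datasets are
simulated, every requested method produces a dimension estimate, and
three indexes summarize each (condition, method) cell:

* accuracy  — proportion of replicates recovering the true number of
  factors exactly;
* MBE       — mean bias error, mean of (estimate - truth), positive when a
  method overfactors;
* MAE       — mean absolute error, mean of |estimate - truth|.

A full-factorial ANOVA on the replicate-level 0/1 accuracy yields the
partial eta-squared effect size of every main effect and interaction of
the four design factors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import FactorDesign, simulate_binary
from .ega import ega
from .polychoric import correlation_matrix
from .retention import (
    eigenvalues,
    information_retention,
    kaiser_rule,
    parallel_analysis,
    velicer_map,
    vss,
)

__all__ = [
    "ConditionSummary",
    "ALL_METHODS",
    "estimate_dimensions",
    "summarize_estimates",
    "evaluate_condition",
    "run_study",
    "aggregate_study",
    "partial_eta_squared",
]

logger = logging.getLogger(__name__)

ALL_METHODS = ("vss", "map", "bic", "ebic", "kaiser", "pa", "ega")

#: Design factors entering the accuracy ANOVA.
ANOVA_FACTORS = ("factor_corr", "n_obs", "items_per_factor", "n_factors")


@dataclass(frozen=True)
class ConditionSummary:
    """Accuracy / bias aggregates for one method in one condition."""

    design: FactorDesign
    method: str
    n_reps: int
    accuracy_mean: float
    accuracy_sd: float
    mbe: float
    mae: float
    n_failures: int


def summarize_estimates(estimates, truth: int) -> dict:
    """Accuracy, MBE and MAE of a sequence of dimension estimates.

    Failed estimates are passed as NaN: they count as inaccurate, and
    their bias is excluded from MBE / MAE (their count is reported).
    """
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("no estimates to summarize")
    ok = ~np.isnan(est)
    hits = (est == truth) & ok
    acc = hits.astype(float)
    bias = est[ok] - truth
    return {
        "n_reps": int(est.size),
        "accuracy_mean": float(acc.mean()),
        "accuracy_sd": float(acc.std(ddof=1)) if est.size > 1 else 0.0,
        "mbe": float(bias.mean()) if bias.size else np.nan,
        "mae": float(np.abs(bias).mean()) if bias.size else np.nan,
        "n_failures": int(np.sum(~ok)),
    }


def estimate_dimensions(data, methods=ALL_METHODS, seed: int = 0,
                        pa_iterations: int = 20, k_max: int = 10,
                        gamma: float = 0.5, steps: int = 4) -> dict[str, float]:
    """Apply the requested retention methods to one dataset.

    The tetrachoric correlation matrix is computed once and shared by
    every eigenvalue / factor-model based method.  A method failure is
    reported as NaN rather than raised.
    """
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown method(s): {sorted(unknown)}")
    out: dict[str, float] = {}
    need_corr = {"map", "kaiser", "vss", "bic", "ebic"} & set(methods)
    R = correlation_matrix(data) if need_corr else None
    info = None  # BIC and EBIC share the same factor fits
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in methods:
            try:
                if method == "ega":
                    out[method] = ega(data, gamma=gamma, steps=steps).ndim
                elif method == "pa":
                    out[method] = parallel_analysis(
                        data, n_iter=pa_iterations, seed=seed
                    ).k_hat
                elif method == "kaiser":
                    out[method] = kaiser_rule(eigenvalues(R))
                elif method == "map":
                    out[method] = velicer_map(R, k_max=k_max).k_hat
                elif method == "vss":
                    out[method] = vss(R, n=R.n_obs, k_max=k_max).k_hat
                elif method in ("bic", "ebic"):
                    if info is None:
                        info = information_retention(
                            R, n=R.n_obs, k_max=k_max, gamma=gamma
                        )
                    out[method] = info[0 if method == "bic" else 1].k_hat
            except Exception as exc:  # estimation failure -> missing
                logger.warning("method %s failed: %s", method, exc)
                out[method] = np.nan
    return out


def replicate_seed(study_seed: int, condition_index: int, replicate: int) -> int:
    """Deterministic dataset seed from (study seed, condition, replicate)."""
    ss = np.random.SeedSequence([study_seed, condition_index, replicate])
    return int(ss.generate_state(1)[0] % (2**31))


def evaluate_condition(design: FactorDesign, methods=ALL_METHODS,
                       n_reps: int = 500, seed: int = 0,
                       condition_index: int = 0,
                       **method_kwargs) -> tuple[list[ConditionSummary], pd.DataFrame]:
    """Simulate replicates of one condition and score every method.

    Returns per-method summaries and the replicate-level table (one row
    per replicate and method, with the estimate and its correctness).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    truth = design.n_factors
    records = []
    for rep in range(n_reps):
        ds = replicate_seed(seed, condition_index, rep)
        data = simulate_binary(design.with_seed(ds))
        est = estimate_dimensions(data, methods=methods, seed=ds,
                                  **method_kwargs)
        for method, k_hat in est.items():
            records.append(
                {
                    "n_factors": design.n_factors,
                    "items_per_factor": design.items_per_factor,
                    "factor_corr": design.factor_corr,
                    "n_obs": design.n_obs,
                    "replicate": rep,
                    "method": method,
                    "k_hat": k_hat,
                    "correct": float(k_hat == truth),
                }
            )
    table = pd.DataFrame.from_records(records)
    summaries = []
    for method in methods:
        est = table.loc[table["method"] == method, "k_hat"].to_numpy()
        s = summarize_estimates(est, truth)
        summaries.append(ConditionSummary(design=design, method=method, **s))
    return summaries, table


def run_study(grid, methods=ALL_METHODS, n_reps: int = 500, seed: int = 0,
              progress: bool = False,
              **method_kwargs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the Monte Carlo over a grid of conditions.

    Returns ``(summary, replicates)``: the tidy per-(condition, method)
    summary table and the replicate-level table used for aggregation and
    the ANOVA.  Deterministic given ``seed``.
    """
    import time

    grid = list(grid)
    if not grid:
        raise ValueError("grid must be nonempty")
    all_summaries = []
    all_tables = []
    for idx, design in enumerate(grid):
        t0 = time.time()
        summaries, table = evaluate_condition(
            design, methods=methods, n_reps=n_reps, seed=seed,
            condition_index=idx, **method_kwargs
        )
        all_tables.append(table)
        for s in summaries:
            all_summaries.append(
                {
                    "n_factors": s.design.n_factors,
                    "items_per_factor": s.design.items_per_factor,
                    "factor_corr": s.design.factor_corr,
                    "n_obs": s.design.n_obs,
                    "method": s.method,
                    "n_reps": s.n_reps,
                    "accuracy_mean": s.accuracy_mean,
                    "accuracy_sd": s.accuracy_sd,
                    "mbe": s.mbe,
                    "mae": s.mae,
                    "n_failures": s.n_failures,
                }
            )
        if progress:
            logger.info(
                "condition %d/%d (M=%d q=%d rho=%.1f n=%d) done in %.1fs",
                idx + 1, len(grid), design.n_factors, design.items_per_factor,
                design.factor_corr, design.n_obs, time.time() - t0,
            )
    return pd.DataFrame(all_summaries), pd.concat(all_tables, ignore_index=True)


def aggregate_study(replicates: pd.DataFrame) -> pd.DataFrame:
    """Marginal accuracy aggregates by correlation, sample size and items
    per factor, mirroring the layout of the per-structure summary tables."""
    rows = []
    for by in ("factor_corr", "n_obs", "items_per_factor", None):
        keys = ["method"] + ([by] if by else [])
        g = replicates.groupby(keys)["correct"].agg(["mean", "std", "size"])
        g = g.reset_index().rename(
            columns={"mean": "accuracy_mean", "std": "accuracy_sd",
                     "size": "n"}
        )
        g["margin"] = by or "total"
        rows.append(g)
    return pd.concat(rows, ignore_index=True)


def partial_eta_squared(replicates: pd.DataFrame, method: str) -> pd.DataFrame:
    """Partial eta-squared of every effect in the 4-way accuracy ANOVA.

    The replicate-level 0/1 correctness is the outcome; the four design
    factors and all their interactions are the effects.  The design must
    be balanced (equal replicate counts per cell) so the sums of squares
    decompose orthogonally.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    sub = replicates[replicates["method"] == method].copy()
    if sub.empty:
        raise ValueError(f"no replicates for method {method!r}")
    counts = sub.groupby(list(ANOVA_FACTORS)).size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: equal replicates per cell required")
    sub["correct"] = sub["correct"].astype(float)
    total_ss = float(np.sum((sub["correct"] - sub["correct"].mean()) ** 2))
    varying = [f for f in ANOVA_FACTORS if sub[f].nunique() > 1]
    if not varying:
        raise ValueError("no design factor varies in the replicate table")
    terms = "*".join(f"C({f})" for f in varying)
    model = smf.ols(f"correct ~ {terms}", data=sub).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(model, typ=2)
    ss_res = float(table.loc["Residual", "sum_sq"])
    rows = []
    for effect, row in table.iterrows():
        if effect == "Residual":
            continue
        ss = float(row["sum_sq"])
        denom = ss + ss_res
        # constant outcome: sums of squares are pure rounding noise
        eta = ss / denom if denom > 1e-10 * max(total_ss, 1.0) else 0.0
        rows.append(
            {
                "effect": effect.replace("C(", "").replace(")", ""),
                "sum_sq": ss,
                "partial_eta_sq": eta,
            }
        )
    out = pd.DataFrame(rows)
    out["ss_residual"] = ss_res
    return out
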