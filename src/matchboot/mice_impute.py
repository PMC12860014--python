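"""Multiple imputation by chained equations.

Each of the ``m`` chains starts from a random warm-start fill, then sweeps
the variables with missing cells in schema order for a fixed number of
rounds.  Conditional models: Bayesian linear regression followed by
predictive mean matching for continuous targets, logistic regression with a
Bernoulli draw from the predictive probability for binary targets, and
one-vs-rest logistic with a normalized categorical draw for categorical
targets.  The imputation model for every target includes all other
covariates plus the treatment arm and outcome indicators.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._logistic import add_intercept, fit_logistic
from .data_model import ARMS, OUTCOMES, CohortTable, CovariateSpec, ValidationError

logger = logging.getLogger(__name__)

RIDGE = 1e-4  # stabilizer for singular designs; logged when it changes a fit


@dataclass
class ImputationConfig:
    m: int = 50
    iterations: int = 5
    pmm_donors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.iterations < 1 or self.pmm_donors < 1:
            raise ValueError("m, iterations and pmm_donors must all be >= 1")


@dataclass
class ImputedCohorts:
    """m completed copies of a cohort sharing row identity."""

    datasets: list[CohortTable]
    config: ImputationConfig
    chain_seeds: list[int]
    imputed_mask: pd.DataFrame  # rows x covariates, True where a cell was imputed

    @property
    def m(self) -> int:
        return len(self.datasets)


def initialize_fill(cohort: CohortTable, rng: np.random.Generator) -> CohortTable:
    """Warm start: every missing cell drawn uniformly from the variable's
    observed values."""
    out = cohort.copy()
    for s in cohort.spec:
        col = out.df[s.name]
        miss = col.isna()
        if not miss.any():
            continue
        observed = col[~miss].to_numpy()
        if len(observed) == 0:
            raise ValidationError(
                f"variable {s.name!r} is fully missing; exclude it before imputation"
            )
        out.df.loc[miss, s.name] = rng.choice(observed, size=int(miss.sum()))
    out.validate()
    return out


def pmm_draw(
    target_prediction: float,
    observed_pairs: list[tuple[float, float]],
    k: int,
    rng: np.random.Generator,
) -> float:
    """Predictive mean matching: return the observed value of one of the k
    nearest observed predictions, chosen uniformly."""
    if not observed_pairs:
        raise ValueError("pmm_draw requires at least one observed pair")
    if k > len(observed_pairs):
        logger.debug("pmm donors clamped from %d to %d", k, len(observed_pairs))
        k = len(observed_pairs)
    preds = np.asarray([p for p, _ in observed_pairs], dtype=float)
    vals = np.asarray([v for _, v in observed_pairs], dtype=float)
    order = np.argsort(np.abs(preds - target_prediction), kind="stable")
    pick = order[rng.integers(k)]
    return float(vals[pick])


def _pmm_vectorized(
    pred_mis: np.ndarray,
    pred_obs: np.ndarray,
    y_obs: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    k = min(k, len(pred_obs))
    dist = np.abs(pred_mis[:, None] - pred_obs[None, :])
    nearest = np.argpartition(dist, kth=k - 1, axis=1)[:, :k]
    choice = rng.integers(k, size=len(pred_mis))
    return y_obs[nearest[np.arange(len(pred_mis)), choice]]


def _design_matrix(
    df: pd.DataFrame, spec: list[CovariateSpec], exclude: str
) -> np.ndarray:
    """Predictor matrix for imputing ``exclude``: all other covariates
    (dummy-coded, continuous standardized) + arm indicator + outcome dummies,
    plus an intercept column."""
    cols: list[np.ndarray] = []
    for s in spec:
        if s.name == exclude:
            continue
        if s.kind == "categorical":
            vals = df[s.name].to_numpy()
            for lv in s.levels[1:]:
                cols.append((vals == lv).astype(float))
        else:
            x = df[s.name].to_numpy(dtype=float)
            sd = x.std()
            if s.kind == "continuous" and sd > 0:
                x = (x - x.mean()) / sd
            cols.append(x)
    cols.append((df["arm"].to_numpy() == ARMS[0]).astype(float))
    out_vals = df["outcome"].to_numpy()
    for lv in OUTCOMES[1:]:
        cols.append((out_vals == lv).astype(float))
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return add_intercept(X)


def _impute_continuous(
    X: np.ndarray,
    y: np.ndarray,
    obs: np.ndarray,
    donors: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bayesian linear regression + PMM; returns values for the missing rows."""
    X_o, y_o = X[obs], y[obs]
    X_m = X[~obs]
    n_o, p = X_o.shape
    XtX = X_o.T @ X_o + RIDGE * np.eye(p)
    Xty = X_o.T @ y_o
    beta_hat = np.linalg.solve(XtX, Xty)
    resid = y_o - X_o @ beta_hat
    df_resid = max(n_o - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(df_resid)
    V = np.linalg.inv(XtX)
    V = (V + V.T) / 2
    try:
        L = np.linalg.cholesky(sigma2 * V + 1e-12 * np.eye(p))
    except np.linalg.LinAlgError:
        w, Q = np.linalg.eigh(sigma2 * V)
        L = Q @ np.diag(np.sqrt(np.clip(w, 0, None)))
    beta_draw = beta_hat + L @ rng.standard_normal(p)
    pred_obs = X_o @ beta_draw
    pred_mis = X_m @ beta_draw
    return _pmm_vectorized(pred_mis, pred_obs, y_o, donors, rng)


def _impute_binary(
    X: np.ndarray, y: np.ndarray, obs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    fit = fit_logistic(X[obs], y[obs], ridge_fallback=RIDGE)
    if fit.used_ridge:
        logger.debug("binary imputation model used ridge fallback")
    p = fit.predict_proba(X[~obs])
    return (rng.random(len(p)) < p).astype(float)


def _impute_categorical(
    X: np.ndarray,
    y: np.ndarray,
    levels: tuple[str, ...],
    obs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    probs = np.empty((int((~obs).sum()), len(levels)))
    for j, lv in enumerate(levels):
        fit = fit_logistic(X[obs], (y[obs] == lv).astype(float), ridge_fallback=RIDGE)
        probs[:, j] = fit.predict_proba(X[~obs])
    probs = np.clip(probs, 1e-12, None)
    probs /= probs.sum(axis=1, keepdims=True)
    cum = np.cumsum(probs, axis=1)
    u = rng.random(len(probs))
    idx = (u[:, None] > cum).sum(axis=1)
    return np.asarray(levels, dtype=object)[np.clip(idx, 0, len(levels) - 1)]


def impute_chained(cohort: CohortTable, config: ImputationConfig) -> ImputedCohorts:
    """Run m independent chained-equation chains and return the completed
    datasets.  Observed cells are carried through untouched."""
    miss = cohort.missing_mask()
    target_vars = [s for s in cohort.spec if miss[s.name].any()]
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.m)
    chain_seeds = [int(c.generate_state(1)[0]) for c in children]

    datasets: list[CohortTable] = []
    for chain_idx, child in enumerate(children):
        rng = np.random.default_rng(child)
        if not target_vars:
            datasets.append(cohort.copy())
            continue
        work = initialize_fill(cohort, rng)
        for _ in range(config.iterations):
            for s in target_vars:
                obs = (~miss[s.name]).to_numpy()
                X = _design_matrix(work.df, cohort.spec, exclude=s.name)
                if s.kind == "categorical":
                    y = work.df[s.name].to_numpy()
                    work.df.loc[~obs, s.name] = _impute_categorical(
                        X, y, s.levels, obs, rng
                    )
                else:
                    y = work.df[s.name].to_numpy(dtype=float)
                    if s.kind == "binary":
                        work.df.loc[~obs, s.name] = _impute_binary(X, y, obs, rng)
                    else:
                        work.df.loc[~obs, s.name] = _impute_continuous(
                            X, y, obs, config.pmm_donors, rng
                        )
        work.validate()
        datasets.append(work)

    return ImputedCohorts(
        datasets=datasets,
        config=config,
        chain_seeds=chain_seeds,
        imputed_mask=miss,
    )


def save_imputed(imputed: ImputedCohorts, outdir: str) -> None:
    """Write the m completed datasets plus a provenance manifest."""
    from .data_model import write_cohort

    os.makedirs(outdir, exist_ok=True)
    for i, ds in enumerate(imputed.datasets, start=1):
        write_cohort(ds, os.path.join(outdir, f"dataset_{i:02d}.csv"))
    manifest = {
        "m": imputed.config.m,
        "iterations": imputed.config.iterations,
        "pmm_donors": imputed.config.pmm_donors,
        "seed": imputed.config.seed,
        "chain_seeds": imputed.chain_seeds,
        "imputed_cells": {
            var: imputed.datasets[0].df.loc[imputed.imputed_mask[var], "id"].tolist()
            for var in imputed.imputed_mask.columns
            if imputed.imputed_mask[var].any()
        },
    }
    with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
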