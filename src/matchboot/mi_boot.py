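"""Bootstrap-within-multiple-imputation confidence intervals.

For each of the m imputed datasets, draw B unstratified bootstrap samples of
the rows; inside every replicate re-fit the propensity model, recompute the
caliper, re-match, and recompute the endpoint panel.  All replicate
estimates are pooled into a single distribution per endpoint; the point
estimate is the pooled median and the 95% CI the 2.5th / 97.5th percentiles
(type-7 / linear-interpolation order statistics).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ARMS, CohortTable, CovariateSpec, ValidationError, ps_covariates
from .propensity_match import (
    SCORE_CLIP,
    compute_caliper,
    design_matrix,
    match_caliper,
)
from ._logistic import add_intercept, fit_logistic
from scipy.special import logit

ENDPOINT_KEYS = (
    "death_pct_BLM",
    "death_pct_BL",
    "death_pct_diff",
    "recovery_pct_BLM",
    "recovery_pct_BL",
    "recovery_pct_diff",
    "abx_days_BLM",
    "abx_days_BL",
    "abx_days_diff",
    "los_days_BLM",
    "los_days_BL",
    "los_days_diff",
    "n_matched",
    "n_inpatient_matched",
)


@dataclass
class BootConfig:
    B: int = 1000
    seed: int = 0
    min_valid_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")


@dataclass
class InvalidReplicate:
    reason: str


@dataclass
class PooledDistribution:
    estimates: np.ndarray
    n_invalid: int
    reasons: Counter = field(default_factory=Counter)


@dataclass
class MiBootResult:
    distributions: dict[str, PooledDistribution]
    summary: dict[str, dict]
    n_replicates: int
    n_invalid_replicates: int


def _prepare_arrays(dataset: CohortTable, covariates: list[CovariateSpec]):
    X, _ = design_matrix(dataset, covariates)
    df = dataset.df
    return {
        "X": add_intercept(X),
        "treated": (df["arm"].to_numpy() == ARMS[0]),
        "death": (df["outcome"].to_numpy() == "death"),
        "recovery": (df["outcome"].to_numpy() == "recovery"),
        "abx": df["abx_days"].to_numpy(dtype=float),
        "los": df["los_days"].to_numpy(dtype=float),
    }


def _replicate_estimates(
    arr: dict, idx: np.ndarray, caliper_multiplier: float
) -> dict[str, float] | InvalidReplicate:
    treated = arr["treated"][idx]
    n1 = int(treated.sum())
    if n1 == 0 or n1 == len(idx):
        return InvalidReplicate("single arm")
    X = arr["X"][idx]
    fit = fit_logistic(X, treated.astype(float))
    ps = np.clip(fit.predict_proba(X), SCORE_CLIP, 1 - SCORE_CLIP)
    scores = logit(ps)
    if len(scores) < 2:
        return InvalidReplicate("too few rows")
    width = caliper_multiplier * float(np.std(scores, ddof=1))
    match = match_caliper(
        pd.Series(scores, index=np.arange(len(idx))),
        pd.Series(np.where(treated, ARMS[0], ARMS[1])),
        width,
    )
    if match.n_pairs == 0:
        return InvalidReplicate("zero matched pairs")
    t_rows = np.asarray([p[0] for p in match.pairs], dtype=int)
    c_rows = np.asarray([p[1] for p in match.pairs], dtype=int)

    out: dict[str, float] = {"n_matched": float(match.n_pairs)}
    for key, vals in (("death_pct", arr["death"]), ("recovery_pct", arr["recovery"])):
        v = vals[idx]
        a = 100.0 * float(v[t_rows].mean())
        b = 100.0 * float(v[c_rows].mean())
        out[f"{key}_BLM"], out[f"{key}_BL"], out[f"{key}_diff"] = a, b, a - b
    abx = arr["abx"][idx]
    a, b = float(abx[t_rows].mean()), float(abx[c_rows].mean())
    out["abx_days_BLM"], out["abx_days_BL"], out["abx_days_diff"] = a, b, a - b
    los = arr["los"][idx]
    los_t, los_c = los[t_rows], los[c_rows]
    los_t, los_c = los_t[~np.isnan(los_t)], los_c[~np.isnan(los_c)]
    out["n_inpatient_matched"] = float(min(len(los_t), len(los_c)))
    if len(los_t) and len(los_c):
        a, b = float(los_t.mean()), float(los_c.mean())
        out["los_days_BLM"], out["los_days_BL"], out["los_days_diff"] = a, b, a - b
    else:
        out["los_days_BLM"] = out["los_days_BL"] = out["los_days_diff"] = np.nan
    return out


def bootstrap_replicate(
    dataset: CohortTable,
    rng: np.random.Generator,
    covariates: list[CovariateSpec] | None = None,
    caliper_multiplier: float = 0.05,
) -> dict[str, float] | InvalidReplicate:
    """One bootstrap replicate of one imputed dataset: resample rows with
    replacement, re-fit the PS, re-match, recompute endpoints."""
    if covariates is None:
        covariates = ps_covariates(dataset.spec)
    arr = _prepare_arrays(dataset, covariates)
    idx = rng.integers(dataset.n, size=dataset.n)
    return _replicate_estimates(arr, idx, caliper_multiplier)


def pool_estimates(
    replicates: list[dict[str, float] | InvalidReplicate],
    min_valid_fraction: float = 0.5,
) -> dict[str, PooledDistribution]:
    """Concatenate replicate estimates across datasets into one distribution
    per endpoint, dropping and counting invalid replicates."""
    if not replicates:
        raise ValidationError("no replicates to pool")
    valid = [r for r in replicates if not isinstance(r, InvalidReplicate)]
    invalid = [r for r in replicates if isinstance(r, InvalidReplicate)]
    if not valid:
        raise ValidationError("all bootstrap replicates invalid")
    frac = len(valid) / len(replicates)
    if frac < min_valid_fraction:
        raise ValidationError(
            f"only {frac:.0%} of bootstrap replicates valid "
            f"(minimum {min_valid_fraction:.0%})"
        )
    reasons = Counter(r.reason for r in invalid)
    pooled: dict[str, PooledDistribution] = {}
    for key in ENDPOINT_KEYS:
        vals = np.asarray([r[key] for r in valid if key in r], dtype=float)
        finite = vals[np.isfinite(vals)]
        pooled[key] = PooledDistribution(
            estimates=finite,
            n_invalid=len(replicates) - len(finite),
            reasons=reasons,
        )
    return pooled


def percentile_ci(
    distribution: PooledDistribution | np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """Type-7 (linear interpolation) percentile interval."""
    x = distribution.estimates if isinstance(distribution, PooledDistribution) else np.asarray(distribution, dtype=float)
    if len(x) == 0:
        raise ValidationError("empty distribution")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def point_estimate(distribution: PooledDistribution | np.ndarray) -> float:
    """Pooled median (type-7 interpolation)."""
    x = distribution.estimates if isinstance(distribution, PooledDistribution) else np.asarray(distribution, dtype=float)
    if len(x) == 0:
        raise ValidationError("empty distribution")
    return float(np.quantile(x, 0.5))


def run_mi_boot(
    datasets: list[CohortTable],
    config: BootConfig,
    covariates: list[CovariateSpec] | None = None,
    caliper_multiplier: float = 0.05,
    level: float = 0.95,
) -> MiBootResult:
    """B bootstrap replicates per imputed dataset, pooled per endpoint."""
    if not datasets:
        raise ValidationError("no datasets")
    if covariates is None:
        covariates = ps_covariates(datasets[0].spec)
    streams = np.random.SeedSequence(config.seed).spawn(len(datasets))
    replicates: list[dict[str, float] | InvalidReplicate] = []
    for ds, stream in zip(datasets, streams):
        arr = _prepare_arrays(ds, covariates)
        rng = np.random.default_rng(stream)
        for _ in range(config.B):
            idx = rng.integers(ds.n, size=ds.n)
            replicates.append(_replicate_estimates(arr, idx, caliper_multiplier))
    pooled = pool_estimates(replicates, config.min_valid_fraction)
    summary = {}
    for key, dist in pooled.items():
        if len(dist.estimates) == 0:
            summary[key] = {
                "point": None, "lower": None, "upper": None,
                "n_valid": 0, "n_invalid": dist.n_invalid,
            }
            continue
        lo, hi = percentile_ci(dist, level)
        summary[key] = {
            "point": point_estimate(dist),
            "lower": lo,
            "upper": hi,
            "n_valid": int(len(dist.estimates)),
            "n_invalid": int(dist.n_invalid),
        }
    n_invalid = sum(isinstance(r, InvalidReplicate) for r in replicates)
    return MiBootResult(
        distributions=pooled,
        summary=summary,
        n_replicates=len(replicates),
        n_invalid_replicates=n_invalid,
    )
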