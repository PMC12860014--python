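"""Propensity-score estimation, cross-imputation averaging, greedy caliper
matching, and standardized-mean-difference balance diagnostics.

The matching score is the logit of the propensity averaged on the
probability scale across imputed datasets; the caliper is a multiplier
(default 0.05) times the sample SD of that logit-scale score.  Matching is
greedy 1:1 nearest-neighbor without replacement, treated units processed in
descending score order, ties broken by the smaller control id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit

from ._logistic import LogisticFit, add_intercept, fit_logistic
from .data_model import ARMS, CohortTable, CovariateSpec, ValidationError, ps_covariates

logger = logging.getLogger(__name__)

SCORE_CLIP = 1e-6
SMD_BALANCE_THRESHOLD = 0.1


@dataclass
class PropensityFit:
    coefficients: dict[str, float]
    scores: pd.Series  # indexed by patient id, strictly inside (0, 1)
    fitted_on: str = ""
    used_ridge: bool = False


@dataclass
class MatchResult:
    pairs: list[tuple[str, str]]  # (treated id, control id)
    caliper_width: float
    unmatched_treated: list[str] = field(default_factory=list)
    score_used: pd.Series | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def matched_ids(self) -> list[str]:
        return [i for pair in self.pairs for i in pair]


def design_matrix(
    dataset: CohortTable, covariates: list[CovariateSpec]
) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded design (no intercept column) for the given covariates;
    categorical reference level = first declared level."""
    cols, names = [], []
    for s in covariates:
        if s.kind == "categorical":
            vals = dataset.df[s.name].to_numpy()
            for lv in s.levels[1:]:
                cols.append((vals == lv).astype(float))
                names.append(f"{s.name}[{lv}]")
        else:
            cols.append(dataset.df[s.name].to_numpy(dtype=float))
            names.append(s.name)
    X = np.column_stack(cols) if cols else np.empty((dataset.n, 0))
    if np.isnan(X).any():
        raise ValidationError("propensity design matrix contains missing values")
    return X, names


def fit_propensity(
    dataset: CohortTable,
    covariates: list[CovariateSpec] | None = None,
    label: str = "",
) -> PropensityFit:
    """Maximum-likelihood logistic regression of arm on the PS covariates;
    ridge fallback on separation.  Scores are clipped to
    [1e-6, 1 - 1e-6]."""
    dataset.require_two_arms()
    if covariates is None:
        covariates = ps_covariates(dataset.spec)
    X, names = design_matrix(dataset, covariates)
    y = (dataset.df["arm"].to_numpy() == ARMS[0]).astype(float)
    fit = fit_logistic(add_intercept(X), y)
    if fit.used_ridge:
        logger.debug("propensity fit %s used ridge fallback", label or "<unnamed>")
    raw = fit.predict_proba(add_intercept(X))
    clipped = np.clip(raw, SCORE_CLIP, 1.0 - SCORE_CLIP)
    if (raw != clipped).any():
        logger.debug("propensity scores clipped at %g", SCORE_CLIP)
    scores = pd.Series(clipped, index=dataset.df["id"].to_numpy(), name="ps")
    coefficients = {"intercept": float(fit.coef[0])}
    coefficients.update({nm: float(b) for nm, b in zip(names, fit.coef[1:])})
    return PropensityFit(
        coefficients=coefficients, scores=scores, fitted_on=label, used_ridge=fit.used_ridge
    )


def average_and_logit(fits: list[PropensityFit]) -> pd.Series:
    """Average propensities across imputed datasets on the probability scale,
    then logit-transform; this is the matching score."""
    if not fits:
        raise ValidationError("no propensity fits to average")
    index = fits[0].scores.index
    for f in fits[1:]:
        if len(f.scores.index) != len(index) or not (f.scores.index == index).all():
            raise ValidationError("propensity fits cover different patient sets")
    mean_ps = np.mean([f.scores.to_numpy() for f in fits], axis=0)
    return pd.Series(logit(mean_ps), index=index, name="logit_ps")


def compute_caliper(scores: pd.Series | np.ndarray, multiplier: float = 0.05) -> float:
    """Caliper width = multiplier x sample SD (n-1) of the matching scores."""
    arr = np.asarray(scores, dtype=float)
    if len(arr) < 2:
        raise ValidationError("need >=2 patients to compute a caliper")
    sd = float(np.std(arr, ddof=1))
    if sd == 0.0:
        logger.warning("matching scores have zero variance; caliper width 0")
    return multiplier * sd


def match_caliper(
    scores: pd.Series, arms: pd.Series, caliper_width: float
) -> MatchResult:
    """Greedy 1:1 nearest-neighbor caliper matching without replacement.

    Treated units are processed in descending score order (ties by id); each
    takes the available control minimizing |score difference|, skipped when
    that minimum exceeds the caliper.  Control-side ties go to the smaller
    control id.
    """
    if caliper_width < 0:
        raise ValidationError("caliper width must be >= 0")
    ids = np.asarray(scores.index)
    s = scores.to_numpy(dtype=float)
    a = np.asarray(arms)
    treated_idx = np.flatnonzero(a == ARMS[0])
    control_idx = np.flatnonzero(a == ARMS[1])

    # treated processing order: descending score, ties by ascending id
    t_order = treated_idx[np.lexsort((ids[treated_idx], -s[treated_idx]))]
    # controls sorted ascending by (score, id) for bisection
    c_order = control_idx[np.lexsort((ids[control_idx], s[control_idx]))]
    c_scores = s[c_order]
    c_ids = ids[c_order]
    available = np.ones(len(c_order), dtype=bool)

    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []
    for ti in t_order:
        target = s[ti]
        pos = np.searchsorted(c_scores, target)
        left = pos - 1
        while left >= 0 and not available[left]:
            left -= 1
        right = pos
        while right < len(c_order) and not available[right]:
            right += 1
        d_left = target - c_scores[left] if left >= 0 else np.inf
        d_right = c_scores[right] - target if right < len(c_order) else np.inf
        best = min(d_left, d_right)
        if not np.isfinite(best) or best > caliper_width:
            unmatched.append(ids[ti])
            continue
        # collect every available control at exactly the winning distance and
        # take the smallest id (equal-score runs sit adjacent in c_order)
        candidates = []
        if d_left == best:
            j = left
            while j >= 0 and target - c_scores[j] == best:
                if available[j]:
                    candidates.append(j)
                j -= 1
        if d_right == best:
            j = right
            while j < len(c_order) and c_scores[j] - target == best:
                if available[j]:
                    candidates.append(j)
                j += 1
        chosen = min(candidates, key=lambda j: c_ids[j])
        available[chosen] = False
        pairs.append((ids[ti], c_ids[chosen]))

    return MatchResult(
        pairs=pairs,
        caliper_width=caliper_width,
        unmatched_treated=unmatched,
        score_used=scores,
    )


def compute_smd(
    group1: np.ndarray, group0: np.ndarray, kind: str, levels: tuple[str, ...] = ()
) -> float:
    """Standardized mean difference between two groups.

    continuous: |m1-m0| / sqrt((s1^2+s0^2)/2); binary: same with Bernoulli
    variances; categorical: Mahalanobis form sqrt(T' S^-1 T) over the K-1
    non-reference level proportions, S the average multinomial covariance.
    """
    g1 = np.asarray(group1)
    g0 = np.asarray(group0)
    if len(g1) == 0 or len(g0) == 0:
        raise ValidationError("compute_smd requires both groups non-empty")
    if kind == "continuous":
        m1, m0 = g1.mean(), g0.mean()
        v1 = g1.var(ddof=1) if len(g1) > 1 else 0.0
        v0 = g0.var(ddof=1) if len(g0) > 1 else 0.0
        pooled = (v1 + v0) / 2
        if pooled == 0.0:
            return 0.0 if m1 == m0 else np.inf
        return float(abs(m1 - m0) / np.sqrt(pooled))
    if kind == "binary":
        p1, p0 = float(np.mean(g1)), float(np.mean(g0))
        pooled = (p1 * (1 - p1) + p0 * (1 - p0)) / 2
        if pooled == 0.0:
            return 0.0 if p1 == p0 else np.inf
        return float(abs(p1 - p0) / np.sqrt(pooled))
    if kind == "categorical":
        if len(levels) < 2:
            raise ValidationError("categorical SMD needs the level list")
        p1 = np.array([(g1 == lv).mean() for lv in levels[1:]])
        p0 = np.array([(g0 == lv).mean() for lv in levels[1:]])
        T = p1 - p0
        if np.allclose(T, 0.0):
            return 0.0
        S = (_multinomial_cov(p1) + _multinomial_cov(p0)) / 2
        try:
            sol = np.linalg.solve(S, T)
        except np.linalg.LinAlgError:
            sol = np.linalg.pinv(S) @ T
        val = float(T @ sol)
        return float(np.sqrt(val)) if val >= 0 else np.inf
    raise ValidationError(f"unknown covariate kind {kind!r}")


def _multinomial_cov(p: np.ndarray) -> np.ndarray:
    return np.diag(p) - np.outer(p, p)


def balance_table(
    dataset: CohortTable,
    match: MatchResult,
    covariates: list[CovariateSpec] | None = None,
) -> pd.DataFrame:
    """SMD per PS covariate before matching (full cohort) and after matching
    (matched pairs only), with the |SMD| < 0.1 balance flag."""
    if covariates is None:
        covariates = ps_covariates(dataset.spec)
    df = dataset.df
    arm1 = df["arm"] == ARMS[0]
    matched_ids = set(match.matched_ids())
    in_match = df["id"].isin(matched_ids)

    rows = []
    for s in covariates:
        vals = df[s.name].to_numpy()
        before = compute_smd(vals[arm1], vals[~arm1], s.kind, s.levels)
        if match.n_pairs == 0:
            after = np.nan
        else:
            after = compute_smd(
                vals[(arm1 & in_match).to_numpy()],
                vals[(~arm1 & in_match).to_numpy()],
                s.kind,
                s.levels,
            )
        rows.append(
            dict(
                variable=s.name,
                smd_before=before,
                smd_after=after,
                balanced_before=bool(abs(before) < SMD_BALANCE_THRESHOLD),
                balanced_after=(
                    bool(abs(after) < SMD_BALANCE_THRESHOLD)
                    if np.isfinite(after)
                    else False
                ),
            )
        )
    return pd.DataFrame(rows)
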