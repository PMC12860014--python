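"""Synthetic two-arm cohort generator.

Produces cohorts with the structure the downstream analysis assumes:
correlated covariates (Gaussian copula), confounded treatment assignment
(logistic on the covariates), cause-specific exponential hazards for the two
terminal events (recovery, death) with a configurable true treatment effect,
routing of event-free patients to the non-terminal outcomes, and MAR
missingness driven by always-observed variables.

A truth side-table (latent propensity, latent cause and time, pre-masking
covariate values) is returned alongside the analysis-facing cohort so tests
can check parameter recovery; it is never written into the cohort CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .data_model import ARMS, CohortTable, CovariateSpec, default_schema

# Marginal distributions for the copula-driven covariates.  Continuous:
# (mean, sd, lower clip, upper clip); binary: prevalence; categorical:
# level probabilities.
DEFAULT_MARGINALS: dict[str, Any] = {
    "age": {"mean": 74.0, "sd": 17.0, "lo": 18.0, "hi": 102.0},
    "female_sex": {"p": 0.39},
    "hospital": {"probs": [0.176, 0.133, 0.122, 0.569]},
    "outpatient": {"p": 0.21},
    "prior_hospitalization": {"p": 0.19},
    "nursing_home": {"p": 0.165},
    "dialysis": {"p": 0.017},
    "diabetes": {"p": 0.206},
    "heart_failure": {"p": 0.155},
    "liver_disease": {"p": 0.057},
    "renal_disease": {"p": 0.111},
    "dementia": {"p": 0.156},
    "malignancy": {"p": 0.196},
    "asthma": {"p": 0.102},
    "copd_bronchiectasis": {"p": 0.234},
    "oral_steroids": {"p": 0.086},
    "antacids": {"p": 0.30},
    "sleeping_drugs": {"p": 0.124},
    "aspiration_episodes": {"p": 0.268},
    "preexisting_impaired_consciousness": {"p": 0.06},
    "neuromuscular_disease": {"p": 0.074},
    "device_insertion": {"p": 0.024},
    "cerebrovascular_disease": {"p": 0.227},
    "bedridden": {"p": 0.128},
    "impaired_consciousness": {"p": 0.19},
    "heart_rate": {"mean": 96.2, "sd": 20.1, "lo": 30.0, "hi": 220.0},
    "respiratory_rate": {"mean": 22.4, "sd": 6.0, "lo": 8.0, "hi": 60.0},
    "systolic_bp": {"mean": 129.8, "sd": 25.5, "lo": 50.0, "hi": 260.0},
    "body_temperature": {"mean": 37.45, "sd": 1.1, "lo": 33.0, "hi": 42.5},
    "hematocrit": {"mean": 36.7, "sd": 5.8, "lo": 12.0, "hi": 60.0},
    "bun": {"mean": 21.8, "sd": 15.2, "lo": 1.0, "hi": 150.0},
    "sodium": {"mean": 137.6, "sd": 4.5, "lo": 110.0, "hi": 165.0},
    "glucose": {"mean": 139.2, "sd": 59.1, "lo": 35.0, "hi": 600.0},
    "albumin": {"mean": 3.42, "sd": 0.56, "lo": 0.8, "hi": 5.8},
    "pleural_effusion": {"p": 0.071},
    # microbiology flags — independent of the copula block
    "blood_culture_positive": {"p": 0.03},
    "pleural_culture_positive": {"p": 0.01},
    "sputum_quality": {"p": 0.40},
    "sputum_cfu": {"log10_mean": 5.5, "log10_sd": 1.5},
    "sputum_semiquant": {"probs": [0.35, 0.2, 0.15, 0.2, 0.1]},  # scores 0..4
    "urinary_antigen_positive": {"p": 0.09},
}

MICRO_COLUMNS = (
    "blood_culture_positive",
    "pleural_culture_positive",
    "sputum_quality",
    "sputum_cfu",
    "sputum_semiquant",
    "urinary_antigen_positive",
)

# Treatment-assignment log-odds on standardized covariates: younger
# outpatients without aspiration-associated factors preferentially receive
# the dual-therapy arm — the confounding the matcher must remove.
DEFAULT_TREAT_COEFS: dict[str, float] = {
    "age": -1.0,
    "outpatient": 0.9,
    "aspiration_episodes": -0.6,
    "cerebrovascular_disease": -0.6,
    "dementia": -0.8,
    "nursing_home": -0.8,
    "heart_failure": -0.4,
    "prior_hospitalization": -0.5,
}

DEFAULT_OUTCOME_COEFS: dict[str, dict[str, float]] = {
    "death": {
        "base_hazard": 0.0042,
        "age": 0.9,
        "impaired_consciousness": 0.7,
        "bun": 0.35,
        "albumin": -0.35,
        "aspiration_episodes": 0.4,
        "heart_failure": 0.3,
    },
    "recovery": {
        "base_hazard": 0.085,
        "age": -0.25,
        "albumin": 0.15,
        "copd_bronchiectasis": -0.10,
    },
}

# MAR missingness: linear predictors on always-observed variables only.
DEFAULT_MISS_PROBS: dict[str, dict[str, Any]] = {
    "bun": {"intercept": -2.0, "coefs": {"outpatient": 0.7, "age": -0.2}},
    "albumin": {"intercept": -2.0, "coefs": {"outpatient": 0.7}},
    "glucose": {"intercept": -2.4, "coefs": {"outpatient": 0.4}},
    "hematocrit": {"intercept": -2.4, "coefs": {}},
    "sodium": {"intercept": -2.4, "coefs": {}},
    "body_temperature": {"intercept": -2.9, "coefs": {"age": 0.2}},
    "respiratory_rate": {"intercept": -1.9, "coefs": {"outpatient": 0.6}},
}

DEFAULT_OUTCOME_MIX = {"stable": 0.5, "deterioration": 0.2, "transfer": 0.3}


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n: int = 2784
    seed: int = 0
    copula_rho: float = 0.15
    marginals: dict[str, Any] = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    treat_coefs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TREAT_COEFS))
    treat_intercept: float | None = None  # None => calibrate to the target fraction
    target_treated_fraction: float = 0.11  # ~306/2784
    outcome_coefs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_OUTCOME_COEFS.items()}
    )
    true_effect: float = 0.0  # log hazard ratio of treatment on death
    secondary_effect: float = 0.0  # log hazard ratio of treatment on recovery
    miss_probs: dict[str, dict[str, Any]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MISS_PROBS.items()}
    )
    outcome_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OUTCOME_MIX))
    max_followup_days: float = 45.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise SimulationError("n must be >= 0")
        if not 0.0 < self.target_treated_fraction < 1.0:
            raise SimulationError("target_treated_fraction must be in (0,1)")
        mix_total = sum(self.outcome_mix.values())
        if self.outcome_mix and not np.isclose(mix_total, 1.0):
            raise SimulationError("outcome_mix probabilities must sum to 1")
        for key in self.outcome_mix:
            if key not in ("stable", "deterioration", "transfer"):
                raise SimulationError(f"outcome_mix: unknown outcome {key!r}")
        for cause, coefs in self.outcome_coefs.items():
            if coefs.get("base_hazard", 0.0) < 0:
                raise SimulationError(f"negative base hazard for {cause!r}")
        for var, model in self.miss_probs.items():
            for pred in model.get("coefs", {}):
                if pred in self.miss_probs:
                    raise SimulationError(
                        f"MAR model for {var!r} references maskable variable {pred!r}"
                    )

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _zscore(values: np.ndarray, marginal: dict[str, Any]) -> np.ndarray:
    if "mean" in marginal:
        return (values - marginal["mean"]) / marginal["sd"]
    return values  # binaries enter on their natural 0/1 scale


def _linear_predictor(
    cov: pd.DataFrame, coefs: dict[str, float], marginals: dict[str, Any]
) -> np.ndarray:
    lp = np.zeros(len(cov))
    for name, beta in coefs.items():
        if name == "base_hazard":
            continue
        if name not in cov.columns:
            raise SimulationError(f"coefficient for unknown covariate {name!r}")
        lp += beta * _zscore(cov[name].to_numpy(dtype=float), marginals.get(name, {}))
    return lp


def generate_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw a complete covariate matrix.

    The core covariates share a Gaussian copula with exchangeable correlation
    ``copula_rho``; binaries arise by thresholding, continuous covariates by a
    clipped normal quantile transform, the site variable by partitioning the
    uniform.  Microbiology columns are drawn independently.
    """
    schema = default_schema()
    core = [s for s in schema if s.name not in MICRO_COLUMNS]
    k = len(core)
    n = config.n
    corr = np.full((k, k), config.copula_rho)
    np.fill_diagonal(corr, 1.0)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise SimulationError("copula correlation matrix not positive definite") from exc
    z = rng.standard_normal(size=(n, k)) @ chol.T
    u = norm.cdf(z)

    cols: dict[str, np.ndarray] = {}
    for j, s in enumerate(core):
        marg = config.marginals.get(s.name)
        if marg is None:
            raise SimulationError(f"no marginal defined for covariate {s.name!r}")
        if s.kind == "binary":
            cols[s.name] = (u[:, j] < marg["p"]).astype(float)
        elif s.kind == "continuous":
            vals = marg["mean"] + marg["sd"] * norm.ppf(u[:, j])
            cols[s.name] = np.clip(vals, marg.get("lo", -np.inf), marg.get("hi", np.inf))
        else:  # categorical: partition the uniform by cumulative level probs
            probs = np.asarray(marg["probs"], dtype=float)
            if len(probs) != len(s.levels) or not np.isclose(probs.sum(), 1.0):
                raise SimulationError(f"bad level probabilities for {s.name!r}")
            idx = np.searchsorted(np.cumsum(probs), u[:, j], side="right")
            idx = np.clip(idx, 0, len(s.levels) - 1)
            cols[s.name] = np.asarray(s.levels, dtype=object)[idx]

    for name in MICRO_COLUMNS:
        marg = config.marginals[name]
        if name == "sputum_cfu":
            cols[name] = 10.0 ** rng.normal(marg["log10_mean"], marg["log10_sd"], size=n)
        elif name == "sputum_semiquant":
            probs = np.asarray(marg["probs"], dtype=float)
            cols[name] = rng.choice(len(probs), size=n, p=probs / probs.sum()).astype(float)
        else:
            cols[name] = (rng.random(n) < marg["p"]).astype(float)

    df = pd.DataFrame(cols)
    return df.reindex(columns=[s.name for s in schema])


def assign_treatment(
    covariates: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Return (arm labels, latent propensity).

    When no intercept is given it is calibrated so the mean latent propensity
    equals ``target_treated_fraction`` on this cohort.
    """
    lp = _linear_predictor(covariates, config.treat_coefs, config.marginals)
    if config.treat_intercept is not None:
        intercept = float(config.treat_intercept)
    elif len(lp) == 0:
        intercept = logit(config.target_treated_fraction)
    else:
        target = config.target_treated_fraction

        def gap(b: float) -> float:
            return float(expit(b + lp).mean() - target)

        intercept = brentq(gap, -30.0, 30.0)
    ps = expit(intercept + lp)
    treated = rng.random(len(ps)) < ps
    arms = np.where(treated, ARMS[0], ARMS[1])
    return arms, ps


def simulate_outcomes(
    covariates: pd.DataFrame,
    arms: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Competing exponential hazards for recovery and death.

    The death hazard is multiplied by exp(true_effect) and the recovery
    hazard by exp(secondary_effect) for treated patients.  The earlier latent
    event wins; patients event-free at the follow-up horizon are routed to
    the non-terminal outcomes by ``outcome_mix``.
    """
    n = len(covariates)
    treated = np.asarray(arms) == ARMS[0]
    hazards = {}
    for cause in ("recovery", "death"):
        coefs = config.outcome_coefs[cause]
        base = coefs.get("base_hazard", 0.0)
        if base < 0:
            raise SimulationError(f"negative base hazard for {cause!r}")
        h = base * np.exp(_linear_predictor(covariates, coefs, config.marginals))
        if cause == "death":
            h = h * np.exp(np.where(treated, config.true_effect, 0.0))
        else:
            h = h * np.exp(np.where(treated, config.secondary_effect, 0.0))
        hazards[cause] = h
    h_total = hazards["recovery"] + hazards["death"]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_event = np.where(h_total > 0, rng.exponential(1.0, size=n) / np.where(h_total > 0, h_total, 1.0), np.inf)
    p_death = np.where(h_total > 0, hazards["death"] / np.where(h_total > 0, h_total, 1.0), 0.0)
    is_death = rng.random(n) < p_death

    horizon = config.max_followup_days
    event = t_event <= horizon
    outcome = np.empty(n, dtype=object)
    outcome[event & is_death] = "death"
    outcome[event & ~is_death] = "recovery"
    mix_levels = list(config.outcome_mix) or ["stable"]
    mix_probs = np.asarray([config.outcome_mix.get(lv, 1.0) for lv in mix_levels], dtype=float)
    mix_probs = mix_probs / mix_probs.sum()
    n_nonevent = int((~event).sum())
    if n_nonevent:
        outcome[~event] = rng.choice(mix_levels, size=n_nonevent, p=mix_probs)

    obs_days = np.where(event, t_event, horizon)
    outpatient = covariates["outpatient"].to_numpy(dtype=float) == 1.0
    los_days = np.where(outpatient, np.nan, obs_days)
    abx_days = np.where(event, np.clip(t_event, 2.0, 21.0), rng.uniform(5.0, 15.0, size=n))

    return pd.DataFrame(
        {
            "outcome": outcome,
            "obs_days": obs_days,
            "los_days": los_days,
            "abx_days": abx_days,
            "latent_cause": np.where(is_death, "death", "recovery"),
            "latent_time": t_event,
        }
    )


def apply_missingness(
    cohort: CohortTable, config: SimulationConfig, rng: np.random.Generator
) -> CohortTable:
    """Mask covariate cells MAR: P(missing) = expit(model on always-observed
    variables).  Arm, outcome and times are never masked."""
    if cohort.missing_mask().to_numpy().any():
        raise SimulationError("apply_missingness expects a complete cohort")
    out = cohort.copy()
    for var, model in config.miss_probs.items():
        if var not in out.covariate_names:
            raise SimulationError(f"MAR model for unknown covariate {var!r}")
        lp = np.full(out.n, float(model.get("intercept", 0.0)))
        for pred, beta in model.get("coefs", {}).items():
            lp += beta * _zscore(
                out.df[pred].to_numpy(dtype=float), config.marginals.get(pred, {})
            )
        mask = rng.random(out.n) < expit(lp)
        out.df.loc[mask, var] = np.nan
    out.validate()
    return out


def generate_cohort(config: SimulationConfig) -> tuple[CohortTable, pd.DataFrame]:
    """Full generator: covariates -> treatment -> outcomes -> MAR masking.

    Returns the analysis-facing cohort and a truth side-table with the latent
    propensity, latent cause/time and the pre-masking covariate values.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    schema = default_schema()
    cov = generate_covariates(config, rng)
    arms, ps = assign_treatment(cov, config, rng)
    out = simulate_outcomes(cov, arms, config, rng)

    ids = [f"P{i:06d}" for i in range(config.n)]
    df = pd.DataFrame({"id": ids, "arm": arms})
    df = pd.concat([df, cov.reset_index(drop=True)], axis=1)
    df["outcome"] = out["outcome"].to_numpy()
    df["obs_days"] = out["obs_days"].to_numpy()
    df["los_days"] = out["los_days"].to_numpy()
    df["abx_days"] = out["abx_days"].to_numpy()
    complete = CohortTable(spec=schema, df=df)

    truth = pd.DataFrame({"id": ids, "latent_ps": ps})
    truth["latent_cause"] = out["latent_cause"].to_numpy()
    truth["latent_time"] = out["latent_time"].to_numpy()
    for name in complete.covariate_names:
        truth[f"true_{name}"] = complete.df[name].to_numpy()

    cohort = apply_missingness(complete, config, rng)
    return cohort, truth
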