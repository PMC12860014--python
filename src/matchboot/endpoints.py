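"""Endpoint estimation on matched cohorts.

Primary endpoints are the per-arm frequencies of death and recovery at the
end of observation with their between-arm absolute differences; secondary
endpoints are mean antibiotic duration and, for inpatients only, mean length
of stay.  Also here: the competing-risks cumulative incidence estimator, the
CURB-65 severity score, and the subgroup / sensitivity filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ARMS, CohortTable, ValidationError
from .propensity_match import MatchResult

TERMINAL_CAUSES = ("death", "recovery")


@dataclass
class EndpointPanel:
    """Per-arm endpoint estimates over matched patients; differences are
    arm BLM minus arm BL."""

    per_arm: dict[str, dict[str, float | None]]
    differences: dict[str, float | None]

    def as_dict(self) -> dict:
        return {"per_arm": self.per_arm, "differences": self.differences}


def endpoint_panel(cohort: CohortTable, match: MatchResult) -> EndpointPanel:
    """Compute the endpoint panel on the matched subset of ``cohort``."""
    if match.n_pairs == 0:
        raise ValidationError("endpoint_panel requires a non-empty match")
    sub = cohort.df[cohort.df["id"].isin(set(match.matched_ids()))]
    per_arm: dict[str, dict[str, float | None]] = {}
    for arm in ARMS:
        g = sub[sub["arm"] == arm]
        n = len(g)
        inpat = g[g["los_days"].notna()]
        per_arm[arm] = {
            "n": float(n),
            "death_pct": 100.0 * float((g["outcome"] == "death").mean()),
            "recovery_pct": 100.0 * float((g["outcome"] == "recovery").mean()),
            "abx_days": float(g["abx_days"].mean()),
            "los_days": float(inpat["los_days"].mean()) if len(inpat) else None,
            "n_inpatient": float(len(inpat)),
        }
    diffs: dict[str, float | None] = {}
    for key in ("death_pct", "recovery_pct", "abx_days", "los_days"):
        a, b = per_arm[ARMS[0]][key], per_arm[ARMS[1]][key]
        diffs[key] = None if a is None or b is None else a - b
    return EndpointPanel(per_arm=per_arm, differences=diffs)


# -- CURB-65 --------------------------------------------------------------

BUN_THRESHOLD_MG_DL = 19.6  # urea > 7 mmol/L expressed as BUN in mg/dL


def curb65(
    impaired_consciousness: bool,
    bun: float,
    respiratory_rate: float,
    systolic_bp: float,
    age: float,
) -> int:
    """Severity score 0-5: one point each for impaired consciousness,
    BUN > 19.6 mg/dL, respiratory rate >= 30/min, systolic BP < 90 mmHg,
    and age >= 65 years.  (Diastolic BP is not collected in this schema, so
    the blood-pressure criterion uses systolic pressure alone.)"""
    score = int(bool(impaired_consciousness))
    score += int(bun > BUN_THRESHOLD_MG_DL)
    score += int(respiratory_rate >= 30)
    score += int(systolic_bp < 90)
    score += int(age >= 65)
    return score


def curb65_scores(cohort: CohortTable) -> pd.Series:
    """Vectorized CURB-65 over a complete cohort."""
    df = cohort.df
    needed = ["impaired_consciousness", "bun", "respiratory_rate", "systolic_bp", "age"]
    if df[needed].isna().to_numpy().any():
        raise ValidationError("CURB-65 requires complete component values")
    score = (
        (df["impaired_consciousness"] == 1.0).astype(int)
        + (df["bun"] > BUN_THRESHOLD_MG_DL).astype(int)
        + (df["respiratory_rate"] >= 30).astype(int)
        + (df["systolic_bp"] < 90).astype(int)
        + (df["age"] >= 65).astype(int)
    )
    return pd.Series(score.to_numpy(), index=df["id"].to_numpy(), name="curb65")


# -- subgroup / sensitivity filters --------------------------------------


def filter_severe(cohort: CohortTable, threshold: int = 3) -> CohortTable:
    """Rows with CURB-65 >= threshold (may be empty)."""
    scores = curb65_scores(cohort)
    mask = (scores >= threshold).to_numpy()
    return cohort.subset(mask)


MICRO_REQUIRED = (
    "blood_culture_positive",
    "pleural_culture_positive",
    "sputum_quality",
    "sputum_cfu",
    "sputum_semiquant",
    "urinary_antigen_positive",
)


def filter_micro_confirmed(cohort: CohortTable) -> CohortTable:
    """Microbiologically confirmed subgroup: positive blood culture, OR
    positive pleural-fluid culture, OR a high-quality sputum sample with
    growth >= 1e6 CFU/mL or semiquantitative score >= 3, OR a positive
    pneumococcal urinary antigen test."""
    missing = [c for c in MICRO_REQUIRED if c not in cohort.covariate_names]
    if missing:
        raise ValidationError(f"missing microbiology column(s): {missing}")
    df = cohort.df
    sputum_ok = (df["sputum_quality"] == 1.0) & (
        (df["sputum_cfu"] >= 1e6) | (df["sputum_semiquant"] >= 3)
    )
    mask = (
        (df["blood_culture_positive"] == 1.0)
        | (df["pleural_culture_positive"] == 1.0)
        | sputum_ok
        | (df["urinary_antigen_positive"] == 1.0)
    )
    return cohort.subset(mask.to_numpy())


def filter_complete_case(cohort: CohortTable) -> CohortTable:
    """Rows with zero missing covariate cells."""
    mask = ~cohort.missing_mask().any(axis=1)
    return cohort.subset(mask.to_numpy())


# -- competing-risks cumulative incidence --------------------------------


@dataclass
class CIFCurve:
    """Aalen-Johansen cumulative incidence for the terminal causes.

    ``grid`` is a tidy frame (time, n_at_risk, km_survival, plus one
    cif_<cause> column per cause) with one row per distinct event time.
    """

    grid: pd.DataFrame
    causes: tuple[str, ...] = TERMINAL_CAUSES

    def cif(self, cause: str, t: float) -> float:
        col = f"cif_{cause}"
        rows = self.grid[self.grid["time"] <= t]
        return float(rows[col].iloc[-1]) if len(rows) else 0.0

    def final(self, cause: str) -> float:
        col = f"cif_{cause}"
        return float(self.grid[col].iloc[-1]) if len(self.grid) else 0.0


def aalen_johansen(
    times: np.ndarray, causes: np.ndarray, causes_of_interest: tuple[str, ...] = TERMINAL_CAUSES
) -> CIFCurve:
    """Aalen-Johansen estimator.

    ``causes`` holds one of the terminal cause labels or "censored" per
    patient.  CIF_k(t) = sum over event times t_i <= t of S(t_i-) d_ki / n_i,
    with S the all-cause Kaplan-Meier survival of the event-free state.
    """
    times = np.asarray(times, dtype=float)
    causes = np.asarray(causes, dtype=object)
    if (times < 0).any():
        raise ValidationError("negative event time")
    unknown = set(np.unique(causes)) - set(causes_of_interest) - {"censored"}
    if unknown:
        raise ValidationError(f"unknown cause label(s): {sorted(unknown)}")

    order = np.argsort(times, kind="stable")
    times, causes = times[order], causes[order]
    event_times = np.unique(times[causes != "censored"])

    n = len(times)
    rows = []
    surv = 1.0
    cif = {c: 0.0 for c in causes_of_interest}
    for t in event_times:
        n_at_risk = int((times >= t).sum())
        d_total = 0
        d_by_cause = {}
        for c in causes_of_interest:
            d = int(((times == t) & (causes == c)).sum())
            d_by_cause[c] = d
            d_total += d
        for c in causes_of_interest:
            cif[c] += surv * d_by_cause[c] / n_at_risk
        surv *= 1.0 - d_total / n_at_risk
        row = {"time": float(t), "n_at_risk": n_at_risk, "km_survival": surv}
        row.update({f"cif_{c}": cif[c] for c in causes_of_interest})
        rows.append(row)
    grid = pd.DataFrame(
        rows,
        columns=["time", "n_at_risk", "km_survival"]
        + [f"cif_{c}" for c in causes_of_interest],
    )
    return CIFCurve(grid=grid, causes=tuple(causes_of_interest))


def cif_from_cohort(
    cohort: CohortTable, ids: list[str] | None = None
) -> dict[str, CIFCurve]:
    """Per-arm CIF curves; non-terminal outcomes censor at obs_days."""
    df = cohort.df
    if ids is not None:
        df = df[df["id"].isin(set(ids))]
    curves = {}
    for arm in ARMS:
        g = df[df["arm"] == arm]
        cause = np.where(
            g["outcome"].isin(TERMINAL_CAUSES), g["outcome"], "censored"
        ).astype(object)
        curves[arm] = aalen_johansen(g["obs_days"].to_numpy(), cause)
    return curves


def cif_tidy(curves: dict[str, CIFCurve]) -> pd.DataFrame:
    """Long-format (arm, time, cause, estimate) table for plotting/export."""
    frames = []
    for arm, curve in curves.items():
        for c in curve.causes:
            frames.append(
                pd.DataFrame(
                    {
                        "arm": arm,
                        "time": curve.grid["time"],
                        "cause": c,
                        "estimate": curve.grid[f"cif_{c}"],
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["arm", "time", "cause", "estimate"])
    return pd.concat(frames, ignore_index=True)
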