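"""Cohort schema, validation, and CSV input/output.

A cohort is a patient-level table with a treatment arm, a set of typed
covariates (binary / continuous / categorical, missing values allowed), a
five-category terminal outcome, and three duration columns.  The schema is a
list of :class:`CovariateSpec`; the default registry of covariates ships with
the package as ``registry.yaml``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

ARMS = ("BLM", "BL")
OUTCOMES = ("recovery", "stable", "deterioration", "death", "transfer")

ID_COL = "id"
ARM_COL = "arm"
OUTCOME_COL = "outcome"
TIME_COLS = ("obs_days", "los_days", "abx_days")

KINDS = ("binary", "continuous", "categorical")


class ValidationError(ValueError):
    """A cohort table or CSV file violates the schema."""


def _to_float(col: pd.Series) -> pd.Series:
    """Exact elementwise float coercion (Python float round-trips repr);
    non-coercible entries become NaN while remaining non-null in ``col``."""
    if col.dtype != object:
        return col.astype(float)

    def conv(v):
        if pd.isna(v):
            return np.nan
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    return col.map(conv)


@dataclass(frozen=True)
class CovariateSpec:
    """Declaration of a single covariate column."""

    name: str
    kind: str
    unit: str = ""
    levels: tuple[str, ...] = ()
    in_propensity_model: bool = True

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"covariate {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if len(self.levels) < 2:
                raise ValidationError(
                    f"categorical covariate {self.name!r} needs >=2 levels"
                )
            if len(set(self.levels)) != len(self.levels):
                raise ValidationError(f"covariate {self.name!r}: duplicate levels")
        elif self.levels:
            raise ValidationError(
                f"covariate {self.name!r}: levels only allowed for categoricals"
            )
        object.__setattr__(self, "levels", tuple(self.levels))


def load_registry(path: str | None = None) -> list[CovariateSpec]:
    """Load a covariate registry; the packaged default when ``path`` is None."""
    if path is None:
        text = (
            importlib.resources.files("matchboot").joinpath("registry.yaml").read_text()
        )
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    specs = [
        CovariateSpec(
            name=entry["name"],
            kind=entry["kind"],
            unit=str(entry.get("unit", "")),
            levels=tuple(entry.get("levels", ())),
            in_propensity_model=bool(entry.get("in_propensity_model", True)),
        )
        for entry in raw["covariates"]
    ]
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError("registry has duplicate covariate names")
    return specs


def default_schema() -> list[CovariateSpec]:
    return load_registry(None)


def ps_covariates(spec: list[CovariateSpec]) -> list[CovariateSpec]:
    """The covariates flagged for propensity-score estimation."""
    return [s for s in spec if s.in_propensity_model]


def canonical_columns(spec: list[CovariateSpec]) -> list[str]:
    return [ID_COL, ARM_COL, *(s.name for s in spec), OUTCOME_COL, *TIME_COLS]


@dataclass
class CohortTable:
    """A validated patient-level cohort.

    ``df`` holds one row per patient in the canonical column order.  Binary
    covariates are floats in {0, 1, NaN}; continuous covariates are floats
    (NaN = missing); categorical covariates are objects drawn from their
    declared levels (NaN = missing).
    """

    spec: list[CovariateSpec] = field(default_factory=default_schema)
    df: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.df.empty and len(self.df.columns) == 0:
            self.df = pd.DataFrame(columns=canonical_columns(self.spec))
        self.df = self.df.reindex(columns=canonical_columns(self.spec))
        self.df = self.df.reset_index(drop=True)
        self.validate()

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        names = [s.name for s in self.spec]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate covariate names in schema")
        df = self.df
        if df[ID_COL].isna().any():
            raise ValidationError("missing patient id")
        if df[ID_COL].duplicated().any():
            dup = df.loc[df[ID_COL].duplicated(), ID_COL].iloc[0]
            raise ValidationError(f"duplicate patient id {dup!r}")
        bad_arm = ~df[ARM_COL].isin(ARMS)
        if bad_arm.any():
            raise ValidationError(
                f"row {df.index[bad_arm][0]}: invalid arm "
                f"{df.loc[bad_arm, ARM_COL].iloc[0]!r} (allowed: {ARMS})"
            )
        bad_out = ~df[OUTCOME_COL].isin(OUTCOMES)
        if bad_out.any():
            raise ValidationError(
                f"row {df.index[bad_out][0]}: invalid outcome "
                f"{df.loc[bad_out, OUTCOME_COL].iloc[0]!r} (allowed: {OUTCOMES})"
            )
        for col in ("obs_days", "abx_days"):
            vals = _to_float(df[col])
            if len(df) and vals.isna().any():
                raise ValidationError(f"column {col}: missing or non-numeric value")
            if len(df) and (vals < 0).any():
                raise ValidationError(f"column {col}: negative duration")
            self.df[col] = vals.astype(float)
        los = _to_float(df["los_days"])
        if len(df) and (los.dropna() < 0).any():
            raise ValidationError("column los_days: negative duration")
        self.df["los_days"] = los.astype(float)
        for s in self.spec:
            self._validate_covariate(s)
        if "outpatient" in names:
            outp = self.df["outpatient"]
            clash = (outp == 1) & self.df["los_days"].notna()
            if clash.any():
                raise ValidationError(
                    f"row {df.index[clash][0]}: los_days present for an outpatient"
                )

    def _validate_covariate(self, s: CovariateSpec) -> None:
        col = self.df[s.name]
        if s.kind == "categorical":
            observed = col[col.notna()]
            bad = ~observed.isin(s.levels)
            if bad.any():
                raise ValidationError(
                    f"column {s.name}: value {observed[bad].iloc[0]!r} "
                    f"not in levels {s.levels}"
                )
            return
        vals = _to_float(col)
        newly_bad = vals.isna() & col.notna()
        if newly_bad.any():
            raise ValidationError(
                f"column {s.name}: non-numeric value "
                f"{col[newly_bad].iloc[0]!r}"
            )
        if s.kind == "binary":
            observed = vals.dropna()
            if len(observed) and not observed.isin([0.0, 1.0]).all():
                bad = observed[~observed.isin([0.0, 1.0])].iloc[0]
                raise ValidationError(f"column {s.name}: non-binary value {bad!r}")
        self.df[s.name] = vals.astype(float)

    # -- convenience ----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def covariate_names(self) -> list[str]:
        return [s.name for s in self.spec]

    @property
    def ps_covariate_names(self) -> list[str]:
        return [s.name for s in ps_covariates(self.spec)]

    def spec_for(self, name: str) -> CovariateSpec:
        for s in self.spec:
            if s.name == name:
                return s
        raise KeyError(name)

    def copy(self) -> "CohortTable":
        return CohortTable(spec=list(self.spec), df=self.df.copy())

    def subset(self, mask: np.ndarray | pd.Series) -> "CohortTable":
        return CohortTable(spec=list(self.spec), df=self.df.loc[mask].copy())

    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame (rows x covariates): True where a cell is missing."""
        return self.df[self.covariate_names].isna()

    def require_two_arms(self) -> None:
        counts = self.df[ARM_COL].value_counts()
        for arm in ARMS:
            if counts.get(arm, 0) == 0:
                raise ValidationError(f"arm {arm!r} is empty")

    def equals(self, other: "CohortTable", rtol: float = 0.0, atol: float = 1e-12) -> bool:
        if [s.name for s in self.spec] != [s.name for s in other.spec]:
            return False
        if len(self.df) != len(other.df):
            return False
        a, b = self.df, other.df
        for col in canonical_columns(self.spec):
            if col in (ID_COL, ARM_COL, OUTCOME_COL) or (
                col in self.covariate_names and self.spec_for(col).kind == "categorical"
            ):
                av, bv = a[col].fillna("\0"), b[col].fillna("\0")
                if not (av.to_numpy() == bv.to_numpy()).all():
                    return False
            else:
                av = pd.to_numeric(a[col], errors="coerce").to_numpy(dtype=float)
                bv = pd.to_numeric(b[col], errors="coerce").to_numpy(dtype=float)
                both_nan = np.isnan(av) & np.isnan(bv)
                close = np.isclose(av, bv, rtol=rtol, atol=atol)
                if not (both_nan | close).all():
                    return False
        return True


# -- IO ------------------------------------------------------------------


def load_cohort(path: str, spec: list[CovariateSpec] | None = None) -> CohortTable:
    """Read and validate a cohort CSV.

    Missing values must be empty cells; every other cell is type-coerced per
    the schema, with errors that name the offending row and column.
    """
    if spec is None:
        spec = default_schema()
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    expected = canonical_columns(spec)
    unknown = [c for c in raw.columns if c not in expected]
    if unknown:
        raise ValidationError(f"unknown column(s): {unknown}")
    absent = [c for c in expected if c not in raw.columns]
    if absent:
        raise ValidationError(f"missing column(s): {absent}")
    return CohortTable(spec=list(spec), df=raw)


def write_cohort(cohort: CohortTable, path: str) -> None:
    """Write a cohort CSV in canonical column order, missing cells empty."""
    out = cohort.df.reindex(columns=canonical_columns(cohort.spec)).copy()
    float_cols = list(TIME_COLS)
    for s in cohort.spec:
        if s.kind == "binary":
            col = out[s.name]
            out[s.name] = col.map(lambda v: "" if pd.isna(v) else str(int(v)))
        elif s.kind == "continuous":
            float_cols.append(s.name)
    for col in float_cols:  # repr round-trips float64 exactly
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False, na_rep="")


def summarize_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Per-arm covariate summary: n / mean / sd for continuous covariates,
    count / pct per level for binary and categorical ones (sample SD,
    n-1 denominator)."""
    if cohort.n == 0:
        raise ValidationError("cannot summarize an empty cohort")
    rows = []
    for arm in ARMS:
        sub = cohort.df[cohort.df[ARM_COL] == arm]
        n_arm = len(sub)
        for s in cohort.spec:
            col = sub[s.name]
            obs = col.dropna()
            if s.kind == "continuous":
                rows.append(
                    dict(
                        variable=s.name, level="", arm=arm, n=len(obs),
                        mean=float(obs.mean()) if len(obs) else np.nan,
                        sd=float(obs.std(ddof=1)) if len(obs) > 1 else np.nan,
                        count=np.nan, pct=np.nan,
                    )
                )
            else:
                levels = s.levels if s.kind == "categorical" else ("1",)
                for lv in levels:
                    if s.kind == "categorical":
                        cnt = int((obs == lv).sum())
                    else:
                        cnt = int((obs == 1.0).sum())
                    rows.append(
                        dict(
                            variable=s.name, level=lv, arm=arm, n=len(obs),
                            mean=np.nan, sd=np.nan, count=cnt,
                            pct=100.0 * cnt / len(obs) if len(obs) else np.nan,
                        )
                    )
    return pd.DataFrame(rows)


def with_ps_set(spec: list[CovariateSpec], names: list[str]) -> list[CovariateSpec]:
    """Return a schema whose PS flag is set exactly on ``names``."""
    known = {s.name for s in spec}
    missing = set(names) - known
    if missing:
        raise ValidationError(f"unknown covariate(s) in PS set: {sorted(missing)}")
    return [replace(s, in_propensity_model=(s.name in names)) for s in spec]
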