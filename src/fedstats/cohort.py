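"""Harmonized patient-level data model for multi-center federation nodes.

One node holds one :class:`CohortTable` — a validated flat table of
pseudonymized patient records (one row per patient) following a shared
variable schema.  This module is the ingestion boundary: everything
upstream (hospital ETL, FHIR mapping) is out of scope, everything
downstream only ever sees aggregates.

Conventions
-----------
* All day offsets (first-line duration, second-line start, death,
  transfer) are counted from the patient's inclusion, day 0.
* The inclusion period is ``before`` or ``after`` the first pandemic
  wave, assigned from the inclusion date against two closed calendar
  windows.
* Disease progression within the observation window (default 24 months)
  is proxied by the start of a second treatment line or death, whichever
  comes first; patients who transferred to another center are censored at
  the transfer date, everyone else at the end of the window.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .dp import ClampBounds

__all__ = [
    "VariableSchema",
    "StudyConfig",
    "OutcomeRecord",
    "CohortTable",
    "CohortValidationError",
    "OutOfStudyError",
    "default_schemas",
    "load_cohort",
    "write_cohort",
    "assign_period",
    "derive_outcome",
    "load_study_config",
]

PERIODS = ("before", "after")

GENDER_LEVELS = ["Female", "Male"]
AGE_LEVELS = ["<55", "55-65", ">65"]
BMI_LEVELS = ["<18.5", "18.5-25", ">25"]
TREATMENT_LEVELS = [
    "Chemotherapy",
    "Chemotherapy+angiogenesis inhibitor",
    "Chemotherapy+immunotherapy",
    "Immunotherapy",
]
PROGRESSION_LEVELS = ["No", "Yes"]

OUTCOME_DAY_COLUMNS = ("secondline_start_day", "death_day", "transfer_day")


class CohortValidationError(ValueError):
    """A record violated the schema (unknown category, bad date, duplicate id)."""


class OutOfStudyError(ValueError):
    """An inclusion date fell outside both study windows."""


@dataclass(frozen=True)
class VariableSchema:
    """Declared type, levels and clamping bounds for one study variable."""

    name: str
    kind: Literal["categorical", "quantitative", "date", "duration"]
    categories: tuple[str, ...] | None = None
    clamp: ClampBounds | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind == "categorical":
            if self.categories is None or len(self.categories) < 2:
                raise ValueError(f"{self.name}: categorical schema needs >= 2 categories")
        elif self.kind in ("quantitative", "duration"):
            if self.clamp is None:
                raise ValueError(f"{self.name}: quantitative schema needs clamp bounds")


def default_schemas() -> dict[str, VariableSchema]:
    """The study's harmonized variable set with default clamping bounds.

    Clamping bounds are public knowledge (physiology / protocol), not
    data-derived: creatinemia [20, 300] umol/L, durations [0, 1500] days.
    They are overridable through the study config.
    """
    return {
        s.name: s
        for s in (
            VariableSchema("gender", "categorical", tuple(GENDER_LEVELS)),
            VariableSchema("age_class", "categorical", tuple(AGE_LEVELS), units="years"),
            VariableSchema("bmi_class", "categorical", tuple(BMI_LEVELS), units="kg/m2"),
            VariableSchema("treatment_category", "categorical", tuple(TREATMENT_LEVELS)),
            VariableSchema("progression", "categorical", tuple(PROGRESSION_LEVELS)),
            VariableSchema(
                "creatinemia", "quantitative", clamp=ClampBounds(20.0, 300.0), units="umol/L"
            ),
            VariableSchema(
                "firstline_duration_days",
                "duration",
                clamp=ClampBounds(0.0, 1500.0),
                units="days",
            ),
        )
    }


@dataclass(frozen=True)
class StudyConfig:
    """Study-level windows, observation span, disclosure and DP defaults."""

    before_window: tuple[dt.date, dt.date] = (dt.date(2019, 3, 1), dt.date(2020, 3, 1))
    after_window: tuple[dt.date, dt.date] = (dt.date(2020, 3, 2), dt.date(2021, 3, 31))
    observation_days: int = 730
    disclosure_min_cell: int = 3
    epsilon_univariate: float = 5.0
    epsilon_ttest: float = 60.0
    screening_alpha: float = 0.20

    def __post_init__(self) -> None:
        b0, b1 = self.before_window
        a0, a1 = self.after_window
        if not (b0 <= b1 and a0 <= a1):
            raise ValueError("study windows must be ordered date intervals")
        if not (b1 < a0 or a1 < b0):
            raise ValueError("study windows must be disjoint")
        if self.epsilon_univariate <= 0 or self.epsilon_ttest <= 0:
            raise ValueError("privacy budgets must be > 0")
        if not 0 < self.screening_alpha < 1:
            raise ValueError("screening_alpha must be in (0, 1)")


@dataclass(frozen=True)
class OutcomeRecord:
    """Derived time-to-event outcome for one patient."""

    time_days: float
    event: Literal["progressed", "censored"]
    censor_reason: Literal["none", "end_of_window", "transfer"]


def assign_period(inclusion_date: dt.date, config: StudyConfig) -> str:
    """Map an inclusion date to ``before`` or ``after`` (closed windows)."""
    if config.before_window[0] <= inclusion_date <= config.before_window[1]:
        return "before"
    if config.after_window[0] <= inclusion_date <= config.after_window[1]:
        return "after"
    raise OutOfStudyError(f"inclusion date {inclusion_date} outside both study windows")


def derive_outcome(record: Mapping, config: StudyConfig) -> OutcomeRecord:
    """Apply the progression-proxy rule to one patient record.

    The event time is the earlier of second-line start and death.  The
    event counts only if it falls inside the patient's observed span,
    which ends at the transfer date if they changed centers and at the
    administrative window otherwise.
    """

    def day(key: str) -> float:
        v = record.get(key)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return np.inf
        v = float(v)
        if v < 0:
            raise CohortValidationError(f"{key} must be >= 0, got {v}")
        return v

    proxy = min(day("secondline_start_day"), day("death_day"))
    horizon = min(float(config.observation_days), day("transfer_day"))
    if proxy <= horizon:
        return OutcomeRecord(proxy, "progressed", "none")
    reason = "transfer" if day("transfer_day") <= config.observation_days else "end_of_window"
    return OutcomeRecord(horizon, "censored", reason)


class CohortTable:
    """One node's validated patient table (pandas-backed, one row per patient)."""

    REQUIRED = (
        "patient_id",
        "center",
        "inclusion_date",
        "gender",
        "age_class",
        "bmi_class",
        "treatment_category",
        "creatinemia",
        "firstline_duration_days",
        "secondline_start_day",
        "death_day",
        "transfer_day",
    )

    def __init__(
        self,
        df: pd.DataFrame,
        schemas: Mapping[str, VariableSchema] | None = None,
        config: StudyConfig | None = None,
    ) -> None:
        self.schemas = dict(schemas) if schemas is not None else default_schemas()
        self.config = config if config is not None else StudyConfig()
        self.df = self._validate(df.copy())

    def _validate(self, df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise CohortValidationError(f"missing columns: {missing}")
        if df["patient_id"].duplicated().any():
            dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise CohortValidationError(f"duplicate patient_id within node: {dup!r}")
        if len(df) == 0:
            df["period"] = pd.Series(dtype=object)
            return df
        # dates
        try:
            dates = pd.to_datetime(df["inclusion_date"].astype(str), format="ISO8601").dt.date
        except (ValueError, TypeError) as exc:
            raise CohortValidationError(f"malformed inclusion_date: {exc}") from exc
        df["inclusion_date"] = dates
        df["period"] = [assign_period(d, self.config) for d in dates]
        # categoricals
        for name, schema in self.schemas.items():
            if schema.kind != "categorical" or name not in df.columns:
                continue
            bad = ~df[name].isin(schema.categories) & df[name].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortValidationError(
                    f"row {row}: unknown category {df[name].iloc[row]!r} for {name!r}"
                )
        # numeric day offsets
        for col in ("firstline_duration_days",) + OUTCOME_DAY_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="raise")
            if (df[col].dropna() < 0).any():
                raise CohortValidationError(f"{col} contains negative day offsets")
        df["creatinemia"] = pd.to_numeric(df["creatinemia"], errors="raise")
        return df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def center(self) -> str:
        return str(self.df["center"].iloc[0]) if len(self.df) else "empty"

    def outcomes(self) -> pd.DataFrame:
        """Per-patient derived outcome (time, event flag, censor reason)."""
        recs = [derive_outcome(row, self.config) for row in self.df.to_dict("records")]
        return pd.DataFrame(
            {
                "patient_id": self.df["patient_id"],
                "period": self.df["period"],
                "time_days": [r.time_days for r in recs],
                "event": [1 if r.event == "progressed" else 0 for r in recs],
                "censor_reason": [r.censor_reason for r in recs],
            }
        )

    def subset(self, mask: pd.Series) -> "CohortTable":
        return CohortTable(self.df.loc[mask].reset_index(drop=True), self.schemas, self.config)


def load_cohort(
    path: str | Path,
    schemas: Mapping[str, VariableSchema] | None = None,
    config: StudyConfig | None = None,
) -> CohortTable:
    """Read one node's cohort CSV (UTF-8, header row, ISO-8601 dates)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"patient_id": str, "center": str})
    return CohortTable(df, schemas, config)


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write the cohort CSV dialect (round-trips through load_cohort)."""
    out = table.df.drop(columns=["period"], errors="ignore")
    out.to_csv(path, index=False)


def _parse_window(raw: Sequence[str]) -> tuple[dt.date, dt.date]:
    a, b = raw
    return (dt.date.fromisoformat(str(a)), dt.date.fromisoformat(str(b)))


def load_study_config(path: str | Path) -> tuple[StudyConfig, dict[str, VariableSchema]]:
    """Read StudyConfig and schema clamp overrides from one YAML file.

    Recognized keys (all optional)::

        study:
          before_window: [2019-03-01, 2020-03-01]
          after_window: [2020-03-02, 2021-03-31]
          observation_days: 730
          disclosure_min_cell: 3
          epsilon_univariate: 5.0
          epsilon_ttest: 60.0
          screening_alpha: 0.20
        clamp:
          creatinemia: [20, 300]
          firstline_duration_days: [0, 1500]
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    study = raw.get("study", {}) or {}
    kwargs: dict = {}
    if "before_window" in study:
        kwargs["before_window"] = _parse_window(study["before_window"])
    if "after_window" in study:
        kwargs["after_window"] = _parse_window(study["after_window"])
    for key in (
        "observation_days",
        "disclosure_min_cell",
        "epsilon_univariate",
        "epsilon_ttest",
        "screening_alpha",
    ):
        if key in study:
            kwargs[key] = study[key]
    config = StudyConfig(**kwargs)
    schemas = default_schemas()
    for name, (lo, hi) in (raw.get("clamp", {}) or {}).items():
        if name not in schemas:
            raise KeyError(f"clamp override for unknown variable {name!r}")
        old = schemas[name]
        schemas[name] = VariableSchema(
            old.name, old.kind, old.categories, ClampBounds(float(lo), float(hi)), old.units
        )
    return config, schemas
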