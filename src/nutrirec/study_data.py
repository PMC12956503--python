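"""Cohort tables, guideline specifications, standardization, and file I/O.

The estimation stage consumes long-format cohort tables of repeated
food-record / laboratory pairs: one row per (subject, visit) with fixed
personal covariates (sex, medications, ...), time-varying nutrient intakes in
natural units (g/d, mg/d, E%, ...) and strictly positive plasma
concentrations (mmol/L, mU/L, g/L).  The recommendation stage additionally
needs guideline intake ranges per nutrient and clinical target ranges per
concentration, the latter possibly conditional on age/sex.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

try:  # packaged Table-1/2-shaped fixtures
    from importlib import resources as _resources
except ImportError:  # pragma: no cover
    _resources = None

__all__ = [
    "ColumnSchema",
    "CohortTable",
    "ValidationReport",
    "StandardizationParams",
    "NutrientSpec",
    "ConcentrationRule",
    "ConcentrationSpec",
    "read_cohort",
    "write_cohort",
    "standardize",
    "destandardize",
    "normalize_spec",
    "denormalize_spec",
    "load_nutrient_specs",
    "load_concentration_specs",
]


class CohortValidationError(ValueError):
    """Raised when a cohort file violates a structural invariant."""


@dataclass(frozen=True)
class ColumnSchema:
    """Assigns a role to every column of a long-format cohort file."""

    subject: str
    concentrations: tuple[str, ...]
    nutrients: tuple[str, ...]
    fixed: tuple[str, ...] = ()
    visit: str | None = None
    group: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "concentrations", tuple(self.concentrations))
        object.__setattr__(self, "nutrients", tuple(self.nutrients))
        object.__setattr__(self, "fixed", tuple(self.fixed))
        if len(self.concentrations) < 1:
            raise ValueError("schema needs at least one concentration column")
        if len(self.nutrients) < 1:
            raise ValueError("schema needs at least one nutrient column")
        names = [self.subject, *self.concentrations, *self.nutrients, *self.fixed]
        if self.visit:
            names.append(self.visit)
        if self.group:
            names.append(self.group)
        if len(set(names)) != len(names):
            raise ValueError("schema assigns one column more than one role")

    @property
    def all_columns(self) -> list[str]:
        cols = [self.subject]
        if self.group:
            cols.append(self.group)
        if self.visit:
            cols.append(self.visit)
        cols += [*self.fixed, *self.nutrients, *self.concentrations]
        return cols

    def to_dict(self) -> dict:
        return {
            "subject": self.subject,
            "group": self.group,
            "visit": self.visit,
            "fixed": list(self.fixed),
            "nutrients": list(self.nutrients),
            "concentrations": list(self.concentrations),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ColumnSchema":
        return cls(
            subject=d["subject"],
            group=d.get("group"),
            visit=d.get("visit"),
            fixed=tuple(d.get("fixed", ())),
            nutrients=tuple(d["nutrients"]),
            concentrations=tuple(d["concentrations"]),
        )


@dataclass
class ValidationReport:
    n_rows_in: int = 0
    n_rows_kept: int = 0
    rejected: pd.DataFrame | None = None
    messages: list[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return 0 if self.rejected is None else len(self.rejected)


@dataclass
class CohortTable:
    """Validated long-format cohort: one row per (subject, visit)."""

    data: pd.DataFrame
    schema: ColumnSchema
    validation: ValidationReport | None = None
    standardized: bool = False

    def __post_init__(self):
        self.data = self.data.reset_index(drop=True)

    # -- basic dimensions ----------------------------------------------------
    @property
    def subject_ids(self) -> list:
        return list(pd.unique(self.data[self.schema.subject]))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_concentrations(self) -> int:
        return len(self.schema.concentrations)

    @property
    def n_nutrients(self) -> int:
        return len(self.schema.nutrients)

    def n_visits(self, subject_id) -> int:
        return int((self.data[self.schema.subject] == subject_id).sum())

    def subject_rows(self, subject_id) -> pd.DataFrame:
        rows = self.data[self.data[self.schema.subject] == subject_id]
        if rows.empty:
            raise KeyError(f"unknown subject {subject_id!r}")
        return rows

    def latest_record(self, subject_id) -> pd.Series:
        rows = self.subject_rows(subject_id)
        if self.schema.visit:
            rows = rows.sort_values(self.schema.visit)
        return rows.iloc[-1]

    # -- array views used by the estimation stage ---------------------------
    def predictor_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X fixed, Z varying) as float arrays, one row per record."""
        X = self.data[list(self.schema.fixed)].to_numpy(float) if self.schema.fixed \
            else np.empty((len(self.data), 0))
        Z = self.data[list(self.schema.nutrients)].to_numpy(float)
        return X, Z

    def concentration_matrix(self) -> np.ndarray:
        return self.data[list(self.schema.concentrations)].to_numpy(float)

    def subject_index(self) -> np.ndarray:
        """Integer subject index per row, in order of first appearance."""
        codes = pd.Categorical(
            self.data[self.schema.subject], categories=self.subject_ids
        ).codes
        return np.asarray(codes, dtype=int)

    def group_index(self) -> tuple[np.ndarray, list] | None:
        if not self.schema.group:
            return None
        labels = list(pd.unique(self.data[self.schema.group]))
        codes = pd.Categorical(self.data[self.schema.group], categories=labels).codes
        return np.asarray(codes, dtype=int), labels


def _validate(df: pd.DataFrame, schema: ColumnSchema) -> tuple[pd.DataFrame, ValidationReport]:
    missing = [c for c in schema.all_columns if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing mandatory columns: {missing}")
    report = ValidationReport(n_rows_in=len(df))
    df = df.copy()

    numeric_cols = [*schema.fixed, *schema.nutrients, *schema.concentrations]
    for c in numeric_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")

    bad_missing = df[numeric_cols].isna().any(axis=1)
    bad_conc = (df[list(schema.concentrations)] <= 0).any(axis=1) & ~bad_missing
    bad = bad_missing | bad_conc
    if bad.any():
        rej = df[bad].copy()
        rej["_reason"] = np.where(
            bad_missing[bad], "missing value", "non-positive concentration"
        )
        report.rejected = rej
        report.messages.append(f"rejected {int(bad.sum())} row(s)")
        df = df[~bad]

    if df.empty:
        raise CohortValidationError("no valid rows after validation")

    # fixed covariates (and group) must be constant within subject
    const_cols = list(schema.fixed) + ([schema.group] if schema.group else [])
    if const_cols:
        nun = df.groupby(schema.subject, sort=False)[const_cols].nunique()
        varying = nun[(nun > 1).any(axis=1)]
        if len(varying):
            subj = varying.index[0]
            col = varying.columns[(varying.iloc[0] > 1).to_numpy()][0]
            raise CohortValidationError(
                f"fixed covariate {col!r} varies within subject {subj!r}"
            )
    report.n_rows_kept = len(df)
    return df.reset_index(drop=True), report


def read_cohort(path, schema: ColumnSchema, sep: str | None = None) -> CohortTable:
    """Read and validate a delimited cohort file.

    Rows with missing values or non-positive concentrations are dropped and
    listed in ``table.validation.rejected``; structural violations raise
    :class:`CohortValidationError`.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    data, report = _validate(df, schema)
    return CohortTable(data=data, schema=schema, validation=report)


def write_cohort(table: CohortTable, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table.data.to_csv(path, sep=sep, index=False)


def from_frame(df: pd.DataFrame, schema: ColumnSchema) -> CohortTable:
    """Validate an in-memory frame (same rules as :func:`read_cohort`)."""
    data, report = _validate(df, schema)
    return CohortTable(data=data, schema=schema, validation=report)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardizationParams:
    """Per-predictor z-scoring parameters (sample mean / sd, ddof=1).

    Binary predictors are flagged passthrough and left on their natural scale.
    """

    mean: dict[str, float]
    sd: dict[str, float]
    standardized: dict[str, bool]

    def transform(self, name: str, x):
        if not self.standardized[name]:
            return x
        return (np.asarray(x, float) - self.mean[name]) / self.sd[name]

    def inverse(self, name: str, z):
        if not self.standardized[name]:
            return z
        return np.asarray(z, float) * self.sd[name] + self.mean[name]

    def subset(self, names: Iterable[str]) -> "StandardizationParams":
        names = list(names)
        return StandardizationParams(
            mean={n: self.mean[n] for n in names},
            sd={n: self.sd[n] for n in names},
            standardized={n: self.standardized[n] for n in names},
        )

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "standardized": self.standardized}

    @classmethod
    def from_dict(cls, d: Mapping) -> "StandardizationParams":
        return cls(mean=dict(d["mean"]), sd=dict(d["sd"]),
                   standardized=dict(d["standardized"]))


def _is_binary(col: pd.Series) -> bool:
    vals = set(pd.unique(col.dropna()))
    return vals <= {0, 1, 0.0, 1.0, True, False}


def standardize(
    table: CohortTable, passthrough_binary: bool = True
) -> tuple[CohortTable, StandardizationParams]:
    """z-score every predictor column; concentrations are left untouched.

    Binary covariates (values in {0,1}) are passed through unchanged unless
    ``passthrough_binary=False``, which z-scores them too.
    """
    df = table.data.copy()
    schema = table.schema
    mean, sd, flag = {}, {}, {}
    for c in [*schema.fixed, *schema.nutrients]:
        col = df[c]
        if passthrough_binary and _is_binary(col):
            mean[c], sd[c], flag[c] = 0.0, 1.0, False
            continue
        m = float(col.mean())
        s = float(col.std(ddof=1))
        if not np.isfinite(s) or s <= 0:
            raise ValueError(f"predictor {c!r} has zero variance; cannot standardize")
        df[c] = (col - m) / s
        mean[c], sd[c], flag[c] = m, s, True
    params = StandardizationParams(mean=mean, sd=sd, standardized=flag)
    out = CohortTable(data=df, schema=schema, validation=table.validation,
                      standardized=True)
    return out, params


def destandardize(table: CohortTable, params: StandardizationParams) -> CohortTable:
    df = table.data.copy()
    for c, is_std in params.standardized.items():
        if is_std and c in df.columns:
            df[c] = df[c] * params.sd[c] + params.mean[c]
    return CohortTable(data=df, schema=table.schema, validation=table.validation,
                       standardized=False)


# ---------------------------------------------------------------------------
# Guideline / target specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NutrientSpec:
    """Guideline intake range [lower, upper] and optional recommended point."""

    name: str
    lower: float
    upper: float
    recommended: float | None = None
    units: str = ""

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower must be < upper")
        if self.recommended is not None and not (
            self.lower <= self.recommended <= self.upper
        ):
            raise ValueError(f"{self.name}: recommended point outside range")


def normalize_spec(spec: NutrientSpec, params: StandardizationParams) -> NutrientSpec:
    """Map a natural-unit guideline range onto the z-scored inference scale."""
    if spec.name not in params.mean:
        raise KeyError(f"nutrient {spec.name!r} not in standardization params")
    rec = None if spec.recommended is None else float(
        params.transform(spec.name, spec.recommended)
    )
    return replace(
        spec,
        lower=float(params.transform(spec.name, spec.lower)),
        upper=float(params.transform(spec.name, spec.upper)),
        recommended=rec,
    )


def denormalize_spec(spec: NutrientSpec, params: StandardizationParams) -> NutrientSpec:
    if spec.name not in params.mean:
        raise KeyError(f"nutrient {spec.name!r} not in standardization params")
    rec = None if spec.recommended is None else float(
        params.inverse(spec.name, spec.recommended)
    )
    return replace(
        spec,
        lower=float(params.inverse(spec.name, spec.lower)),
        upper=float(params.inverse(spec.name, spec.upper)),
        recommended=rec,
    )


@dataclass(frozen=True)
class ConcentrationRule:
    """One clinical target range with an age/sex/group selector.

    ``None`` selector fields match anything; ``age_min``/``age_max`` are
    inclusive.
    """

    lower: float
    upper: float
    sex: str | None = None
    age_min: float | None = None
    age_max: float | None = None
    group: str | None = None

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("rule lower must be < upper")

    def matches(self, attrs: Mapping) -> bool:
        if self.sex is not None and attrs.get("sex") != self.sex:
            return False
        age = attrs.get("age")
        if self.age_min is not None and (age is None or age < self.age_min):
            return False
        if self.age_max is not None and (age is None or age > self.age_max):
            return False
        if self.group is not None and attrs.get("group") != self.group:
            return False
        return True


@dataclass(frozen=True)
class ConcentrationSpec:
    """Clinical target ranges for one concentration, conditional on age/sex."""

    name: str
    rules: tuple[ConcentrationRule, ...]
    units: str = ""

    def __post_init__(self):
        object.__setattr__(self, "rules", tuple(self.rules))
        if not self.rules:
            raise ValueError(f"{self.name}: at least one rule required")

    def resolve(self, attrs: Mapping | None = None) -> tuple[float, float]:
        """Return (lower, upper) for a subject; exactly one rule must apply."""
        attrs = attrs or {}
        hits = [r for r in self.rules if r.matches(attrs)]
        if len(hits) == 0:
            raise KeyError(f"{self.name}: no target rule matches {dict(attrs)!r}")
        if len(hits) > 1:
            raise KeyError(
                f"{self.name}: {len(hits)} target rules match {dict(attrs)!r}; "
                "selectors must partition the population"
            )
        return hits[0].lower, hits[0].upper


# -- JSON I/O ----------------------------------------------------------------

def _nutrient_from_dict(d: Mapping) -> NutrientSpec:
    return NutrientSpec(
        name=d["name"], lower=float(d["lower"]), upper=float(d["upper"]),
        recommended=(None if d.get("recommended") is None else float(d["recommended"])),
        units=d.get("units", ""),
    )


def _conc_from_dict(d: Mapping) -> ConcentrationSpec:
    rules = tuple(
        ConcentrationRule(
            lower=float(r["lower"]), upper=float(r["upper"]),
            sex=r.get("sex"), age_min=r.get("age_min"), age_max=r.get("age_max"),
            group=r.get("group"),
        )
        for r in d["rules"]
    )
    return ConcentrationSpec(name=d["name"], rules=rules, units=d.get("units", ""))


def _load_spec_file(path_or_preset, kind: str):
    p = Path(str(path_or_preset))
    if p.exists():
        payload = json.loads(p.read_text())
    else:  # packaged preset name, e.g. "sysdimet" / "dialysis"
        fname = f"{path_or_preset}_{kind}.json"
        ref = _resources.files("nutrirec.data").joinpath(fname)
        if not ref.is_file():
            raise FileNotFoundError(f"no spec file or preset named {path_or_preset!r}")
        payload = json.loads(ref.read_text())
    return payload


def load_nutrient_specs(path_or_preset) -> list[NutrientSpec]:
    """Load nutrient guideline specs from a JSON file or packaged preset."""
    payload = _load_spec_file(path_or_preset, "nutrients")
    return [_nutrient_from_dict(d) for d in payload]


def load_concentration_specs(path_or_preset) -> list[ConcentrationSpec]:
    """Load concentration target specs from a JSON file or packaged preset."""
    payload = _load_spec_file(path_or_preset, "concentrations")
    return [_conc_from_dict(d) for d in payload]
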