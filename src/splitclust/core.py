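"""Domain types and cohort I/O.

The pipeline's universal input is a rectangular patient table: one row per
patient, columns for demographics (age, sex), clinical ordinal scores
(Fisher, Hunt and Hess, GOS, mRS), a binary group label (CVS yes/no), a
set label (training/validation) and a panel of continuous serum biomarkers.
A :class:`VariableSchema` declares the role and measurement scale of every
column and drives which statistical test or transform applies downstream.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "ROLES",
    "SCALES",
    "Variable",
    "VariableSchema",
    "Cohort",
    "AnalysisConfig",
    "CohortError",
    "SchemaError",
    "EmptyCohortError",
    "read_cohort",
    "write_cohort",
    "exclude_incomplete",
    "count_variable_pairs",
    "default_schema",
]

ROLES = (
    "biomarker",
    "demographic",
    "clinical_score",
    "outcome_score",
    "group_label",
    "set_label",
)
SCALES = ("continuous", "binary", "ordinal")

#: canonical values of the set label column
TRAINING, VALIDATION = "training", "validation"

#: values accepted as missing in CSV/TSV input
MISSING_TOKENS = ["", "NA"]


class CohortError(ValueError):
    """Malformed cohort table (bad value, duplicate id, unknown column ...)."""


class SchemaError(CohortError):
    """Schema violated: missing/unknown column, bad role/scale declaration."""


class EmptyCohortError(CohortError):
    """An operation left no patients in the cohort."""


@dataclass(frozen=True)
class Variable:
    """Declaration of one cohort column.

    Parameters
    ----------
    name : str
        Column name in the patient table.
    role : str
        One of :data:`ROLES`.
    scale : str
        ``continuous``, ``binary`` or ``ordinal``.
    levels : tuple, optional
        Ordered levels; required (>= 2) for ordinal variables.
    coding : mapping, optional
        Human-readable coding map for encoded values, e.g. ``{1: "female"}``.
    """

    name: str
    role: str
    scale: str
    levels: tuple | None = None
    coding: Mapping | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for {self.name!r}")
        if self.scale not in SCALES:
            raise SchemaError(f"unknown scale {self.scale!r} for {self.name!r}")
        if self.scale == "ordinal":
            if self.levels is None or len(self.levels) < 2:
                raise SchemaError(
                    f"ordinal variable {self.name!r} must declare >= 2 levels"
                )
        if self.levels is not None and not isinstance(self.levels, tuple):
            object.__setattr__(self, "levels", tuple(self.levels))


@dataclass(frozen=True)
class VariableSchema:
    """Set of :class:`Variable` declarations plus the patient-id column.

    Exactly one variable carries role ``group_label`` (the binary outcome
    stratifying the analysis) and exactly one carries ``set_label``
    (training/validation membership).  ``correlation_variables`` names the
    subset entering the pairwise-correlation stage; by default these are the
    biomarkers plus any continuous demographic plus the Hunt and Hess score,
    mirroring the screened panel of 12 analysis variables.
    """

    variables: tuple[Variable, ...]
    id_column: str = "patient_id"
    correlation_variables: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("variable names must be unique within a schema")
        if self.id_column in names:
            raise SchemaError("id column must not double as an analysis variable")
        for role in ("group_label", "set_label"):
            k = sum(v.role == role for v in self.variables)
            if k != 1:
                raise SchemaError(f"schema needs exactly one {role} variable, got {k}")
        if self.correlation_variables is not None:
            object.__setattr__(
                self, "correlation_variables", tuple(self.correlation_variables)
            )
            unknown = set(self.correlation_variables) - set(names)
            if unknown:
                raise SchemaError(f"correlation variables not in schema: {unknown}")

    # -- lookups ---------------------------------------------------------
    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def by_role(self, role: str) -> list[str]:
        return [v.name for v in self.variables if v.role == role]

    @property
    def group_label(self) -> str:
        return self.by_role("group_label")[0]

    @property
    def set_label(self) -> str:
        return self.by_role("set_label")[0]

    @property
    def biomarkers(self) -> list[str]:
        return self.by_role("biomarker")

    @property
    def analysis_variables(self) -> list[str]:
        """Variables entering the correlation analysis."""
        if self.correlation_variables is not None:
            return list(self.correlation_variables)
        out = list(self.biomarkers)
        out += [
            v.name
            for v in self.variables
            if v.role == "demographic" and v.scale == "continuous"
        ]
        return out


#: Biomarker panel in the canonical order used throughout.
BIOMARKERS = (
    "HMGB1",
    "Cyt-B",
    "D-loop",
    "Cox-1",
    "IL-6",
    "IL-17",
    "IL-23",
    "IL-10",
    "CCL5",
    "Leukocytes",
)


def default_schema() -> VariableSchema:
    """Schema for the aSAH/CVS biomarker cohort.

    Ten serum biomarkers, age and sex, four ordinal clinical scores, the CVS
    group label and the training/validation set label.  The 12 correlation
    variables are the biomarkers plus age plus the Hunt and Hess score;
    Fisher grade and the outcome scores (GOS, mRS) are screened but excluded
    from the correlation stage.
    """
    variables = [Variable(b, "biomarker", "continuous") for b in BIOMARKERS]
    variables += [
        Variable("age", "demographic", "continuous"),
        Variable("sex", "demographic", "binary", coding={1: "female", 0: "male"}),
        Variable("Fisher", "clinical_score", "ordinal", levels=(1, 2, 3, 4)),
        Variable("HuntHess", "clinical_score", "ordinal", levels=(1, 2, 3, 4, 5)),
        Variable("GOS", "outcome_score", "ordinal", levels=(1, 2, 3, 4, 5)),
        Variable("mRS", "outcome_score", "ordinal", levels=(0, 1, 2, 3, 4, 5, 6)),
        Variable("CVS", "group_label", "binary"),
        Variable("set", "set_label", "ordinal", levels=(TRAINING, VALIDATION)),
    ]
    return VariableSchema(
        tuple(variables),
        correlation_variables=BIOMARKERS + ("age", "HuntHess"),
    )


@dataclass
class Cohort:
    """A patient table conforming to a :class:`VariableSchema`.

    ``data`` keeps one row per patient with the id column present.  Rows with
    missing analysis values are *flagged*, never silently dropped; use
    :func:`exclude_incomplete` to obtain the complete-case subset together
    with an auditable exclusion log.
    """

    data: pd.DataFrame
    schema: VariableSchema
    exclusion_log: list[tuple[object, tuple[str, ...]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing_cols = set(self.schema.names + [self.schema.id_column]) - set(
            self.data.columns
        )
        if missing_cols:
            raise SchemaError(f"cohort table lacks columns: {sorted(missing_cols)}")
        ids = self.data[self.schema.id_column]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].tolist()
            raise CohortError(f"duplicate patient identifier(s): {dup}")
        sets = set(self.data[self.schema.set_label].dropna().unique())
        if not sets <= {TRAINING, VALIDATION}:
            raise CohortError(f"set label takes unexpected values: {sorted(sets)}")

    def __len__(self) -> int:
        return len(self.data)

    # -- missingness -----------------------------------------------------
    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data[self.schema.names].isna()

    @property
    def flagged_ids(self) -> list:
        """Patient ids with at least one missing analysis value."""
        mask = self.missing_mask.any(axis=1)
        return self.data.loc[mask.to_numpy(), self.schema.id_column].tolist()

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.to_numpy().any()

    # -- set / stratum accessors ----------------------------------------
    @property
    def n_training(self) -> int:
        return int((self.data[self.schema.set_label] == TRAINING).sum())

    @property
    def n_validation(self) -> int:
        return int((self.data[self.schema.set_label] == VALIDATION).sum())

    def subset(self, mask) -> "Cohort":
        return Cohort(
            self.data.loc[mask].reset_index(drop=True).copy(),
            self.schema,
            list(self.exclusion_log),
        )

    def split(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(training rows, validation rows)."""
        s = self.data[self.schema.set_label]
        return self.data[s == TRAINING], self.data[s == VALIDATION]

    def strata(self) -> dict[object, "Cohort"]:
        """Sub-cohorts keyed by group-label value (e.g. CVS 1/0)."""
        g = self.data[self.schema.group_label]
        return {v: self.subset((g == v).to_numpy()) for v in sorted(g.unique())}


@dataclass
class AnalysisConfig:
    """Thresholds and options of the stability-clustering pipeline.

    delta_consistency
        Maximum allowed |r_train - r_val| for a pair to count as consistent
        (default 0.25; the loosened variant uses 0.3).
    tau_magnitude
        Minimum |r| on the combined set for a pair to count as relevant.
    min_cluster_size
        Minimum number of connected variables forming a cluster (default 3).
    n_splits, split_ratio
        Resampling-validation settings: number of random splits and the
        training fraction (default 2/3, the conventional 2:1 split).
    """

    delta_consistency: float = 0.25
    tau_magnitude: float = 0.25
    min_cluster_size: int = 3
    n_splits: int = 10_000
    split_ratio: float = 2 / 3
    rng_seed: int = 0
    correlation_kind: str = "pearson"
    # option flags (defaults follow the published procedure)
    relevance_on: str = "combined"  # or "train"
    cluster_method: str = "components"  # or "cliques"
    fit_transform_per_set: bool = False
    stratified_splits: bool = True
    slope_p_method: str = "interaction"  # or "welch_z"
    embedding_dissimilarity: str = "signed"  # or "absolute"

    def __post_init__(self) -> None:
        if not 0 < self.tau_magnitude < 1:
            raise ValueError("tau_magnitude must lie in (0, 1)")
        if not 0 < self.delta_consistency < 2:
            raise ValueError("delta_consistency must lie in (0, 2)")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must lie in (0, 1)")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")
        if self.correlation_kind not in ("pearson", "spearman"):
            raise ValueError("correlation_kind must be pearson or spearman")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

def _separator(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_cohort(path: str | Path, schema: VariableSchema) -> Cohort:
    """Read a CSV/TSV patient table against *schema*.

    Missing values are encoded as an empty field or ``NA``.  Rows with
    missing analysis values are flagged on the returned cohort, not dropped.

    Raises
    ------
    SchemaError
        Header does not match the schema (missing or unknown column).
    CohortError
        Non-coercible value, duplicate patient identifier.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_separator(path),
        na_values=MISSING_TOKENS,
        keep_default_na=False,
    )
    expected = set(schema.names) | {schema.id_column}
    unknown = set(df.columns) - expected
    if unknown:
        raise SchemaError(f"unknown column(s) in {path.name}: {sorted(unknown)}")
    df = _coerce(df, schema)
    return Cohort(df, schema)


def _coerce(df: pd.DataFrame, schema: VariableSchema) -> pd.DataFrame:
    df = df.copy()
    for var in schema.variables:
        if var.name not in df.columns:
            continue
        if var.role == "set_label":
            df[var.name] = df[var.name].astype("string").astype(object)
            continue
        try:
            df[var.name] = pd.to_numeric(df[var.name])
        except (ValueError, TypeError) as exc:
            raise CohortError(f"non-numeric value in column {var.name!r}: {exc}")
        if var.scale == "binary":
            vals = set(df[var.name].dropna().unique())
            if not vals <= {0, 1}:
                raise CohortError(f"binary column {var.name!r} takes values {vals}")
        elif var.scale == "ordinal" and var.levels is not None:
            vals = set(df[var.name].dropna().unique())
            if not vals <= set(var.levels):
                raise CohortError(
                    f"ordinal column {var.name!r} outside declared levels: "
                    f"{sorted(vals - set(var.levels))}"
                )
    return df


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort back to CSV/TSV; missing cells become ``NA``."""
    path = Path(path)
    cohort.data.to_csv(path, sep=_separator(path), index=False, na_rep="NA")


def exclude_incomplete(cohort: Cohort) -> Cohort:
    """Complete-case subset with an auditable exclusion log.

    The log records, per dropped patient, the id and the offending columns.
    Idempotent: a complete cohort is returned unchanged (empty log appended).

    Raises
    ------
    EmptyCohortError
        Every row carries at least one missing analysis value.
    """
    mask = cohort.missing_mask
    bad = mask.any(axis=1).to_numpy()
    log = list(cohort.exclusion_log)
    ids = cohort.data[cohort.schema.id_column]
    for i in range(len(cohort.data)):
        if bad[i]:
            cols = tuple(mask.columns[mask.iloc[i].to_numpy()])
            log.append((ids.iloc[i], cols))
    kept = cohort.data.loc[~bad].reset_index(drop=True).copy()
    if kept.empty:
        raise EmptyCohortError("all rows carry missing values; nothing to analyse")
    return Cohort(kept, cohort.schema, log)


def count_variable_pairs(n_variables: int) -> int:
    """Number of unordered variable pairs, n(n-1)/2 (12 variables -> 66)."""
    if n_variables < 2:
        raise ValueError("need at least 2 variables to form a pair")
    return n_variables * (n_variables - 1) // 2
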