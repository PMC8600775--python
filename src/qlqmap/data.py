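"""Analysis dataset, delimited-text readers and the complete-case filter.

The unit of analysis is a patient-visit: one row with the 15 QLQ-C30
scale/item scores (0-100), age in years, a patient identifier, and —
for estimation — either an EQ-5D-3L utility or the five dimension
responses.  Patients contribute repeated visits, so downstream models
cluster standard errors on ``patient_id``.

Covariates enter every model rescaled by 100 (scores in [0, 1]); age is
used in raw years.  The complete-case filter drops any row with a
missing outcome or a missing covariate and reports how much was lost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tariff import DIMENSIONS

__all__ = [
    "SCALE_COLUMNS",
    "FUNCTIONAL_SCALES",
    "SYMPTOM_SCALES",
    "RESPONSE_COLUMNS",
    "MappingDataset",
    "DropReport",
    "SchemaError",
    "read_dataset",
    "parse_column_map",
    "filter_complete_cases",
    "build_design_matrices",
    "rescale_scores",
]

#: Global health plus the five functional and nine symptom scales/items,
#: in the order they appear in the trial descriptive table.
SCALE_COLUMNS = [
    "global_health",
    "physical_f",
    "role_f",
    "emotional_f",
    "cognitive_f",
    "social_f",
    "fatigue",
    "nausea_vomiting",
    "pain",
    "dyspnoea",
    "insomnia",
    "appetite_loss",
    "constipation",
    "diarrhoea",
    "financial",
]
FUNCTIONAL_SCALES = SCALE_COLUMNS[1:6]
SYMPTOM_SCALES = SCALE_COLUMNS[6:]
RESPONSE_COLUMNS = list(DIMENSIONS)

ID_COLUMNS = ["patient_id", "visit_index", "age"]
UTILITY_COLUMN = "eq5d"

_DEFAULT_MISSING = ("", "NA", "NaN", "nan", ".", "NULL")


class SchemaError(ValueError):
    """Input file does not match the expected column schema."""


@dataclass
class DropReport:
    """Outcome of the complete-case filter."""

    n_total: int
    n_dropped: int

    @property
    def n_kept(self) -> int:
        return self.n_total - self.n_dropped

    @property
    def pct_dropped(self) -> float:
        return 100.0 * self.n_dropped / self.n_total if self.n_total else 0.0


@dataclass
class MappingDataset:
    """A mapping analysis dataset wrapping a long-format DataFrame.

    ``frame`` holds one row per patient-visit with ``patient_id``,
    ``visit_index``, ``age``, the 15 scale scores and, when available,
    an ``eq5d`` utility column and/or the five dimension response
    columns.
    """

    frame: pd.DataFrame
    has_utility: bool = False
    has_responses: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in ID_COLUMNS + SCALE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"dataset missing required columns: {missing}")
        if self.has_utility and UTILITY_COLUMN not in self.frame.columns:
            raise SchemaError(f"has_utility set but no '{UTILITY_COLUMN}' column")
        if self.has_responses:
            missing = [c for c in RESPONSE_COLUMNS if c not in self.frame.columns]
            if missing:
                raise SchemaError(f"has_responses set but missing: {missing}")

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    @property
    def n_patients(self) -> int:
        return self.frame["patient_id"].nunique()

    def rescaled(self) -> pd.DataFrame:
        """The 15 scale scores divided by 100 (idempotent on the raw frame)."""
        return rescale_scores(self.frame)


def rescale_scores(frame: pd.DataFrame) -> pd.DataFrame:
    """Return score/100 for each QLQ-C30 column; exact division, no centring."""
    return frame[SCALE_COLUMNS].astype(float) / 100.0


def parse_column_map(path: str | Path) -> dict[str, str]:
    """Parse a plain-text ``canonical: file_column`` map, one pair per line."""
    mapping: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise SchemaError(f"bad column-map line: {raw!r}")
        key, _, value = line.partition(":")
        mapping[key.strip()] = value.strip()
    return mapping


def read_dataset(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    has_responses: bool = False,
    missing_sentinels: Sequence[str] = _DEFAULT_MISSING,
) -> MappingDataset:
    """Read a delimited text file (comma or tab) into a :class:`MappingDataset`.

    ``column_map`` maps canonical names (``global_health`` ...) to the
    file's column names.  Out-of-range scores raise; missing cells are
    preserved as NaN for :func:`filter_complete_cases` to handle.
    """
    try:
        frame = pd.read_csv(
            path,
            sep=None,
            engine="python",
            na_values=list(missing_sentinels),
            keep_default_na=True,
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed delimited text
        raise SchemaError(f"could not parse {path}: {exc}") from exc

    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        missing_src = [s for s in rename if s not in frame.columns]
        if missing_src:
            raise SchemaError(f"column-map sources not in file: {missing_src}")
        frame = frame.rename(columns=rename)

    required = ID_COLUMNS + SCALE_COLUMNS
    outcome_cols: list[str] = []
    if has_responses:
        outcome_cols = RESPONSE_COLUMNS
    elif UTILITY_COLUMN in frame.columns:
        outcome_cols = [UTILITY_COLUMN]
    missing_cols = [c for c in required + outcome_cols if c not in frame.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory columns: {missing_cols}")

    for col in SCALE_COLUMNS + ["age"] + outcome_cols:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            raise SchemaError(
                f"non-numeric values in column '{col}' at rows "
                f"{frame.index[bad].tolist()[:5]}"
            )
        frame[col] = coerced

    for col in SCALE_COLUMNS:
        vals = frame[col].dropna()
        if ((vals < 0) | (vals > 100)).any():
            raise SchemaError(f"column '{col}' has scores outside [0, 100]")
    if (frame["age"].dropna() <= 0).any():
        raise SchemaError("non-positive ages present")
    if has_responses:
        for col in RESPONSE_COLUMNS:
            vals = frame[col].dropna()
            if not vals.isin([1, 2, 3]).all():
                raise SchemaError(f"column '{col}' has levels outside {{1,2,3}}")

    return MappingDataset(
        frame=frame,
        has_utility=UTILITY_COLUMN in frame.columns,
        has_responses=has_responses,
    )


def filter_complete_cases(data: MappingDataset) -> tuple[MappingDataset, DropReport]:
    """Drop rows with any missing outcome or QLQ-C30 covariate.

    Retained rows are untouched.  An empty result warns rather than
    raising (tiny synthetic datasets with high missingness hit this).
    """
    frame = data.frame
    check_cols = SCALE_COLUMNS + ["age"]
    if data.has_utility:
        check_cols = check_cols + [UTILITY_COLUMN]
    if data.has_responses:
        check_cols = check_cols + RESPONSE_COLUMNS
    keep = frame[check_cols].notna().all(axis=1)
    report = DropReport(n_total=len(frame), n_dropped=int((~keep).sum()))
    kept = frame.loc[keep].copy()
    if report.n_total and not len(kept):
        warnings.warn("complete-case filter removed every row", stacklevel=2)
    return (
        MappingDataset(kept, has_utility=data.has_utility,
                       has_responses=data.has_responses),
        report,
    )


#: Canonical design-column names.
COMPONENT_COVARIATES = ["const"] + SCALE_COLUMNS + ["age"]
MEMBERSHIP_COVARIATES = ["const", "global_health", "global_health_sq"]
COMPARATOR_COVARIATES = ["const"] + SCALE_COLUMNS + ["age", "age_sq"]


def build_design_matrices(frame: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Build the three covariate blocks shared by every model.

    * ``component`` — intercept, the 15 scale scores / 100, age in years;
      the within-component design of the mixture model.
    * ``membership`` — intercept, global health / 100 and its square;
      drives the component-membership probabilities.
    * ``comparator`` — the component block plus age squared; used by the
      linear and response-mapping comparators.

    Emits a collinearity warning when a non-intercept column is constant.
    """
    scores = rescale_scores(frame)
    n = len(frame)
    const = pd.Series(np.ones(n), index=frame.index, name="const")
    age = frame["age"].astype(float)

    component = pd.concat([const, scores, age.rename("age")], axis=1)
    component.columns = COMPONENT_COVARIATES

    gh = scores["global_health"]
    membership = pd.DataFrame(
        {"const": const, "global_health": gh, "global_health_sq": gh**2},
        index=frame.index,
    )

    comparator = component.copy()
    comparator["age_sq"] = age**2

    for name, block in (("component", component), ("membership", membership),
                        ("comparator", comparator)):
        nunique = block.iloc[:, 1:].nunique()
        constant_cols = nunique.index[nunique <= 1].tolist()
        if constant_cols and n > 1:
            warnings.warn(
                f"{name} design has constant non-intercept columns: {constant_cols}",
                stacklevel=2,
            )
    return {"component": component, "membership": membership,
            "comparator": comparator}
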