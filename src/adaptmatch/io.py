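"""Subject-table I/O for simulation and trial modes.

Simulated cohorts round-trip through CSV with the canonical header
``id,z,x1,x2,x3,x4,x5,y`` (empty ``y`` allowed).  Trial-mode tables may use
arbitrary column names, declared through a :class:`SubjectSchema`; rows with
missing values in declared matching covariates are excluded at load time
with a logged count (outcomes may be missing — interim analyses run before
outcomes exist in a prospective design).

CSV dialect is pinned: comma separator, '.' decimal, header row required,
UTF-8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import ARM_CONTROL, ARM_TREATED, Cohort

logger = logging.getLogger("adaptmatch")

SIMULATED_COVARIATES = ["x1", "x2", "x3", "x4", "x5"]


@dataclass(frozen=True)
class SubjectSchema:
    """Column declaration for a subject-level CSV table."""

    id_col: str = "id"
    arm_col: str = "z"
    covariate_cols: tuple = tuple(SIMULATED_COVARIATES)
    outcome_col: Optional[str] = "y"


def write_cohort(cohort: Cohort, path: Union[str, Path]) -> None:
    """Write both arms to CSV (canonical column order, id column first)."""
    df = cohort.all_subjects().copy()
    df.insert(0, "id", df.index)
    cols = ["id", "z"] + [c for c in df.columns if c not in ("id", "z")]
    df[cols].to_csv(path, index=False)


def load_subject_table(
    path: Union[str, Path],
    schema: SubjectSchema = SubjectSchema(),
) -> Cohort:
    """Load and validate a subject-level CSV into a :class:`Cohort`.

    Rows with missing values in any declared matching covariate are
    excluded (count logged and stored in ``cohort.meta['n_excluded']``).
    Schema violations raise ``ValueError`` with row/column diagnostics.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = [schema.id_col, schema.arm_col, *schema.covariate_cols]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    if df[schema.id_col].duplicated().any():
        dupes = df[schema.id_col][df[schema.id_col].duplicated()].tolist()[:5]
        raise ValueError(f"{path}: duplicate subject ids, e.g. {dupes}")
    arm = df[schema.arm_col]
    bad_arm = ~arm.isin([ARM_CONTROL, ARM_TREATED])
    if bad_arm.any():
        rows = df.index[bad_arm].tolist()[:5]
        raise ValueError(
            f"{path}: arm column {schema.arm_col!r} must be binary 0/1; "
            f"offending rows (0-based): {rows}"
        )
    for c in schema.covariate_cols:
        if not pd.api.types.is_numeric_dtype(df[c]):
            coerced = pd.to_numeric(df[c], errors="coerce")
            if coerced.isna().sum() > df[c].isna().sum():
                raise ValueError(f"{path}: covariate column {c!r} is not numeric")
            df[c] = coerced

    complete = df[list(schema.covariate_cols)].notna().all(axis=1)
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.info("%s: excluded %d row(s) with missing matching covariates",
                    path, n_excluded)
    df = df[complete]

    df = df.set_index(schema.id_col)
    df.index.name = "id"
    keep = [schema.arm_col, *schema.covariate_cols]
    if schema.outcome_col and schema.outcome_col in df.columns:
        out = df[schema.outcome_col]
        bad_y = out.notna() & ~out.isin([0, 1])
        if bad_y.any():
            raise ValueError(
                f"{path}: outcome column {schema.outcome_col!r} must be "
                "binary 0/1 where present"
            )
        keep.append(schema.outcome_col)
    sub = df[keep].rename(columns={schema.arm_col: "z",
                                   (schema.outcome_col or "y"): "y"})
    controls = sub[sub["z"] == ARM_CONTROL]
    treated = sub[sub["z"] == ARM_TREATED]
    return Cohort(controls=controls, treated=treated,
                  meta={"n_excluded": n_excluded, "source": str(path)})


def load_simulated_cohort(path: Union[str, Path]) -> Cohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    return load_subject_table(path, SubjectSchema())


def write_report(records: Union[dict, Sequence[dict]], path: Union[str, Path]) -> None:
    """Write one or more flat key-value records as a CSV report."""
    if isinstance(records, dict):
        records = [records]
    pd.DataFrame(list(records)).to_csv(path, index=False)
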