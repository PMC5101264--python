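"""Reading and writing long-format longitudinal count tables.

The only accepted layout is long format: one row per subject-visit with a
subject identifier, a 1-based consecutive visit index, a non-negative
integer outcome, and numeric covariate columns.  An intercept column is
prepended on read.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .model import LongitudinalDataset, Subject

__all__ = ["read_long_table", "write_long_table"]


def read_long_table(path, subject_col: str = "subject",
                    visit_col: str = "visit", outcome_col: str = "y",
                    covariate_cols=None, sep: str = ",",
                    add_intercept: bool = True) -> LongitudinalDataset:
    """Parse a delimited long-format file into a LongitudinalDataset.

    Rows are grouped by subject and sorted by visit index; visit indices
    must be consecutive integers starting at 1 with no duplicates or gaps.
    """
    df = pd.read_csv(path, sep=sep)
    required = [subject_col, visit_col, outcome_col]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {missing}")
    if covariate_cols is None:
        covariate_cols = [c for c in df.columns if c not in required]
    else:
        covariate_cols = list(covariate_cols)
        absent = [c for c in covariate_cols if c not in df.columns]
        if absent:
            raise ValidationError(f"covariate column(s) not found: {absent}")

    y_raw = pd.to_numeric(df[outcome_col], errors="coerce")
    if y_raw.isna().any():
        raise ValidationError(f"non-numeric outcome in column "
                              f"'{outcome_col}'")
    if ((y_raw < 0) | (y_raw != np.round(y_raw))).any():
        raise ValidationError(f"outcome column '{outcome_col}' must hold "
                              "non-negative integers")

    subjects = []
    for sid, grp in df.groupby(subject_col, sort=False):
        grp = grp.sort_values(visit_col)
        visits = grp[visit_col].to_numpy()
        if len(np.unique(visits)) != len(visits):
            raise ValidationError(f"subject {sid!r}: duplicated visit index")
        if not np.array_equal(visits, np.arange(1, len(visits) + 1)):
            raise ValidationError(
                f"subject {sid!r}: visit indices must be consecutive "
                f"1-based integers, got {visits.tolist()}")
        X = grp[covariate_cols].to_numpy(dtype=float)
        if add_intercept:
            X = np.column_stack([np.ones(len(grp)), X])
        subjects.append(Subject(y=grp[outcome_col].to_numpy(dtype=float),
                                X=X, subject_id=sid))
    names = (["intercept"] if add_intercept else []) + covariate_cols
    return LongitudinalDataset(subjects, covariate_names=names)


def write_long_table(data: LongitudinalDataset, path,
                     subject_col: str = "subject", visit_col: str = "visit",
                     outcome_col: str = "y", sep: str = ",") -> None:
    """Write a dataset back to delimited long format (intercept column,
    if present as the first all-ones column, is dropped)."""
    names = list(data.covariate_names)
    drop_first = bool(names) and all(
        np.allclose(s.X[:, 0], 1.0) for s in data.subjects)
    rows = []
    for s in data.subjects:
        for j in range(s.n):
            row = {subject_col: s.subject_id, visit_col: j + 1,
                   outcome_col: int(s.y[j])}
            cols = s.X[j, 1:] if drop_first else s.X[j]
            labels = names[1:] if drop_first else names
            row.update(dict(zip(labels, cols)))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
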