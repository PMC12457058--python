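"""Delimited-text readers and writers for cohorts.

A cohort lives in three CSV files inside one directory:

* ``measurements.csv`` — subject_id, variable, time, value (analysis scale)
* ``events.csv``       — subject_id, state, entry_time, exit_time, next_state
  (blank next_state = censored in that state)
* ``baseline.csv``     — subject_id, sex, age_at_gada, fdr, dq_group

Times are decimal years written with full precision so that a write/read
round trip reproduces every numeric field.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import List, Union

import pandas as pd

from .datamodel import (
    LONGITUDINAL_VARIABLES,
    BaselineCovariates,
    Cohort,
    LongitudinalRecord,
    StateRecord,
    Subject,
    validate_cohort,
)

MEASUREMENTS = "measurements.csv"
EVENTS = "events.csv"
BASELINE = "baseline.csv"


class CohortParseError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, cols, fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CohortParseError(f"{fname}: missing columns {missing}")


def write_long_table(cohort: Cohort, path: Union[str, os.PathLike]) -> Path:
    """Write the three cohort CSVs into directory ``path`` (created if needed)."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)

    meas_rows = []
    event_rows = []
    base_rows = []
    for s in cohort:
        base_rows.append(
            {
                "subject_id": s.id,
                "sex": s.baseline.sex,
                "age_at_gada": repr(float(s.baseline.age_at_gada)),
                "fdr": s.baseline.fdr,
                "dq_group": s.baseline.dq_group,
            }
        )
        for r in s.longitudinal:
            meas_rows.append(
                {"subject_id": s.id, "variable": r.variable, "time": repr(float(r.time)), "value": repr(float(r.value))}
            )
        for rec in s.path:
            event_rows.append(
                {
                    "subject_id": s.id,
                    "state": rec.state,
                    "entry_time": repr(float(rec.entry_time)),
                    "exit_time": repr(float(rec.exit_time)),
                    "next_state": "" if rec.next_state is None else rec.next_state,
                }
            )

    pd.DataFrame(meas_rows, columns=["subject_id", "variable", "time", "value"]).to_csv(
        out / MEASUREMENTS, index=False
    )
    pd.DataFrame(
        event_rows, columns=["subject_id", "state", "entry_time", "exit_time", "next_state"]
    ).to_csv(out / EVENTS, index=False)
    pd.DataFrame(
        base_rows, columns=["subject_id", "sex", "age_at_gada", "fdr", "dq_group"]
    ).to_csv(out / BASELINE, index=False)
    return out


def read_long_table(path: Union[str, os.PathLike], validate: bool = True) -> Cohort:
    """Read a cohort from the directory written by :func:`write_long_table`.

    Raises :class:`CohortParseError` (with the offending row number) on unknown
    variable names, non-numeric times/values, or duplicate measurement keys,
    and a ``ValueError`` listing violations when path validation fails.
    """
    d = Path(path)
    meas = pd.read_csv(d / MEASUREMENTS, dtype={"subject_id": str}, float_precision="round_trip")
    events = pd.read_csv(d / EVENTS, dtype={"subject_id": str}, float_precision="round_trip")
    base = pd.read_csv(d / BASELINE, dtype={"subject_id": str}, float_precision="round_trip")

    _require_columns(meas, ["subject_id", "variable", "time", "value"], MEASUREMENTS)
    _require_columns(events, ["subject_id", "state", "entry_time", "exit_time", "next_state"], EVENTS)
    _require_columns(base, ["subject_id", "sex", "age_at_gada", "fdr", "dq_group"], BASELINE)

    bad = ~meas["variable"].isin(LONGITUDINAL_VARIABLES)
    if bad.any():
        row = int(bad.idxmax()) + 2  # header + 1-based
        raise CohortParseError(
            f"{MEASUREMENTS} row {row}: unknown variable {meas.loc[bad.idxmax(), 'variable']!r}"
        )
    for col in ("time", "value"):
        coerced = pd.to_numeric(meas[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax()) + 2
            raise CohortParseError(f"{MEASUREMENTS} row {row}: non-numeric {col}")
        meas[col] = coerced
    dup = meas.duplicated(subset=["subject_id", "variable", "time"])
    if dup.any():
        row = int(dup.idxmax()) + 2
        raise CohortParseError(f"{MEASUREMENTS} row {row}: duplicate (subject, variable, time)")

    for col in ("entry_time", "exit_time"):
        coerced = pd.to_numeric(events[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax()) + 2
            raise CohortParseError(f"{EVENTS} row {row}: non-numeric {col}")
        events[col] = coerced

    subjects: List[Subject] = []
    for _, brow in base.iterrows():
        sid = str(brow["subject_id"])
        bc = BaselineCovariates(
            sex=str(brow["sex"]),
            age_at_gada=float(brow["age_at_gada"]),
            fdr=int(brow["fdr"]),
            dq_group=str(brow["dq_group"]),
        )
        recs = [
            LongitudinalRecord(variable=r.variable, time=float(r.time), value=float(r.value))
            for r in meas[meas["subject_id"] == sid].itertuples()
        ]
        path_rows = events[events["subject_id"] == sid].sort_values("entry_time")
        path = []
        for r in path_rows.itertuples():
            ns = r.next_state
            next_state = None if (pd.isna(ns) or str(ns).strip() == "") else int(float(ns))
            path.append(
                StateRecord(
                    state=int(r.state),
                    entry_time=float(r.entry_time),
                    exit_time=float(r.exit_time),
                    next_state=next_state,
                )
            )
        subjects.append(Subject(id=sid, baseline=bc, longitudinal=recs, path=path))

    cohort = Cohort(subjects=subjects, metadata={"source": str(d)})
    if validate:
        issues = validate_cohort(cohort)
        if issues:
            msg = "; ".join(str(i) for i in issues[:10])
            raise CohortParseError(f"cohort validation failed ({len(issues)} issues): {msg}")
    return cohort
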