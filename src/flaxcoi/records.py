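"""Person-level microdata records shared by every pipeline stage.

The canonical in-memory container is a :class:`pandas.DataFrame` with the
columns in :data:`MICRODATA_COLUMNS`; :class:`IndividualRecord` is the
row-level view used for single-record operations and for building small
populations by hand in tests and examples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MICRODATA_COLUMNS = (
    "person_id",
    "age_years",
    "sex",
    "sbp",
    "dbp",
    "on_medication",
    "weight",
)

SEX_VALUES = ("M", "F")

# Physiological plausibility windows for clinic blood-pressure readings (mm Hg).
SBP_RANGE = (60.0, 260.0)
DBP_RANGE = (30.0, 160.0)

MIN_AGE = 18

#: Age bands used for cost attribution and grouped summaries.  The last band
#: is open-ended: seniors 75 and older.
DEFAULT_AGE_BANDS: tuple[tuple[int, int | None, str], ...] = (
    (18, 44, "18-44"),
    (45, 54, "45-54"),
    (55, 64, "55-64"),
    (65, 74, "65-74"),
    (75, None, "75+"),
)


@dataclass(frozen=True)
class IndividualRecord:
    """One adult survey respondent with clinic BP measurements.

    Parameters
    ----------
    person_id : str
        Opaque respondent identifier.
    age_years : int
        Age at clinic visit, 18 or older.
    sex : str
        ``"M"`` or ``"F"``.
    sbp, dbp : float
        Systolic / diastolic blood pressure in mm Hg.
    on_medication : bool
        Self-reported current use of anti-hypertensive medication.
    weight : float
        Positive survey weight: the number of population members this
        respondent represents.
    """

    person_id: str
    age_years: int
    sex: str
    sbp: float
    dbp: float
    on_medication: bool
    weight: float

    def __post_init__(self) -> None:
        problems = record_problems(
            self.age_years, self.sex, self.sbp, self.dbp, self.weight
        )
        if problems:
            field, msg = problems[0]
            raise ValueError(f"invalid record {self.person_id!r}: {field}: {msg}")


def record_problems(
    age_years: float, sex: str, sbp: float, dbp: float, weight: float
) -> list[tuple[str, str]]:
    """Return ``(field, message)`` pairs for every violated invariant."""
    out: list[tuple[str, str]] = []
    if not np.isfinite(age_years) or age_years < MIN_AGE or age_years != int(age_years):
        out.append(("age_years", f"must be an integer >= {MIN_AGE}, got {age_years!r}"))
    if sex not in SEX_VALUES:
        out.append(("sex", f"must be one of {SEX_VALUES}, got {sex!r}"))
    if not np.isfinite(sbp) or not (SBP_RANGE[0] <= sbp <= SBP_RANGE[1]):
        out.append(("sbp", f"must be in {SBP_RANGE} mm Hg, got {sbp!r}"))
    if not np.isfinite(dbp) or not (DBP_RANGE[0] <= dbp <= DBP_RANGE[1]):
        out.append(("dbp", f"must be in {DBP_RANGE} mm Hg, got {dbp!r}"))
    if np.isfinite(sbp) and np.isfinite(dbp) and dbp >= sbp:
        out.append(("dbp", f"diastolic ({dbp}) must be below systolic ({sbp})"))
    if not np.isfinite(weight) or weight <= 0:
        out.append(("weight", f"survey weight must be > 0, got {weight!r}"))
    return out


def to_frame(records: "pd.DataFrame | Iterable[IndividualRecord]") -> pd.DataFrame:
    """Normalise a record collection to the canonical microdata DataFrame."""
    if isinstance(records, pd.DataFrame):
        missing = [c for c in MICRODATA_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"microdata frame missing columns: {missing}")
        return records
    rows = list(records)
    if rows and not isinstance(rows[0], IndividualRecord):
        raise TypeError(f"expected IndividualRecord rows, got {type(rows[0])!r}")
    return pd.DataFrame(
        {name: [getattr(r, name) for r in rows] for name in MICRODATA_COLUMNS}
    )


def frame_to_records(df: pd.DataFrame) -> list[IndividualRecord]:
    return [
        IndividualRecord(
            person_id=str(row.person_id),
            age_years=int(row.age_years),
            sex=str(row.sex),
            sbp=float(row.sbp),
            dbp=float(row.dbp),
            on_medication=bool(row.on_medication),
            weight=float(row.weight),
        )
        for row in df.itertuples(index=False)
    ]


def assign_age_band(
    ages: Sequence[float] | np.ndarray,
    bands: tuple[tuple[int, int | None, str], ...] = DEFAULT_AGE_BANDS,
) -> np.ndarray:
    """Map ages to band labels; raises if any age falls outside all bands."""
    ages = np.asarray(ages)
    labels = np.full(ages.shape, "", dtype=object)
    for low, high, label in bands:
        mask = (ages >= low) if high is None else ((ages >= low) & (ages <= high))
        labels[mask] = label
    uncovered = labels == ""
    if uncovered.any():
        bad = np.unique(ages[uncovered])
        raise ValueError(f"ages outside all age bands: {bad.tolist()}")
    return labels
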