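"""Readers, writers, validation and small shared helpers.

All files are plain text with a pinned CSV dialect (comma separator,
"." decimal, UTF-8, Unix newlines) so cost figures cannot drift with
locale.  Money is carried as real CAD and rounded only for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coi_engine import CostTable
from .monte_carlo import ScenarioConfig
from .records import MICRODATA_COLUMNS, record_problems
from .synthetic_population import PopulationModel

logger = logging.getLogger("flaxcoi")

__all__ = [
    "ValidationReport",
    "read_microdata",
    "write_microdata",
    "read_cost_table",
    "write_cost_table",
    "read_scenario_config",
    "write_scenario_config",
    "read_population_model",
    "write_population_model",
    "percent_excess",
]


@dataclass
class ValidationReport:
    """Outcome of validating a microdata file row by row."""

    n_read: int
    n_rejected: int
    reasons: list[tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_rejected > self.n_read:
            raise ValueError("n_rejected cannot exceed n_read")


def read_microdata(path: str | Path, strict: bool = False) -> tuple[pd.DataFrame, ValidationReport]:
    """Read person-level microdata CSV, rejecting invalid rows.

    Rows violating any record invariant (age < 18, BP out of range,
    diastolic >= systolic, non-positive weight, missing values, bad
    codes) are dropped and reported; ``strict=True`` raises instead.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"person_id": str, "sex": str}, encoding="utf-8")
    expected = list(MICRODATA_COLUMNS)
    if list(df.columns) != expected:
        raise ValueError(
            f"unexpected microdata header {list(df.columns)}; expected {expected}"
        )
    reasons: list[tuple[int, str, str]] = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        row_problems: list[tuple[str, str]] = []
        for name in expected:
            v = getattr(row, name)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                row_problems.append((name, "missing value"))
        if not row_problems:
            if row.on_medication not in (0, 1, True, False):
                row_problems.append(("on_medication", f"must be 0/1, got {row.on_medication!r}"))
            row_problems.extend(
                record_problems(row.age_years, row.sex, row.sbp, row.dbp, row.weight)
            )
        if row_problems:
            keep[i] = False
            reasons.extend((i, f, m) for f, m in row_problems)
    report = ValidationReport(n_read=len(df), n_rejected=int((~keep).sum()), reasons=reasons)
    if report.n_rejected:
        logger.warning("rejected %d/%d microdata rows", report.n_rejected, report.n_read)
        if strict:
            raise ValueError(
                f"strict read: {report.n_rejected} invalid rows, first: {reasons[0]}"
            )
    out = df[keep].reset_index(drop=True)
    out["age_years"] = out["age_years"].astype(int)
    out["on_medication"] = out["on_medication"].astype(bool)
    return out, report


def write_microdata(df: pd.DataFrame, path: str | Path) -> None:
    """Write microdata CSV in the pinned dialect (on_medication as 0/1)."""
    out = df[list(MICRODATA_COLUMNS)].copy()
    out["on_medication"] = out["on_medication"].astype(int)
    out.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def read_cost_table(path: str | Path) -> CostTable:
    """Read an age-band cost CSV: age_low, age_high (empty = open), annual_cost_cad."""
    df = pd.read_csv(path, encoding="utf-8")
    expected = ["age_low", "age_high", "annual_cost_cad"]
    if list(df.columns) != expected:
        raise ValueError(f"unexpected cost-table header {list(df.columns)}; expected {expected}")
    bands = tuple(
        (
            int(r.age_low),
            None if pd.isna(r.age_high) else int(r.age_high),
            float(r.annual_cost_cad),
        )
        for r in df.itertuples(index=False)
    )
    return CostTable(bands=bands)


def write_cost_table(table: CostTable, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"age_low": lo, "age_high": "" if hi is None else hi, "annual_cost_cad": cost}
            for lo, hi, cost in table.bands
        ]
    ).to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def read_scenario_config(path: str | Path) -> ScenarioConfig:
    with open(path, encoding="utf-8") as fh:
        return ScenarioConfig.from_dict(yaml.safe_load(fh))


def write_scenario_config(config: ScenarioConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def read_population_model(path: str | Path) -> PopulationModel:
    with open(path, encoding="utf-8") as fh:
        return PopulationModel.from_dict(yaml.safe_load(fh))


def write_population_model(model: PopulationModel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=False)


def percent_excess(a: float, b: float) -> float:
    """How much larger ``a`` is than ``b``, in percent, to 2 decimals.

    Used e.g. to express one jurisdiction's per-capita spending relative
    to the national figure.
    """
    if b <= 0:
        raise ValueError(f"reference value must be > 0, got {b}")
    return round(100.0 * (a - b) / b, 2)
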