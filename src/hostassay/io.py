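"""Reading and writing assay tables and derived outputs.

Tables are UTF-8 CSV with a required header and empty fields for
missing values; XLSX input is auto-detected by extension.  Deposited
files with different column headers are handled through an alias map
rather than code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["COLUMNS", "ValidationReport", "read_assay_table",
           "write_assay_table"]

#: canonical column order; ``brood`` is optional on input
COLUMNS = [
    "id",
    "population",
    "host",
    "culture",
    "brood",
    "sex",
    "survived",
    "pupal_mass_mg",
    "dev_time_days",
]

_REQUIRED = [c for c in COLUMNS if c != "brood"]


@dataclass
class ValidationReport:
    """Row-level validation outcome of one table read."""

    n_rows: int
    n_flagged: int = 0
    messages: list = field(default_factory=list)

    def flag(self, msg: str) -> None:
        self.n_flagged += 1
        self.messages.append(msg)


def write_assay_table(table: pd.DataFrame, path) -> None:
    """Write a table with canonical column order; missing values empty."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False)


def read_assay_table(path, aliases: dict | None = None):
    """Read and validate an assay table.

    Parameters
    ----------
    path
        CSV or XLSX file (chosen by extension).
    aliases
        Optional map from the file's column names to canonical names,
        e.g. ``{"Population": "population"}``.

    Returns
    -------
    (DataFrame, ValidationReport)
        Validated records plus a report of flagged rows.  Survivors with
        missing mass or development time are flagged but retained (they
        still inform the survival model); non-survivors with recorded
        mass/time have those values blanked and are flagged.  Non-binary
        survival codes are a hard error naming the row.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if aliases:
        df = df.rename(columns=aliases)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"table {path} is missing required columns {missing}")

    report = ValidationReport(n_rows=len(df))
    surv = pd.to_numeric(df["survived"], errors="coerce")
    bad = df.index[~surv.isin([0, 1]) | surv.isna()]
    if len(bad):
        raise ValueError(
            f"non-binary survival value in row(s) {list(bad[:5])} of {path}"
        )
    df["survived"] = surv.astype(int)
    for col in ("pupal_mass_mg", "dev_time_days"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    alive = df["survived"] == 1
    for col in ("pupal_mass_mg", "dev_time_days"):
        holes = df.index[alive & df[col].isna()]
        for i in holes:
            report.flag(f"row {i}: survivor missing {col}; excluded from "
                        f"that response's model")
        ghost = df.index[~alive & df[col].notna()]
        for i in ghost:
            report.flag(f"row {i}: non-survivor with recorded {col}; blanked")
        df.loc[ghost, col] = np.nan
    ghost_sex = df.index[~alive & df["sex"].notna()]
    for i in ghost_sex:
        report.flag(f"row {i}: non-survivor with recorded sex; blanked")
    df.loc[ghost_sex, "sex"] = np.nan

    nonpos = df.index[(df["pupal_mass_mg"] <= 0) | (df["dev_time_days"] <= 0)]
    if len(nonpos):
        raise ValueError(
            f"non-positive mass or development time in row(s) "
            f"{list(nonpos[:5])} of {path}"
        )
    return df, report
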