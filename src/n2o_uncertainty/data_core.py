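"""Measurement table I/O, exclusion filtering and summary statistics.

The unit of observation is one field measurement of annual N2O emission:
publication id, applied-N dose (kg N ha-1), replicate index and the measured
emission (kg N2O-N ha-1 yr-1), plus the metadata needed to decide whether a
record belongs in an emission-factor analysis of fertilized agricultural
mineral soils (land use, soil class, gas measured, nitrification inhibitors,
grazing).

Six exclusion criteria are applied, in a fixed order so the audit attributes
each dropped record to the first criterion it violates:

(i) natural (non-agricultural) areas, (ii) NO-only measurements,
(iii) organic soils, (iv) nitrification inhibitors, (v) grazing systems,
(vi) doses exceeding 500 kg N ha-1 yr-1 (strictly; 500 itself is retained).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EmissionRecord",
    "FilterAudit",
    "SchemaError",
    "EmptyInputError",
    "CANONICAL_COLUMNS",
    "REQUIRED_COLUMNS",
    "EXCLUSION_CRITERIA",
    "read_emission_table",
    "write_emission_table",
    "records_to_frame",
    "frame_to_records",
    "apply_exclusion_filters",
    "summarize",
]

#: Canonical CSV schema (comma-delimited, UTF-8, header row; booleans as 0/1).
CANONICAL_COLUMNS: tuple[str, ...] = (
    "publication_id",
    "n_rate_kg_ha",
    "n2o_kg_n_ha_yr",
    "replicate",
    "land_use",
    "soil_class",
    "gas_measured",
    "inhibitor",
    "grazing",
    "continent",
    "climate",
)

REQUIRED_COLUMNS: tuple[str, ...] = (
    "publication_id",
    "n_rate_kg_ha",
    "n2o_kg_n_ha_yr",
)

MAX_DOSE = 500.0  # kg N ha-1 yr-1; records strictly above are excluded


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class EmptyInputError(ValueError):
    """The input table holds no data rows."""


@dataclass
class EmissionRecord:
    """One field measurement of N2O emission."""

    publication_id: str
    dose: float
    n2o: float
    replicate: int = 1
    land_use: str = "agricultural"
    soil_class: str = "mineral"
    gas_measured: str = "N2O"
    inhibitor: bool = False
    grazing: bool = False
    continent: str | None = None
    climate: str | None = None

    def __post_init__(self) -> None:
        if not self.publication_id:
            raise ValueError("publication_id must be non-empty")
        if self.dose < 0:
            raise ValueError("dose must be nonnegative")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        if self.land_use not in ("agricultural", "natural"):
            raise ValueError(f"unknown land_use {self.land_use!r}")
        if self.soil_class not in ("mineral", "organic"):
            raise ValueError(f"unknown soil_class {self.soil_class!r}")
        if self.gas_measured not in ("N2O", "NO", "both"):
            raise ValueError(f"unknown gas_measured {self.gas_measured!r}")


#: (criterion key, human-readable description, predicate on a record).
EXCLUSION_CRITERIA: tuple[tuple[str, str], ...] = (
    ("natural_area", "experiment in a natural (non-agricultural) area"),
    ("no_only", "NO emission measured only"),
    ("organic_soil", "organic soil"),
    ("inhibitor", "nitrification inhibitor applied"),
    ("grazing", "grazing system"),
    ("dose_above_500", f"applied N exceeds {MAX_DOSE:g} kg N ha-1 yr-1"),
)

_PREDICATES = {
    "natural_area": lambda r: r.land_use != "agricultural",
    "no_only": lambda r: r.gas_measured == "NO",
    "organic_soil": lambda r: r.soil_class != "mineral",
    "inhibitor": lambda r: r.inhibitor,
    "grazing": lambda r: r.grazing,
    "dose_above_500": lambda r: r.dose > MAX_DOSE,
}


@dataclass
class FilterAudit:
    """Bookkeeping of the exclusion filters.

    ``excluded`` counts records by the *first* criterion they violated, in
    the canonical order, so the counts plus ``records_retained`` always sum
    to the input size.
    """

    n_input: int = 0
    excluded: dict[str, int] = field(
        default_factory=lambda: {key: 0 for key, _ in EXCLUSION_CRITERIA}
    )
    records_retained: int = 0
    publications_retained: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _coerce_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, float, np.integer, np.floating)):
        return bool(int(value))
    s = str(value).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no", "", "nan"):
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean flag")


def read_emission_table(
    path: str | Path, schema: dict[str, str] | None = None
) -> list[EmissionRecord]:
    """Read a delimiter-separated measurement table.

    Parameters
    ----------
    path:
        CSV file with a header row.
    schema:
        Optional mapping from canonical column names to the names actually
        used in the file, e.g. ``{"n_rate_kg_ha": "N_rate"}``.

    Rows whose dose or emission cannot be parsed as numbers are skipped with
    a logged warning — they are reported, never silently dropped.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data found") from None
    if schema:
        rename = {file_col: canon for canon, file_col in schema.items()}
        frame = frame.rename(columns=rename)
    for col in REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"{path}: required column {col!r} is missing")
    if len(frame) == 0:
        raise EmptyInputError(f"{path}: table has a header but no rows")

    records: list[EmissionRecord] = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        row_d = dict(zip(frame.columns, row))
        dose = pd.to_numeric(row_d["n_rate_kg_ha"], errors="coerce")
        n2o = pd.to_numeric(row_d["n2o_kg_n_ha_yr"], errors="coerce")
        if pd.isna(dose) or pd.isna(n2o):
            logger.warning(
                "%s line %d: unparseable dose=%r or n2o=%r; row skipped",
                path.name,
                row_number,
                row_d["n_rate_kg_ha"],
                row_d["n2o_kg_n_ha_yr"],
            )
            continue

        def _opt(col, default):
            val = row_d.get(col)
            if val is None or (isinstance(val, float) and np.isnan(val)) or pd.isna(val):
                return default
            return val

        records.append(
            EmissionRecord(
                publication_id=str(row_d["publication_id"]),
                dose=float(dose),
                n2o=float(n2o),
                replicate=int(float(_opt("replicate", 1))),
                land_use=str(_opt("land_use", "agricultural")),
                soil_class=str(_opt("soil_class", "mineral")),
                gas_measured=str(_opt("gas_measured", "N2O")),
                inhibitor=_coerce_bool(_opt("inhibitor", False)),
                grazing=_coerce_bool(_opt("grazing", False)),
                continent=_opt("continent", None),
                climate=_opt("climate", None),
            )
        )
    return records


def records_to_frame(records: Iterable[EmissionRecord]) -> pd.DataFrame:
    """Records as a DataFrame with canonical column names."""
    rows = [
        {
            "publication_id": r.publication_id,
            "n_rate_kg_ha": r.dose,
            "n2o_kg_n_ha_yr": r.n2o,
            "replicate": r.replicate,
            "land_use": r.land_use,
            "soil_class": r.soil_class,
            "gas_measured": r.gas_measured,
            "inhibitor": int(r.inhibitor),
            "grazing": int(r.grazing),
            "continent": r.continent,
            "climate": r.climate,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def frame_to_records(frame: pd.DataFrame) -> list[EmissionRecord]:
    """Inverse of :func:`records_to_frame` for an in-memory table."""
    records = []
    for row in frame.itertuples(index=False):
        d = dict(zip(frame.columns, row))
        records.append(
            EmissionRecord(
                publication_id=str(d["publication_id"]),
                dose=float(d["n_rate_kg_ha"]),
                n2o=float(d["n2o_kg_n_ha_yr"]),
                replicate=int(d.get("replicate", 1)),
                land_use=str(d.get("land_use", "agricultural")),
                soil_class=str(d.get("soil_class", "mineral")),
                gas_measured=str(d.get("gas_measured", "N2O")),
                inhibitor=_coerce_bool(d.get("inhibitor", False)),
                grazing=_coerce_bool(d.get("grazing", False)),
                continent=None if pd.isna(d.get("continent")) else d.get("continent"),
                climate=None if pd.isna(d.get("climate")) else d.get("climate"),
            )
        )
    return records


def write_emission_table(records: Iterable[EmissionRecord], path: str | Path) -> None:
    """Write records to the canonical CSV schema."""
    records_to_frame(records).to_csv(path, index=False)


def apply_exclusion_filters(
    records: Sequence[EmissionRecord],
) -> tuple[list[EmissionRecord], FilterAudit]:
    """Apply the six exclusion criteria in canonical order.

    Returns the retained records (original order preserved) and a
    :class:`FilterAudit`.  An empty result is legal; the audit shows why.
    """
    audit = FilterAudit(n_input=len(records))
    kept: list[EmissionRecord] = []
    for record in records:
        for key, _desc in EXCLUSION_CRITERIA:
            if _PREDICATES[key](record):
                audit.excluded[key] += 1
                break
        else:
            kept.append(record)
    audit.records_retained = len(kept)
    audit.publications_retained = len({r.publication_id for r in kept})
    return kept, audit


_SUMMARY_VARIABLES = {"n2o": "n2o_kg_n_ha_yr", "dose": "n_rate_kg_ha"}


def summarize(
    records: Sequence[EmissionRecord], group_by: str | None = None
) -> pd.DataFrame:
    """Min / median / mean / max / n of emission and dose, optionally grouped.

    ``group_by`` may name any categorical record field (e.g. ``"continent"``).
    Without grouping a single ``"world"`` group is reported.
    """
    frame = records_to_frame(records)
    if group_by is not None:
        if group_by not in CANONICAL_COLUMNS:
            raise ValueError(f"unknown grouping field {group_by!r}")
        groups = frame.groupby(group_by, dropna=True, sort=True)
        items = [(name, sub) for name, sub in groups]
    else:
        items = [("world", frame)]

    rows = []
    for variable, column in _SUMMARY_VARIABLES.items():
        for name, sub in items:
            values = sub[column].astype(float)
            rows.append(
                {
                    "variable": variable,
                    "group": name,
                    "min": values.min(),
                    "median": values.median(),
                    "mean": values.mean(),
                    "max": values.max(),
                    "n": len(values),
                }
            )
    return pd.DataFrame(rows, columns=["variable", "group", "min", "median", "mean", "max", "n"])
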