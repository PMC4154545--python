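"""Readers and writers for the pipeline's file formats.

CSV conventions: one header row, UTF-8, ``#`` lines are comments (generated
files carry their RNG seed there), and an empty cell means "not reported",
which is distinct from 0. Incidence files may contain one row whose site is
``all cancers``; it carries the all-sites total, which can exceed the sum of
the listed sites.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .errors import FormatError
from .types import (
    ALL_CANCERS_LABEL,
    AvailabilityInventory,
    CapacityNorms,
    DemandOverrides,
    EQUIPMENT_CATEGORIES,
    Geography,
    IncidenceRecord,
    IncidenceTable,
    TreatmentFractionRecord,
)

PathLike = Union[str, Path]

_INCIDENCE_COLUMNS = ["site", "cases_both", "cases_men", "cases_women"]
_FRACTION_COLUMNS = [
    "site", "level", "pct_surgery", "alos_surgery",
    "pct_chemo", "alos_chemo", "pct_rt", "alos_rt",
]


def _require_columns(df: pd.DataFrame, required: list[str], path: PathLike) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def _opt_int(value) -> Optional[int]:
    return None if pd.isna(value) else int(value)


def read_incidence_csv(path: PathLike, geography: Geography, year: int) -> IncidenceTable:
    df = pd.read_csv(path, comment="#", dtype={"site": str})
    _require_columns(df, _INCIDENCE_COLUMNS[:2], path)
    if df["site"].isna().any():
        raise FormatError(f"{path}: record with missing site label")
    records, total = [], None
    for _, row in df.iterrows():
        men = _opt_int(row.get("cases_men"))
        women = _opt_int(row.get("cases_women"))
        if row["site"].strip().lower() == ALL_CANCERS_LABEL:
            total = int(row["cases_both"])
            continue
        records.append(
            IncidenceRecord(
                site=row["site"].strip(),
                cases_both=int(row["cases_both"]),
                cases_men=men,
                cases_women=women,
            )
        )
    if total is None:
        total = sum(r.cases_both for r in records)
    return IncidenceTable(geography=geography, year=year, records=records, total_all_cancers=total)


def write_incidence_csv(
    table: IncidenceTable, path: PathLike, header_comment: Optional[str] = None
) -> None:
    rows = [
        {
            "site": ALL_CANCERS_LABEL,
            "cases_both": table.total_all_cancers,
            "cases_men": None,
            "cases_women": None,
        }
    ]
    rows += [r.model_dump() for r in table.records]
    _write_csv(pd.DataFrame(rows, columns=_INCIDENCE_COLUMNS), path, header_comment)


def read_fractions_csv(path: PathLike) -> list[TreatmentFractionRecord]:
    df = pd.read_csv(path, comment="#", dtype={"site": str, "level": str})
    _require_columns(df, _FRACTION_COLUMNS, path)
    return [TreatmentFractionRecord(**row) for row in df.to_dict("records")]


def write_fractions_csv(
    records: list[TreatmentFractionRecord], path: PathLike,
    header_comment: Optional[str] = None,
) -> None:
    df = pd.DataFrame([r.model_dump() for r in records], columns=_FRACTION_COLUMNS)
    _write_csv(df, path, header_comment)


def read_inventory_csv(path: PathLike) -> dict[str, AvailabilityInventory]:
    """Inventories keyed by geography name.

    Columns: geography, category, count, flag (optional). A ``nonexistent``
    flag marks a category with no local specialization (count 0 by
    definition); a ``merged-from:<label>`` flag records merge provenance.
    """
    df = pd.read_csv(path, comment="#", dtype={"geography": str, "category": str, "flag": str})
    _require_columns(df, ["geography", "category", "count"], path)
    out: dict[str, AvailabilityInventory] = {}
    for geo, group in df.groupby("geography", sort=False):
        staff: dict[str, int] = {}
        equipment: dict[str, int] = {}
        beds = 0
        nonexistent: set[str] = set()
        merged: dict[str, list[str]] = {}
        for _, row in group.iterrows():
            category, count = row["category"].strip(), int(row["count"])
            flag = None if pd.isna(row.get("flag")) else str(row["flag"]).strip()
            if category == "beds":
                beds = count
            elif category in EQUIPMENT_CATEGORIES:
                equipment[category] = count
            else:
                staff[category] = count
            if flag == "nonexistent":
                nonexistent.add(category)
            elif flag and flag.startswith("merged-from:"):
                merged.setdefault(category, []).append(flag.split(":", 1)[1])
        out[str(geo)] = AvailabilityInventory(
            geography=str(geo),
            staff_available=staff,
            beds_available=beds,
            equipment_available=equipment,
            categories_nonexistent=nonexistent,
            merged_from=merged,
        )
    return out


def write_inventory_csv(
    inventories: dict[str, AvailabilityInventory], path: PathLike,
    header_comment: Optional[str] = None,
) -> None:
    rows = []
    for geo, inv in inventories.items():
        for category, count in inv.staff_available.items():
            flag = "nonexistent" if category in inv.categories_nonexistent else None
            rows.append((geo, category, count, flag))
        rows.append((geo, "beds", inv.beds_available, None))
        for category, count in inv.equipment_available.items():
            rows.append((geo, category, count, None))
    df = pd.DataFrame(rows, columns=["geography", "category", "count", "flag"])
    _write_csv(df, path, header_comment)


def _write_csv(df: pd.DataFrame, path: PathLike, header_comment: Optional[str]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def _load_mapping(path: PathLike) -> dict:
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def read_norms(path: PathLike) -> CapacityNorms:
    """Norms from YAML/JSON; omitted fields keep their defaults."""
    return CapacityNorms(**_load_mapping(path))


def read_overrides(path: PathLike) -> DemandOverrides:
    return DemandOverrides(**_load_mapping(path))


def read_geographies(path: PathLike) -> list[Geography]:
    data = _load_mapping(path)
    items = data.get("geographies", data) if isinstance(data, dict) else data
    return [Geography(**item) for item in items]


def write_geographies(geographies: list[Geography], path: PathLike) -> None:
    payload = {"geographies": [g.model_dump() for g in geographies]}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")


def read_site_groups(path: PathLike) -> dict[str, str]:
    """Explicit subtype → group site-label mapping."""
    df = pd.read_csv(path, comment="#", dtype=str)
    _require_columns(df, ["subtype", "group"], path)
    return {row["subtype"].strip().lower(): row["group"].strip() for _, row in df.iterrows()}


# ---------------------------------------------------------------------------
# packaged reference data

def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("oncocap").joinpath("data", name))


def default_fractions() -> list[TreatmentFractionRecord]:
    """Packaged canonical per-site treatment fractions and lengths of stay."""
    return read_fractions_csv(_data_path("treatment_fractions.csv"))


def default_norms() -> CapacityNorms:
    return read_norms(_data_path("default_norms.yaml"))


def default_site_groups() -> dict[str, str]:
    return read_site_groups(_data_path("site_groups.csv"))


def up_incidence() -> IncidenceTable:
    """Estimated 2008 incidence for Uttar Pradesh (most common sites)."""
    geo = Geography(name="UP", population=200_000_000, level="state", parent="India")
    return read_incidence_csv(_data_path("up_incidence_2008.csv"), geo, 2008)


def up_availability() -> AvailabilityInventory:
    """2013 survey inventory of cancer-control resources in Uttar Pradesh."""
    return read_inventory_csv(_data_path("up_availability_2013.csv"))["UP"]


def up_overrides() -> DemandOverrides:
    """Published state-level modality totals and bed requirement."""
    return read_overrides(_data_path("up_overrides_2008.yaml"))
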