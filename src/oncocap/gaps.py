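"""Needed-vs-available gap analysis and report rendering.

For every category, shortage = max(0, needed − available) and surplus =
max(0, available − needed); the two never coexist and their difference is
exactly needed − available. A surplus in one geography never offsets a
shortage elsewhere — gaps are computed per geography and per category.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from typing import Optional

from pydantic import BaseModel

from .errors import DomainError
from .types import (
    AvailabilityInventory,
    EQUIPMENT_CATEGORIES,
    GapReport,
    GapRow,
    RequirementSummary,
)

logger = logging.getLogger(__name__)

BEDS_CATEGORY = "beds"

REPORT_COLUMNS = ("geography", "category", "needed", "available", "shortage", "surplus")

#: footnote markers used in the text-table rendering
FLOOR_MARK = "^a"  # raised to the city minimum
NONEXISTENT_MARK = "^b"  # no such specialization exists locally


class MergeRule(BaseModel):
    """Fold availability counts of source categories into a target category."""

    sources: list[str]
    into: str


def merge_available_categories(
    inventory: AvailabilityInventory, merges: list[MergeRule]
) -> AvailabilityInventory:
    """Sum the counts of merged categories under the target label.

    Typical use: a locally recognized specialty whose practice is in scope
    (e.g. gastro-surgeons doing mostly gastrointestinal cancer surgery)
    counted toward the corresponding oncology category. Provenance of each
    merge is recorded on the inventory and surfaced in reports.
    """
    staff = dict(inventory.staff_available)
    merged_from = {k: list(v) for k, v in inventory.merged_from.items()}
    for rule in merges:
        if rule.into not in staff:
            logger.warning(
                "merge target %r did not exist in %s inventory; creating it",
                rule.into, inventory.geography,
            )
            staff[rule.into] = 0
        for source in rule.sources:
            if source not in staff:
                raise DomainError(
                    f"cannot merge unknown category {source!r} in "
                    f"{inventory.geography} inventory"
                )
            staff[rule.into] += staff.pop(source)
            merged_from.setdefault(rule.into, []).append(source)
    return inventory.model_copy(
        update={"staff_available": staff, "merged_from": merged_from}
    )


def compute_gaps(
    required: RequirementSummary, available: AvailabilityInventory
) -> GapReport:
    """Category-wise needed / available / shortage / surplus for one geography.

    Categories present on only one side appear with the other side 0 and a
    warning logged — never dropped.
    """
    if required.geography != available.geography:
        raise DomainError(
            f"geography mismatch: requirements for {required.geography!r}, "
            f"inventory for {available.geography!r}"
        )
    rows: list[GapRow] = []

    def add(category: str, needed: int, avail: int) -> None:
        rows.append(
            GapRow.from_counts(
                category,
                needed,
                avail,
                needed_floored=category in required.floored,
                available_nonexistent=category in available.categories_nonexistent,
            )
        )

    for category in _ordered_union(required.staff, available.staff_available):
        needed = required.staff.get(category)
        avail = available.staff_available.get(category)
        if needed is None:
            logger.warning(
                "category %r present only in the %s availability inventory",
                category, available.geography,
            )
        elif avail is None and category not in available.categories_nonexistent:
            logger.warning(
                "category %r has no availability entry for %s; assuming 0",
                category, available.geography,
            )
        add(category, needed or 0, avail or 0)

    add(BEDS_CATEGORY, required.beds, available.beds_available)

    for category in _ordered_union(required.equipment, available.equipment_available):
        add(
            category,
            required.equipment.get(category, 0),
            available.equipment_available.get(category, 0),
        )
    return GapReport(geography=required.geography, rows=rows)


def _ordered_union(primary: dict, secondary: dict) -> list[str]:
    seen = list(primary)
    seen += [k for k in sorted(secondary) if k not in primary]
    return seen


def render_report(reports: list[GapReport], format: str = "csv") -> str:
    """Serialize gap reports deterministically as csv, json, or a text table."""
    if not reports:
        raise DomainError("no gap reports to render")
    if format == "csv":
        return _render_csv(reports)
    if format == "json":
        return _render_json(reports)
    if format == "text":
        return _render_text(reports)
    raise DomainError(f"unknown report format {format!r} (expected csv, json, or text)")


def _render_csv(reports: list[GapReport]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(REPORT_COLUMNS)
    for report in reports:
        for row in report.rows:
            writer.writerow(
                [report.geography, row.category, row.needed, row.available,
                 row.shortage, row.surplus]
            )
    return buf.getvalue()


def _render_json(reports: list[GapReport]) -> str:
    payload = [
        {
            "geography": report.geography,
            "rows": [row.model_dump() for row in report.rows],
        }
        for report in reports
    ]
    return json.dumps(payload, indent=2, sort_keys=False) + "\n"


def _render_text(reports: list[GapReport]) -> str:
    lines = []
    header = ("category", "needed", "available", "shortage", "surplus")
    for report in reports:
        cells = []
        for row in report.rows:
            needed = f"{row.needed}{FLOOR_MARK if row.needed_floored else ''}"
            avail = f"{row.available}{NONEXISTENT_MARK if row.available_nonexistent else ''}"
            cells.append((row.category, needed, avail, str(row.shortage), str(row.surplus)))
        widths = [max(len(h), *(len(c[i]) for c in cells)) for i, h in enumerate(header)]
        lines.append(f"== {report.geography} ==")
        lines.append("  ".join(h.ljust(w) for h, w in zip(header, widths)))
        for c in cells:
            lines.append(
                c[0].ljust(widths[0]) + "  "
                + "  ".join(v.rjust(w) for v, w in zip(c[1:], widths[1:]))
            )
        lines.append("")
    lines.append(f"{FLOOR_MARK} raised to the per-city minimum; "
                 f"{NONEXISTENT_MARK} no such specialization exists locally")
    return "\n".join(lines) + "\n"


def read_report_csv(text: str) -> list[GapReport]:
    """Parse a csv rendering back into GapReports (shortage/surplus recomputed)."""
    reader = csv.DictReader(io.StringIO(text))
    by_geo: dict[str, list[GapRow]] = {}
    for rec in reader:
        by_geo.setdefault(rec["geography"], []).append(
            GapRow.from_counts(
                rec["category"], int(rec["needed"]), int(rec["available"])
            )
        )
    return [GapReport(geography=g, rows=rows) for g, rows in by_geo.items()]
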