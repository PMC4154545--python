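"""End-to-end pipeline: incidence → demand → requirements → gap report."""

from __future__ import annotations

from typing import Optional

from .capacity import apply_city_minimum, compute_requirements
from .demand import compute_demand
from .gaps import MergeRule, compute_gaps, merge_available_categories
from .types import (
    AvailabilityInventory,
    CapacityNorms,
    DemandOverrides,
    GapReport,
    IncidenceTable,
    ModalityDemand,
    RequirementSummary,
    TreatmentFractionRecord,
)


def run_gap_pipeline(
    incidence: IncidenceTable,
    fractions: list[TreatmentFractionRecord],
    inventory: AvailabilityInventory,
    norms: Optional[CapacityNorms] = None,
    *,
    level: str = "group",
    nonstop_allowed: bool = False,
    overrides: Optional[DemandOverrides] = None,
    merges: Optional[list[MergeRule]] = None,
) -> tuple[ModalityDemand, RequirementSummary, GapReport]:
    """One geography, start to finish.

    Computes modality demand from the incidence table and fraction records,
    converts it (or the supplied overrides) into staffing/bed/equipment
    requirements, applies the per-city minimum for city-level geographies,
    optionally merges availability categories, and returns the gap report
    alongside the intermediate results.
    """
    norms = norms or CapacityNorms()
    demand = compute_demand(incidence, fractions, level=level)
    required = compute_requirements(
        incidence, demand, norms, nonstop_allowed=nonstop_allowed, overrides=overrides
    )
    if required.level == "city":
        required = apply_city_minimum(required, norms)
    if merges:
        inventory = merge_available_categories(inventory, merges)
    return demand, required, compute_gaps(required, inventory)
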