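"""Capacity conversions: demand into staff, wards, and radiotherapy equipment.

All conversions round **up**: a fractional requirement still needs a whole
professional or machine. The ratio rules are of the form ceil(patients ×
rate / 1000); the surgical workforce divides annual surgical patients by a
surgeon's annual caseload; ward staff are fixed multiples of the ward count;
and radiotherapy equipment comes in per-1000-patient blocks, with teletherapy
doubled unless near-non-stop operation of a single unit is acceptable.
"""

from __future__ import annotations

from typing import Optional

from .demand import beds_needed
from .errors import ConfigurationError, DomainError
from .rounding import ceil_exact, per_1000_ceil
from .types import (
    CapacityNorms,
    DemandOverrides,
    IncidenceTable,
    ModalityDemand,
    RequirementSummary,
    SUBSPECIALTY_SITES,
)


def ratio_staff_need(patients: int, per_1000: float) -> int:
    """ceil(patients × per_1000 / 1000) — the generic staffing-ratio rule."""
    if patients < 0:
        raise DomainError(f"patient count must be non-negative, got {patients}")
    if per_1000 <= 0:
        raise DomainError(f"staffing rate must be positive, got {per_1000}")
    return per_1000_ceil(patients, per_1000)


def surgeon_need(surgical_patients: int, norms: CapacityNorms) -> int:
    """Surgical oncologists from annual surgical caseload.

    Throughput per surgeon = surgeries/day × days/week × weeks/year
    (default 2 × 5 × 48 = 480 operations a year).
    """
    if surgical_patients < 0:
        raise DomainError(f"patient count must be non-negative, got {surgical_patients}")
    throughput = norms.surgeon_annual_throughput
    if throughput <= 0:
        raise ConfigurationError("surgeon annual throughput is zero")
    return ceil_exact(surgical_patients / throughput)


def ward_staffing(beds: int, norms: CapacityNorms) -> dict[str, int]:
    """Wards and ward-bound staff for a bed requirement.

    A ward is a fixed-size in-patient oncology unit (default 24 beds) with a
    fixed complement of nurses, oncopharmacists, and pharmacy technicians;
    staff counts are exact multiples of the ward count.
    """
    if beds < 0:
        raise DomainError(f"bed count must be non-negative, got {beds}")
    wards = ceil_exact(beds / norms.ward_size_beds)
    return {
        "wards": wards,
        "oncology_nurses": norms.nurses_per_ward * wards,
        "oncopharmacists": norms.oncopharmacists_per_ward * wards,
        "pharmacy_technicians": norms.pharmacy_techs_per_ward * wards,
    }


def rt_staff_need(rt_patients: int, norms: CapacityNorms) -> dict[str, int]:
    """Radiotherapy staff per 1000 patients requiring radiotherapy."""
    if rt_patients < 0:
        raise DomainError(f"patient count must be non-negative, got {rt_patients}")
    return {
        "rt_technicians": per_1000_ceil(rt_patients, norms.rt_techs_per_1000_rt),
        "medical_physicists": per_1000_ceil(rt_patients, norms.physicists_per_1000_rt),
        "linac_engineers": per_1000_ceil(rt_patients, norms.linac_engineers_per_1000_rt),
        "rt_nurses": per_1000_ceil(rt_patients, norms.rt_nurses_per_1000_rt),
    }


def rt_equipment_need(
    rt_patients: int, nonstop_allowed: bool, norms: CapacityNorms
) -> dict[str, int]:
    """Radiotherapy equipment in per-1000-patient blocks.

    Each block needs one brachytherapy unit, CT simulator, treatment planning
    system, and dosimetry/QA package. A single megavoltage teletherapy unit
    per block suffices only if it may run nearly non-stop; otherwise each
    block needs two units.
    """
    if rt_patients < 0:
        raise DomainError(f"patient count must be non-negative, got {rt_patients}")
    blocks = ceil_exact(rt_patients / 1000)
    per_block = norms.equipment_per_1000_rt
    tele_factor = 1 if nonstop_allowed else norms.teletherapy_units_if_not_nonstop
    return {
        "teletherapy": tele_factor * per_block * blocks,
        "brachytherapy": per_block * blocks,
        "ct_simulator": per_block * blocks,
        "tps": per_block * blocks,
        "dosimetry_qa": per_block * blocks,
    }


def apply_city_minimum(
    requirements: RequirementSummary, norms: CapacityNorms
) -> RequirementSummary:
    """Raise every city staff requirement to the redundancy floor (default 2).

    A city needs at least two professionals of each kind so that cover exists
    when one leaves or is away. The floor applies to cities only; state and
    country totals are computed directly from their own case loads.
    """
    if requirements.level != "city":
        raise DomainError(
            f"city minimum applies only to city-level summaries, got {requirements.level!r}"
        )
    staff = dict(requirements.staff)
    floored = set(requirements.floored)
    for category, value in staff.items():
        if value < norms.city_minimum:
            staff[category] = norms.city_minimum
            floored.add(category)
    return requirements.model_copy(update={"staff": staff, "floored": floored})


def compute_requirements(
    incidence: IncidenceTable,
    demand: Optional[ModalityDemand] = None,
    norms: Optional[CapacityNorms] = None,
    *,
    nonstop_allowed: bool = False,
    overrides: Optional[DemandOverrides] = None,
) -> RequirementSummary:
    """Full requirement summary for one geography.

    Case-driven ratios (radiation/clinical oncologists, pathologists,
    palliative care, site subspecialists) come from the incidence table;
    modality-driven needs (surgeons, beds/wards, RT staff and equipment)
    come from ``demand`` unless an override supplies the totals directly.
    The radiation/clinical oncologist need is driven by total cancer cases,
    not by the radiotherapy caseload, even though it is conventionally
    reported alongside RT staffing.
    """
    norms = norms or CapacityNorms()
    overrides = overrides or DemandOverrides()

    def effective(name: str) -> int:
        value = getattr(overrides, name)
        if value is not None:
            return value
        if demand is None:
            raise ConfigurationError(
                f"no demand table and no override for {name!r}"
            )
        return getattr(demand.totals, name) if name != "beds" else beds_needed(demand)

    total_cases = incidence.total_all_cancers
    site_cases = incidence.site_cases()

    staff: dict[str, int] = {
        "radiation_clinical_oncologists": ratio_staff_need(
            total_cases, norms.rco_per_1000_cases
        ),
        "pathologists": ratio_staff_need(total_cases, norms.pathologists_per_1000_cases),
        "palliative_care_specialists": ratio_staff_need(
            total_cases, norms.palliative_per_1000_cases
        ),
        "surgical_oncologists": surgeon_need(effective("surgery"), norms),
    }
    for category, site in SUBSPECIALTY_SITES.items():
        if site in site_cases:
            staff[category] = ratio_staff_need(
                site_cases[site], norms.subspecialists_per_1000_site_cases
            )

    beds = effective("beds")
    ward = ward_staffing(beds, norms)
    wards = ward.pop("wards")
    staff.update(ward)

    rt_patients = effective("rt")
    staff.update(rt_staff_need(rt_patients, norms))
    equipment = rt_equipment_need(rt_patients, nonstop_allowed, norms)

    return RequirementSummary(
        geography=incidence.geography.name,
        level=incidence.geography.level,
        staff=staff,
        beds=beds,
        wards=wards,
        equipment=equipment,
    )
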