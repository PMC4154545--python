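"""Domain types for the capacity-planning pipeline.

The models mirror the data a planner actually handles: an incidence table
for one geography, per-site treatment fractions with in-patient lengths of
stay, the staffing/equipment norms, an availability inventory, and the
needed-vs-available gap report.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import DomainError

GeoLevel = Literal["country", "state", "city"]

#: canonical staff-category labels used in requirement summaries and inventories
STAFF_CATEGORIES = (
    "radiation_clinical_oncologists",
    "pathologists",
    "palliative_care_specialists",
    "surgical_oncologists",
    "gynecologic_oncologists",
    "urologic_oncologists",
    "neurologic_oncologists",
    "hematologist_oncologists",
    "oncology_nurses",
    "oncopharmacists",
    "pharmacy_technicians",
    "rt_technicians",
    "medical_physicists",
    "linac_engineers",
    "rt_nurses",
)

#: canonical radiotherapy equipment labels
EQUIPMENT_CATEGORIES = (
    "teletherapy",
    "brachytherapy",
    "ct_simulator",
    "tps",
    "dosimetry_qa",
)

#: cancer-site label driving each site-specific subspecialty ratio
SUBSPECIALTY_SITES = {
    "gynecologic_oncologists": "gynecological",
    "urologic_oncologists": "urological",
    "neurologic_oncologists": "brain, nervous system",
    "hematologist_oncologists": "hematological malignancies",
}

#: site label of the all-sites total row in incidence CSV files
ALL_CANCERS_LABEL = "all cancers"


class Geography(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    population: int = Field(ge=0)
    level: GeoLevel
    parent: Optional[str] = None


def validate_geographies(geographies: list[Geography]) -> list[str]:
    """Cross-record checks: a city never outgrows its parent state."""
    by_name = {g.name: g for g in geographies}
    violations = []
    for g in geographies:
        if g.level == "city" and g.parent and g.parent in by_name:
            parent = by_name[g.parent]
            if g.population > parent.population:
                violations.append(
                    f"city {g.name!r} population {g.population} exceeds "
                    f"parent {parent.name!r} population {parent.population}"
                )
    return violations


class IncidenceRecord(BaseModel):
    """Annual new cancer cases for one site; sex-specific counts optional."""

    site: str
    cases_both: int
    cases_men: Optional[int] = None
    cases_women: Optional[int] = None


class IncidenceTable(BaseModel):
    """Per-site annual new cancer cases for one geography.

    ``total_all_cancers`` may exceed the sum over listed records: planning
    tables typically list only the most common sites.
    """

    geography: Geography
    year: int
    records: list[IncidenceRecord]
    total_all_cancers: int

    def site_cases(self) -> dict[str, int]:
        return {r.site.lower(): r.cases_both for r in self.records}


class GrowthProjection(BaseModel):
    base_year: int
    base_total: int = Field(gt=0)
    horizon_year: int
    horizon_total: int = Field(gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "GrowthProjection":
        if self.horizon_year <= self.base_year:
            raise DomainError(
                f"horizon_year {self.horizon_year} must exceed base_year {self.base_year}"
            )
        return self


class TreatmentFractionRecord(BaseModel):
    """Percent of a site's patients needing each modality, with mean in-patient days (ALOS)."""

    site: str
    level: Literal["group", "subtype"] = "group"
    pct_surgery: float = Field(ge=0, le=100)
    alos_surgery: float = Field(ge=0)
    pct_chemo: float = Field(ge=0, le=100)
    alos_chemo: float = Field(ge=0)
    pct_rt: float = Field(ge=0, le=100)
    alos_rt: float = Field(ge=0)


class ModalityCounts(BaseModel):
    surgery: int = 0
    chemo: int = 0
    rt: int = 0


class ModalityDays(BaseModel):
    surgery: float = 0.0
    chemo: float = 0.0
    rt: float = 0.0


class ModalityDemand(BaseModel):
    """Patients requiring each modality, per site and in total, plus bed-days."""

    geography: str
    per_site: dict[str, ModalityCounts]
    totals: ModalityCounts
    bed_days: ModalityDays


class DemandOverrides(BaseModel):
    """Externally supplied totals that replace computed ones downstream.

    Planning documents sometimes print modality totals that cannot be
    recomputed from the published site-level inputs; an override keeps the
    downstream staffing arithmetic reproducible from those printed totals
    without pretending they came out of the site-level computation.
    """

    surgery: Optional[int] = Field(default=None, ge=0)
    chemo: Optional[int] = Field(default=None, ge=0)
    rt: Optional[int] = Field(default=None, ge=0)
    beds: Optional[int] = Field(default=None, ge=0)


class CapacityNorms(BaseModel):
    """Staffing ratios, ward model, surgical throughput, and RT norms.

    Defaults follow the IAEA-style planning assumptions for LMIC settings:
    combined radiation/clinical oncologists at 5 per 1000 new cancer cases,
    site subspecialists at 2 per 1000 site cases, a fixed-staff 24-bed
    oncology ward, and radiotherapy staff/equipment per 1000 RT courses.
    Every field is overridable from a config file.
    """

    rco_per_1000_cases: float = Field(default=5, gt=0)
    pathologists_per_1000_cases: float = Field(default=2, gt=0)
    palliative_per_1000_cases: float = Field(default=2, gt=0)
    subspecialists_per_1000_site_cases: float = Field(default=2, gt=0)
    surgeries_per_day: float = Field(default=2, gt=0)
    days_per_week: float = Field(default=5, gt=0)
    weeks_per_year: float = Field(default=48, gt=0)
    ward_size_beds: int = Field(default=24, gt=0)
    nurses_per_ward: int = Field(default=15, gt=0)
    oncopharmacists_per_ward: int = Field(default=4, gt=0)
    pharmacy_techs_per_ward: int = Field(default=6, gt=0)
    rt_techs_per_1000_rt: float = Field(default=12, gt=0)
    physicists_per_1000_rt: float = Field(default=4, gt=0)
    linac_engineers_per_1000_rt: float = Field(default=1, gt=0)
    rt_nurses_per_1000_rt: float = Field(default=4, gt=0)
    equipment_per_1000_rt: int = Field(default=1, gt=0)
    teletherapy_units_if_not_nonstop: int = Field(default=2, gt=0)
    city_minimum: int = Field(default=2, gt=0)

    @property
    def surgeon_annual_throughput(self) -> float:
        return self.surgeries_per_day * self.days_per_week * self.weeks_per_year


class RequirementSummary(BaseModel):
    """Required staff, beds/wards, and equipment for one geography."""

    geography: str
    level: GeoLevel = "state"
    staff: dict[str, int]
    beds: int = 0
    wards: int = 0
    equipment: dict[str, int] = Field(default_factory=dict)
    floored: set[str] = Field(default_factory=set)  # categories raised to the city minimum


class AvailabilityInventory(BaseModel):
    """Counts of each professional/equipment category actually present."""

    geography: str
    staff_available: dict[str, int] = Field(default_factory=dict)
    beds_available: int = 0
    equipment_available: dict[str, int] = Field(default_factory=dict)
    categories_nonexistent: set[str] = Field(default_factory=set)
    merged_from: dict[str, list[str]] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _nonnegative(self) -> "AvailabilityInventory":
        for label, count in {**self.staff_available, **self.equipment_available,
                             "beds": self.beds_available}.items():
            if count < 0:
                raise DomainError(f"negative availability for {label!r}: {count}")
        return self


class GapRow(BaseModel):
    category: str
    needed: int
    available: int
    shortage: int
    surplus: int
    needed_floored: bool = False
    available_nonexistent: bool = False

    @classmethod
    def from_counts(cls, category: str, needed: int, available: int, **flags) -> "GapRow":
        return cls(
            category=category,
            needed=needed,
            available=available,
            shortage=max(0, needed - available),
            surplus=max(0, available - needed),
            **flags,
        )


class GapReport(BaseModel):
    geography: str
    rows: list[GapRow]

    def row(self, category: str) -> GapRow:
        for r in self.rows:
            if r.category == category:
                return r
        raise KeyError(category)

    def shortage(self, category: str) -> int:
        return self.row(category).shortage
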