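"""Synthetic planning scenarios for end-to-end testing without any download.

The generator emulates the data shapes the pipeline consumes: a country
whose listed cancer sites carry a random share of the national caseload, a
populous state with a handful of much smaller cities (mirroring a setting
where the major treatment-centre cities hold well under a tenth of the state
population), and sparse availability inventories in which some professional
categories simply do not exist locally.

It makes no attempt at epidemiological realism beyond those shapes — no age
structure, no site-specific sex biology, no urban/rural incidence gradient.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import io as ocio
from .errors import ConfigurationError, DomainError
from .rounding import round_half_up
from .types import (
    AvailabilityInventory,
    CapacityNorms,
    EQUIPMENT_CATEGORIES,
    Geography,
    IncidenceRecord,
    IncidenceTable,
    STAFF_CATEGORIES,
    TreatmentFractionRecord,
)


class ScenarioSpec(BaseModel):
    """Parameters of one synthetic scenario.

    Defaults mirror the reference setting: a ~200-million-person state inside
    a ~1.19-billion-person country with roughly 0.95 million annual new
    cancer cases, ten treatment-centre cities of 0.5–2.8 million people, and
    listed sites carrying ~84.5% of the all-sites total.
    """

    seed: int = 0
    n_cities: int = Field(default=10, gt=0)
    national_population: int = Field(default=1_190_000_000, gt=0)
    state_population: int = Field(default=200_000_000, gt=0)
    city_population_range: tuple[int, int] = (500_000, 2_800_000)
    national_total_cases: int = Field(default=948_858, gt=0)
    listed_site_share: float = Field(default=0.845, gt=0, le=1)
    site_share_concentration: float = Field(default=1.0, gt=0)
    sex_split_range: tuple[float, float] = (0.35, 0.65)
    availability_sparsity: float = Field(default=0.3, ge=0, le=1)
    year: int = 2008
    fraction_table: Optional[list[TreatmentFractionRecord]] = None

    @model_validator(mode="after")
    def _feasible(self) -> "ScenarioSpec":
        lo, hi = self.city_population_range
        if lo > hi:
            raise ConfigurationError(f"city population range inverted: {lo} > {hi}")
        slo, shi = self.sex_split_range
        if not (0 <= slo <= shi <= 1):
            raise ConfigurationError(f"sex split range invalid: [{slo}, {shi}]")
        if self.n_cities * hi >= self.state_population:
            raise ConfigurationError(
                "cities could outgrow the state: "
                f"{self.n_cities} × {hi} ≥ {self.state_population}"
            )
        if self.state_population > self.national_population:
            raise ConfigurationError("state population exceeds national population")
        return self

    def fractions(self) -> list[TreatmentFractionRecord]:
        return self.fraction_table or ocio.default_fractions()


class Scenario(BaseModel):
    geographies: list[Geography]
    national_incidence: IncidenceTable
    inventories: dict[str, AvailabilityInventory]
    fraction_table: list[TreatmentFractionRecord]
    seed: int


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``weights``.

    Largest-remainder (Hamilton) apportionment: floor the exact quotas, then
    hand the leftover units to the largest fractional parts (ties broken by
    index). The result always sums to ``total`` exactly.
    """
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise DomainError("weights must be non-negative with a positive sum")
    quotas = weights / weights.sum() * total
    base = np.floor(quotas).astype(int)
    remainder = total - int(base.sum())
    if remainder:
        order = np.lexsort((np.arange(len(weights)), -(quotas - base)))
        base[order[:remainder]] += 1
    return base


def generate_scenario(spec: ScenarioSpec) -> Scenario:
    """Deterministic scenario for a seed: geographies, incidence, inventories."""
    rng = np.random.default_rng(spec.seed)
    fractions = spec.fractions()

    lo, hi = spec.city_population_range
    city_pops = rng.integers(lo, hi + 1, size=spec.n_cities)
    country = Geography(name="Nation", population=spec.national_population, level="country")
    state = Geography(
        name="State", population=spec.state_population, level="state", parent="Nation"
    )
    cities = [
        Geography(name=f"City{i + 1:02d}", population=int(p), level="city", parent="State")
        for i, p in enumerate(city_pops)
    ]

    sites = [f.site for f in fractions if f.level == "group"]
    listed_total = round_half_up(spec.national_total_cases * spec.listed_site_share)
    proportions = rng.dirichlet([spec.site_share_concentration] * len(sites))
    counts = largest_remainder(proportions, listed_total)

    slo, shi = spec.sex_split_range
    records = []
    for site, both in zip(sites, counts):
        male_share = rng.uniform(slo, shi)
        men = round_half_up(int(both) * male_share)
        records.append(
            IncidenceRecord(
                site=site, cases_both=int(both), cases_men=men, cases_women=int(both) - men
            )
        )
    national = IncidenceTable(
        geography=country,
        year=spec.year,
        records=records,
        total_all_cancers=spec.national_total_cases,
    )

    inventories = {
        g.name: _random_inventory(g, rng, spec.availability_sparsity)
        for g in [state, *cities]
    }
    return Scenario(
        geographies=[country, state, *cities],
        national_incidence=national,
        inventories=inventories,
        fraction_table=fractions,
        seed=spec.seed,
    )


def _random_inventory(
    geo: Geography, rng: np.random.Generator, sparsity: float
) -> AvailabilityInventory:
    staff_hi, beds_hi, equip_hi = (200, 1200, 40) if geo.level != "city" else (30, 150, 8)
    staff, equipment, nonexistent = {}, {}, set()

    def draw(hi: int, category: str) -> int:
        if rng.random() < sparsity:
            nonexistent.add(category)
            return 0
        return int(rng.integers(1, hi + 1))

    for category in STAFF_CATEGORIES:
        staff[category] = draw(staff_hi, category)
    for category in EQUIPMENT_CATEGORIES:
        equipment[category] = draw(equip_hi, category)
    beds = 0 if rng.random() < sparsity else int(rng.integers(1, beds_hi + 1))
    return AvailabilityInventory(
        geography=geo.name,
        staff_available=staff,
        beds_available=beds,
        equipment_available=equipment,
        categories_nonexistent=nonexistent,
    )


def perturb_norms(norms: CapacityNorms, relative_range: float, seed: int) -> CapacityNorms:
    """Jitter every norm by an independent factor in [1−r, 1+r] (sensitivity runs).

    Integer norms are re-rounded half-up and floored at 1 so the perturbed
    set is still a valid configuration.
    """
    if not 0 <= relative_range < 1:
        raise DomainError(f"relative range must be in [0, 1), got {relative_range}")
    rng = np.random.default_rng(seed)
    updates = {}
    for name, value in norms.model_dump().items():
        factor = rng.uniform(1 - relative_range, 1 + relative_range)
        if isinstance(value, int):
            updates[name] = max(1, round_half_up(value * factor))
        else:
            updates[name] = value * factor
    return CapacityNorms(**updates)


def write_scenario(scenario: Scenario, outdir) -> None:
    """Write a scenario as files the main pipeline consumes unchanged."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"seed={scenario.seed}"
    ocio.write_geographies(scenario.geographies, outdir / "geographies.yaml")
    ocio.write_incidence_csv(
        scenario.national_incidence, outdir / "national_incidence.csv", header_comment=stamp
    )
    ocio.write_fractions_csv(
        scenario.fraction_table, outdir / "treatment_fractions.csv", header_comment=stamp
    )
    ocio.write_inventory_csv(
        scenario.inventories, outdir / "availability.csv", header_comment=stamp
    )
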