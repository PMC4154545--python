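"""Incidence tables: validation, population-share extrapolation, growth projection.

In settings without a sub-national cancer registry, the standard first step
is to assume the sub-national site mix matches the national one and scale
national case counts by population share. The operations here implement
exactly that, plus the consistency checks a transcribed incidence table
must satisfy (sex counts summing to both-sexes counts; the all-sites total
bounding the listed-site sum).
"""

from __future__ import annotations

from fractions import Fraction
from typing import Optional

from .errors import ConfigurationError, DomainError
from .rounding import _as_fraction, scale_half_up
from .types import Geography, GrowthProjection, IncidenceRecord, IncidenceTable


def validate_incidence(table: IncidenceTable) -> list[str]:
    """Return one human-readable violation per failed invariant (empty list = clean).

    Checks, per record: non-negative counts; men + women = both when both
    sex-specific counts are present. Table-level: the all-cancers total is
    at least the sum of listed-site counts (the total covers unlisted sites).
    """
    violations: list[str] = []
    for rec in table.records:
        for field in ("cases_both", "cases_men", "cases_women"):
            value = getattr(rec, field)
            if value is not None and value < 0:
                violations.append(f"{rec.site}: {field} is negative ({value})")
        if rec.cases_men is not None and rec.cases_women is not None:
            if rec.cases_men + rec.cases_women != rec.cases_both:
                violations.append(
                    f"{rec.site}: men ({rec.cases_men}) + women ({rec.cases_women}) "
                    f"= {rec.cases_men + rec.cases_women} != both sexes ({rec.cases_both})"
                )
    if table.total_all_cancers < 0:
        violations.append(f"total_all_cancers is negative ({table.total_all_cancers})")
    listed = sum(r.cases_both for r in table.records)
    if table.total_all_cancers < listed:
        violations.append(
            f"all-cancers total ({table.total_all_cancers}) is below the "
            f"sum of listed sites ({listed})"
        )
    return violations


def _scale_record(rec: IncidenceRecord, share: Fraction) -> IncidenceRecord:
    both = scale_half_up(rec.cases_both, share)
    men = women = None
    if rec.cases_men is not None and rec.cases_women is not None:
        # keep men + women = both exact under rounding
        men = scale_half_up(rec.cases_men, share)
        women = both - men
    elif rec.cases_men is not None:
        men = scale_half_up(rec.cases_men, share)
    elif rec.cases_women is not None:
        women = scale_half_up(rec.cases_women, share)
    return IncidenceRecord(site=rec.site, cases_both=both, cases_men=men, cases_women=women)


def extrapolate_incidence(
    national: IncidenceTable,
    target: Geography,
    share: Optional[float] = None,
) -> IncidenceTable:
    """Scale a (national) incidence table to a target geography by population share.

    ``share`` may be given explicitly, in (0, 1]; otherwise it is derived as
    ``target.population / national.geography.population``. Per-site counts
    round half-up to whole cases; the all-cancers total is scaled
    independently of the rounded site counts because it covers sites the
    table does not list.
    """
    if share is None:
        src_pop = national.geography.population
        if src_pop <= 0 or target.population <= 0:
            raise ConfigurationError(
                "share not given and populations unavailable: "
                f"source={src_pop}, target={target.population}"
            )
        share_f = Fraction(target.population, src_pop)
    else:
        share_f = _as_fraction(share)
    if not (0 < share_f <= 1):
        raise DomainError(f"population share must be in (0, 1], got {float(share_f)}")
    return IncidenceTable(
        geography=target,
        year=national.year,
        records=[_scale_record(r, share_f) for r in national.records],
        total_all_cancers=scale_half_up(national.total_all_cancers, share_f),
    )


def growth_factor(projection: GrowthProjection, query_year: int) -> float:
    """Multiplier on resource needs at ``query_year``, interpolated linearly.

    Returns 1.0 at the base year and ``horizon_total / base_total`` at the
    horizon year; years in between interpolate linearly in the factor.
    Queries outside [base_year, horizon_year] are refused rather than
    extrapolated.
    """
    if not (projection.base_year <= query_year <= projection.horizon_year):
        raise DomainError(
            f"query year {query_year} outside "
            f"[{projection.base_year}, {projection.horizon_year}]"
        )
    ratio = projection.horizon_total / projection.base_total
    span = projection.horizon_year - projection.base_year
    return 1.0 + (ratio - 1.0) * (query_year - projection.base_year) / span
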