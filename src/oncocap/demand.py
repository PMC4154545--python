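"""Treatment demand: patients per modality and in-patient bed-days.

Per-site demand is the site's annual new cases times the fraction needing
each modality (surgery, chemotherapy, radiotherapy), rounded half-up to
whole patients. Bed-days multiply each site's treated patients by the
modality's average length of stay (ALOS); the bed requirement divides total
annual bed-days by 365 and rounds up.
"""

from __future__ import annotations

from fractions import Fraction

from .errors import ConfigurationError, DomainError
from .rounding import _as_fraction, ceil_exact, round_half_up
from .types import (
    IncidenceTable,
    ModalityCounts,
    ModalityDays,
    ModalityDemand,
    TreatmentFractionRecord,
)

MODALITIES = ("surgery", "chemo", "rt")


def site_modality_demand(cases: int, pct: float) -> int:
    """Patients at one site requiring one modality: round-half-up(cases × pct/100)."""
    if not 0 <= pct <= 100:
        raise DomainError(f"percentage must be in [0, 100], got {pct}")
    if cases < 0:
        raise DomainError(f"case count must be non-negative, got {cases}")
    return round_half_up(Fraction(cases) * _as_fraction(pct) / 100)


def compute_demand(
    incidence: IncidenceTable,
    fractions: list[TreatmentFractionRecord],
    level: str = "group",
) -> ModalityDemand:
    """Per-site and total modality demand plus bed-days for one geography.

    Every incidence site with cases > 0 must have a fraction record at the
    chosen level (``group`` or ``subtype``); a missing record is a
    configuration error naming the site, never a silent zero.
    """
    lookup = {f.site.lower(): f for f in fractions if f.level == level}
    per_site: dict[str, ModalityCounts] = {}
    bed_days = {m: Fraction(0) for m in MODALITIES}
    for rec in incidence.records:
        frac = lookup.get(rec.site.lower())
        if frac is None:
            if rec.cases_both > 0:
                raise ConfigurationError(
                    f"no {level}-level treatment-fraction record for site "
                    f"{rec.site!r} ({rec.cases_both} cases)"
                )
            continue
        counts = ModalityCounts(
            surgery=site_modality_demand(rec.cases_both, frac.pct_surgery),
            chemo=site_modality_demand(rec.cases_both, frac.pct_chemo),
            rt=site_modality_demand(rec.cases_both, frac.pct_rt),
        )
        per_site[rec.site] = counts
        bed_days["surgery"] += counts.surgery * _as_fraction(frac.alos_surgery)
        bed_days["chemo"] += counts.chemo * _as_fraction(frac.alos_chemo)
        bed_days["rt"] += counts.rt * _as_fraction(frac.alos_rt)
    totals = ModalityCounts(
        surgery=sum(c.surgery for c in per_site.values()),
        chemo=sum(c.chemo for c in per_site.values()),
        rt=sum(c.rt for c in per_site.values()),
    )
    return ModalityDemand(
        geography=incidence.geography.name,
        per_site=per_site,
        totals=totals,
        bed_days=ModalityDays(**{m: float(v) for m, v in bed_days.items()}),
    )


def beds_needed(demand: ModalityDemand) -> int:
    """Oncology beds: total annual bed-days over all modalities, divided by 365, rounded up."""
    total = (
        _as_fraction(demand.bed_days.surgery)
        + _as_fraction(demand.bed_days.chemo)
        + _as_fraction(demand.bed_days.rt)
    )
    return ceil_exact(total / 365)
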