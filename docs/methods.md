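# Methods

## Scope and model structure

`oncocap` implements a deterministic, norm-based planning chain:

```
national incidence ──(population share)──▶ local incidence
local incidence ──(per-site % and ALOS)──▶ modality demand, bed-days
demand / overrides ──(staffing & equipment norms)──▶ requirements
requirements vs inventory ──▶ gap report
```

Every stage is a pure function of its inputs; re-running the pipeline on
identical inputs is byte-identical. There is no queueing, utilization,
survival, or attrition modelling: the chain answers "how many professionals,
beds, and machines does this caseload imply under these norms", not "how
would a system with those resources perform".

## Assumptions

1. **Proportional incidence.** Without a sub-national registry, the local
   site mix is assumed identical to the national one, so local counts are
   national counts times the population share. The share is an *explicit*
   input: it may be passed directly or derived from two population figures,
   but the package never silently chooses a population source, because
   different census vintages give materially different shares.
2. **Fixed treatment fractions.** The percent of each site's patients
   requiring surgery, chemotherapy, and radiotherapy is stage-independent
   and constant, as is the average in-patient length of stay (ALOS). Every
   treated patient is assumed admitted for the stated ALOS — the model has
   no out-patient fraction.
3. **Linear staffing norms with whole-unit rounding.** Staff and equipment
   scale linearly with caseload at fixed ratios, rounded **up**: ceiling
   rounding is the only convention consistent with whole-person requirements
   (801.48 oncologists means 802 must exist; 120.5 wards means 121).
   Demand, by contrast, rounds **half-up** to whole patients.
4. **Redundancy floor.** A city needs at least two professionals of each
   kind so that cover exists during leave. The floor applies to cities only;
   a state's need is computed directly from state totals, *not* as the sum
   of floored city values — summing floors would inflate the state figure
   with minima that exist purely for local redundancy.

## Parameters

| parameter | default | units | note |
|---|---|---|---|
| radiation/clinical oncologists | 5 / 1000 cases | staff | combined-track model for LMIC |
| pathologists, palliative care | 2 / 1000 cases | staff | pathologists not oncology-exclusive |
| site subspecialists | 2 / 1000 site cases | staff | gyn/uro/neuro/heme sites |
| surgeon throughput | 2 × 5 × 48 = 480 | operations/yr | surgeries/day × days/wk × wks/yr |
| ward size | 24 | beds | fixed-complement in-patient unit |
| ward staff | 15 / 4 / 6 | per ward | nurses / oncopharmacists / pharmacy techs |
| RT staff | 12 / 4 / 1 / 4 | per 1000 RT pts | techs / physicists / linac eng. / RT nurses |
| RT equipment | 1 of each | per 1000 RT pts | teletherapy, brachy, CT sim, TPS, dosimetry/QA |
| teletherapy (no non-stop) | 2 | per block | default; a single unit per block implies near-24/7 running |
| city minimum | 2 | staff | per category, cities only |

All norms load from a YAML/JSON file; omitted fields keep these defaults.

## Numerical choices

- All rounding passes through exact rational arithmetic (`fractions.Fraction`
  via decimal string repr), so values like 57% of 28,934 or 2892/24 = 120.5
  never land on the wrong side of a half through binary floating point.
- Extrapolation scales each site half-up independently and the all-sites
  total independently of the rounded site counts (the total covers unlisted
  sites, so it is not the sum of the listed ones). When both sex-specific
  counts are present, men are scaled half-up and women set to both − men, so
  the sex-sum invariant survives rounding exactly.
- Growth projection interpolates the growth *factor* linearly between the
  base year (factor 1) and the horizon year (horizon/base). Other plausible
  schemes (geometric, population-weighted) give slightly different mid-span
  values; linear was chosen as the simplest defensible default, and queries
  outside the projection span are refused rather than extrapolated.
- Ties in largest-remainder apportionment break by index, making the
  synthetic generator fully deterministic for a seed.

## Computed vs override totals

The packaged reference exercise exposes a real reproducibility gap:
recomputing modality demand from the packaged group-level tables yields
68,212 / 101,434 / 83,839 patients (surgery / chemo / RT), while the
published planning totals are 74,860 / 117,172 / 94,808 — evidently derived
at a subtype resolution whose case counts were never published, possibly
including the ~24,870 cases at unlisted sites. The same applies to the
published bed figure (2,892). The package therefore supports an explicit
`DemandOverrides` object: computed demand is always reported as computed,
and overrides feed only the downstream capacity stages. Nothing is imputed;
the two sets of numbers are never mixed silently. Similarly, the published
surgical-oncologist figure (157) exceeds `⌈74,860/480⌉ = 156` by one and the
published bed shortage (2,018) exceeds 2,892 − 875 = 2,017 by one; the
pipeline reports the arithmetic values.

## Synthetic data

`ScenarioSpec` defaults emulate the reference setting: a ~1.19-billion-person
country with 948,858 annual new cancer cases, a 200-million-person state, and
ten treatment-centre cities of 0.5–2.8 million people (so the cities hold well
under a tenth of the state's population). Listed sites carry 84.5% of the
all-sites total (matching the reference table's listed/total ratio); site
proportions are Dirichlet-distributed with unit concentration; sex splits are
uniform in [0.35, 0.65] and reconciled so men + women = both exactly;
availability categories are absent with probability 0.3 and otherwise small
positive integers. These choices were made once, as plausible magnitudes for
the setting, and are not tuned.

What the generator deliberately does **not** emulate: age structure,
site-specific sex biology (a synthetic "gynecological" site can have male
cases), urban/rural gradients, or correlated availability across categories.
Passing end-to-end tests on synthetic scenarios therefore demonstrates that
the pipeline's *invariants* (sex sums, demand ≤ cases, ward multiples, gap
identities, determinism) hold over a wide input space — not that the
generator's outputs are epidemiologically realistic.

## Known limitations

- Raw counts only: no age-standardization or rate computation.
- No treatment sequencing, re-treatment, stage stratification, or survival.
- Subtype-level demand requires user-supplied subtype case counts; no
  imputation of subtype shares from group totals is attempted (an explicit
  subtype → group mapping file is packaged for aggregation instead).
- Availability inventories are taken at face value; double-counting of staff
  across institutions cannot be detected from the inputs.
- Report rendering keeps the six-column CSV contract
  (`geography,category,needed,available,shortage,surplus`); footnote markers
  for city-minimum-floored values (`^a`) and locally nonexistent
  specializations (`^b`) appear in the text and JSON renderings, where they
  cannot corrupt numeric cells.
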