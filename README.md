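# oncocap

Needs-based capacity planning for cancer control in settings without
registry coverage. Given national cancer incidence, a geography's population
share, per-site treatment fractions, and a handful of staffing norms, the
package estimates how many oncologists, pathologists, nurses, oncology beds,
and radiotherapy machines a state or city requires — and compares that
against a survey of what is actually available, category by category.

It is written for health-ministry analysts, hospital planners, and
researchers studying oncology workforce gaps in low- and middle-income
countries, where sub-national cancer registries are rare and planning has to
start from national totals.

## The model

For a geography with population share *s* of the national population and
national incidence *N_i* at cancer site *i*:

- **Incidence extrapolation** — local cases `n_i = round(s · N_i)` (half-up),
  with the all-sites total scaled independently because incidence tables list
  only the most common sites. A linear growth factor projects needs between a
  base and horizon year.
- **Treatment demand** — patients needing modality *m* at site *i* are
  `d_im = round(n_i · p_im / 100)` where `p_im` is the percent of that site's
  patients requiring surgery, chemotherapy, or radiotherapy. Bed-days are
  `Σ_i d_im · ALOS_im`; the bed requirement is `⌈total bed-days / 365⌉`.
- **Capacity norms** (all overridable; ceiling rounding throughout, because a
  fractional requirement still needs a whole person or machine):
  - radiation/clinical oncologists `⌈5 · cases / 1000⌉`; pathologists and
    palliative-care specialists `⌈2 · cases / 1000⌉`;
  - site subspecialists (gynecologic, urologic, neurologic,
    hematologist-oncologists) `⌈2 · site cases / 1000⌉`;
  - surgical oncologists `⌈surgical patients / 480⌉` (2 operations/day,
    5 days/week, 48 weeks/year);
  - oncology wards `⌈beds / 24⌉`, each staffed by exactly 15 nurses,
    4 oncopharmacists, and 6 pharmacy technicians;
  - per 1000 radiotherapy patients: 12 RT technicians, 4 medical physicists,
    1 linac engineer, 4 RT nurses, and one of each equipment block
    (teletherapy, brachytherapy, CT simulator, planning system, dosimetry/QA)
    — with **two** teletherapy units per block unless near-non-stop operation
    of a single unit is acceptable;
  - every city needs at least 2 professionals of each kind (leave cover).
- **Gap analysis** — per category, `shortage = max(0, needed − available)`
  and `surplus = max(0, available − needed)`; a surplus in one geography
  never offsets a deficit elsewhere.

A synthetic-scenario generator (`oncocap.synthetic`) produces complete,
seed-deterministic inputs — geographies, a national incidence table with
reconciled sex splits, sparse availability inventories — so the whole
pipeline is testable without any external data.

## Worked example

The packaged reference data transcribe a published planning exercise for
Uttar Pradesh (UP), India: an estimated 160,296 new cancer cases in 2008 and
a 2013 telephone-survey inventory of oncology resources.

```python
from oncocap import MergeRule, run_gap_pipeline
from oncocap import io as ocio

demand, required, report = run_gap_pipeline(
    ocio.up_incidence(),          # 14 most common sites, 160,296 cases total
    ocio.default_fractions(),     # % requiring surgery/chemo/RT + lengths of stay
    ocio.up_availability(),       # 2013 survey inventory
    overrides=ocio.up_overrides(),  # published modality totals and bed figure
    merges=[MergeRule(sources=["gastro_surgeons"], into="surgical_oncologists")],
)
for cat in ("radiation_clinical_oncologists", "pathologists",
            "oncology_nurses", "teletherapy"):
    r = report.row(cat)
    print(cat, r.needed, r.available, r.shortage)
```

prints

```
radiation_clinical_oncologists 802 87 715
pathologists 321 179 142
oncology_nurses 1815 233 1582
teletherapy 190 26 164
```

i.e. the state needs 802 radiation/clinical oncologists (ceil of
160,296 × 5/1000) but has 87 — a shortage of 715 — and needs 190 megavoltage
teletherapy units (two per started block of 1000 radiotherapy patients,
95 blocks) against 26 available.

Note the deliberate separation of computed and published totals: recomputing
modality demand from the packaged site-level tables gives 68,212 surgical /
101,434 chemotherapy / 83,839 radiotherapy patients, while the published
planning totals (74,860 / 117,172 / 94,808 — derived at a finer site
resolution that was never published) are supplied as explicit *overrides*
for the downstream capacity stages. The pipeline never conflates the two.

The same stages are available from a shell:

```bash
oncocap --seed 7 simulate --out scenario/          # synthetic inputs
oncocap validate --incidence scenario/national_incidence.csv
oncocap gaps --incidence ... --inventory ... --out results/
```

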