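# Default capacity-planning norms (all user-overridable).
rco_per_1000_cases: 5
pathologists_per_1000_cases: 2
palliative_per_1000_cases: 2
subspecialists_per_1000_site_cases: 2
surgeries_per_day: 2
days_per_week: 5
weeks_per_year: 48
ward_size_beds: 24
nurses_per_ward: 15
oncopharmacists_per_ward: 4
pharmacy_techs_per_ward: 6
rt_techs_per_1000_rt: 12
physicists_per_1000_rt: 4
linac_engineers_per_1000_rt: 1
rt_nurses_per_1000_rt: 4
equipment_per_1000_rt: 1
teletherapy_units_if_not_nonstop: 2
city_minimum: 2
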