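geography,category,count,flag
UP,radiation_clinical_oncologists,87,
UP,pathologists,179,
UP,palliative_care_specialists,8,
UP,surgical_oncologists,21,
UP,gastro_surgeons,21,
UP,gynecologic_oncologists,24,
UP,urologic_oncologists,20,
UP,neurologic_oncologists,26,
UP,hematologist_oncologists,7,
UP,oncology_nurses,233,
UP,oncopharmacists,0,nonexistent
UP,pharmacy_technicians,0,nonexistent
UP,rt_technicians,83,
UP,medical_physicists,38,
UP,linac_engineers,0,nonexistent
UP,rt_nurses,0,nonexistent
UP,beds,875,
UP,teletherapy,26,
UP,brachytherapy,17,
UP,ct_simulator,11,
UP,tps,19,
UP,dosimetry_qa,0,
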