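subtype,group
cervix uteri,gynecological
corpus uteri,gynecological
ovary,gynecological
larynx,head and neck
lip and oral cavity,head and neck
nasopharynx,head and neck
other pharynx,head and neck
thyroid,head and neck
hodgkin lymphoma,hematological malignancies
leukemia,hematological malignancies
multiple myeloma,hematological malignancies
non-hodgkin lymphoma,hematological malignancies
bladder,urological
kidney,urological
prostate,urological
testis,urological
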