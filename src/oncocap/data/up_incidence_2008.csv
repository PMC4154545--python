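site,cases_both,cases_men,cases_women
all cancers,160296,72659,87637
gynecological,28934,,28934
head and neck,26080,18359,7721
breast,19470,,19470
hematological malignancies,12026,7301,4725
lung,9894,7942,1952
esophagus,8126,4867,3259
urological,7130,6040,1090
colorectal,6162,3406,2756
stomach,5923,3561,2362
"brain, nervous system",3689,2211,1478
liver,3403,2452,951
gallbladder,2916,1001,1915
pancreas,1513,858,655
melanoma of skin,160,85,75
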