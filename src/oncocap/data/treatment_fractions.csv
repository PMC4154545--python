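site,level,pct_surgery,alos_surgery,pct_chemo,alos_chemo,pct_rt,alos_rt
gynecological,group,57,6.5,67,3,40,5
cervix uteri,subtype,20,5,80,3,80,5
corpus uteri,subtype,80,5,20,3,20,5
ovary,subtype,70,9,100,3,20,5
head and neck,group,44,7,66,3.5,71,5
larynx,subtype,50,9,50,3,75,5
lip and oral cavity,subtype,40,9,80,3,80,5
nasopharynx,subtype,0,0,100,3,100,5
other pharynx,subtype,40,9,80,3,80,5
thyroid,subtype,90,7,20,5,20,5
hematological malignancies,group,0,0,100,6.5,33,5
hodgkin lymphoma,subtype,0,0,100,5,40,5
leukemia,subtype,0,0,100,7,20,5
multiple myeloma,subtype,0,0,100,7,20,5
non-hodgkin lymphoma,subtype,0,0,100,7,50,5
urological,group,74,8,63,3.5,41,5
bladder,subtype,100,9,50,3,50,5
kidney,subtype,75,9,50,3,20,5
prostate,subtype,20,9,50,3,65,5
testis,subtype,100,5,100,5,30,5
"brain, nervous system",group,100,9,100,3,100,5
breast,group,100,5,100,3,100,5
colorectal,group,70,9,90,3,25,5
gallbladder,group,33,9,66,3,50,5
kaposi's sarcoma,group,0,0,70,3,50,5
liver,group,5,10,20,3,20,5
lung,group,25,10,50,3,90,5
melanoma of skin,group,100,3,50,3,50,5
esophagus,group,20,9,90,3,90,5
pancreas,group,10,10,50,5,50,5
stomach,group,33,5,66,3,50,5
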