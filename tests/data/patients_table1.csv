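patient_id,age,sex,pathology,cortical_area,seizure_history,dexamethasone,levetiracetam,hemisphere,lobe
P01,50.0,M,temporal lobe epilepsy,right inferior temporal gyrus,within_1y,none,true,right,temporal
P02,36.0,F,germinoma,right superior frontal gyrus,none,none,false,right,frontal
P03,43.0,M,oligodendroglioma,right inferior temporal gyrus,more_than_1y_ago,at_surgery,true,right,temporal
P04,48.0,F,metastatic adenocarcinoma,right superior frontal gyrus,none,presurgery,false,right,frontal
P05,64.0,F,glioblastoma,right inferior temporal gyrus,none,none,false,right,temporal
P06,61.0,M,glioblastoma,right middle temporal gyrus,none,at_surgery,true,right,temporal
P07,57.0,M,glioblastoma,right middle frontal gyrus,none,at_surgery,true,right,frontal
P08,56.0,F,meningioma,right middle temporal gyrus,within_1y,none,true,right,temporal
P09,61.0,M,glioblastoma,left middle temporal gyrus,within_1y,presurgery,true,left,temporal
P10,54.0,M,glioblastoma,right inferior temporal gyrus,none,at_surgery,true,right,temporal
P11,38.0,F,anaplastic astrocytoma,right inferior temporal gyrus,within_1y,presurgery,true,right,temporal
P12,50.0,F,glioblastoma,left inferior temporal gyrus,within_1y,none,true,left,temporal
P13,72.0,M,metastatic carcinoma,right middle frontal gyrus,none,none,false,right,frontal
P14,64.0,M,dysembryoplastic neuroepithelial tumor,right inferior parietal lobule,none,at_surgery,false,right,parietal
P15,60.0,M,anaplastic astrocytoma,right inferior temporal gyrus,more_than_1y_ago,none,true,right,temporal
P16,42.0,M,glioblastoma,left superior parietal lobule,none,presurgery,false,left,parietal
P17,69.0,F,glioblastoma,right superior frontal gyrus,none,presurgery,false,right,frontal
P18,56.0,F,oligodendroglioma,left superior frontal gyrus,none,none,false,left,frontal
P19,45.0,F,metastatic adenocarcinoma,right superior occipital gyrus,none,presurgery,false,right,occipital
P20,53.0,M,glioblastoma,left middle temporal gyrus,none,none,true,left,temporal
P21,50.0,M,glioblastoma,right inferior frontal gyrus,none,presurgery,false,right,frontal
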