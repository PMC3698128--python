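category,item,rrms_mild,rrms_mod,rrms_sev,spms_mod,spms_sev
drug,avonex,9861,9861,0,9861,0
drug,rebif,7106,7106,0,7106,0
drug,betaferon,9176,9176,0,9176,0
drug,cbp_im_1a,3762,3762,0,3762,0
drug,cbp_sc_1a,5873,5873,0,5873,0
drug,cbp_sc_1b,7969,7969,0,7969,0
symptomatic,antidepressant_first3,2.3,2.7,3.2,2.7,3.2
symptomatic,antidepressant_other,1.5,1.8,2.2,1.8,2.2
symptomatic,anti_spasm,11.65,11.65,11.65,11.65,11.65
symptomatic,anti_fatigue,1.36,1.36,1.36,1.36,1.36
symptomatic,painkiller,4.7,6.6,9.8,23.5,29.9
nsaid,im_ifnb1a,0.15,0.15,0,0.15,0
nsaid,sc_ifnb1a,0.42,0.42,0,0.42,0
nsaid,sc_ifnb1b,0.53,0.53,0,0.53,0
other_direct_medical,laboratory,13,13,0,13,0
other_direct_medical,imaging,103,103,0,103,0
other_direct_medical,physician_visits,45,32,14,32,14
other_direct_medical,physiotherapy,0,15,326,15,326
other_direct_medical,psychotherapy,6,64,0,64,0
other_direct_medical,nursing,0,41,816,41,816
other_direct_medical,mobility_aids,0,48,387,48,387
other_direct_medical,total,167,316,1543,316,1543
non_medical_direct,transport,266,373,40,373,40
non_medical_direct,house_reconstruction,0,0,1529,0,1529
non_medical_direct,car_rebuilding,0,1468,1468,1468,1468
non_medical_direct,total,266,1841,3037,1841,3037
indirect,absence_from_work,71,120,0,65,0
indirect,unemployment_retirement,7,0,616,308,740
indirect,mortality,12,10,0,6,0
indirect,total,90,130,616,379,740
relapse,medical_treatment,27,27,27,45,45
relapse,hospitalization,6,6,6,9,9
relapse,total,33,33,33,54,54
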