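parameter,natural_history,im_ifnb1a,sc_ifnb1a,sc_ifnb1b
p_rrms_mild_to_mod,0.4,0.219,0.193,0.2
p_rrms_mod_to_sev,0.27,0.11,0.115,0.15
p_rrms_mod_to_spms_mod,0.43,0.43,0.197,0.433
p_rrms_sev_to_spms_sev,0.31,0.31,0.31,0.31
p_spms_mod_to_sev,0.5,0.3,0.5,0.4
relapse_rate_rrms_cycle1,2.54,1.34,1.73,1.68
relapse_rate_rrms_other,2.04,1.31,1.18,1.01
relapse_rate_spms,0.7,0.47,0.5,0.35
wd_rrms_mild_cycles_1_2,,0.04,0.078,0.086
wd_rrms_mild_other,,0.04,0.05,0.09
wd_rrms_mod_cycle_2,,0.26,0.42,0.247
wd_rrms_mod_other,,0.04,0.05,0.09
wd_spms_mod_all,,0.19,0.357,0.25
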