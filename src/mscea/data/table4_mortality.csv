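age_lo,age_hi,mortality_rate_pct
30,35,7.69
36,40,7.61
41,45,8.29
46,50,10.17
51,55,12.71
56,60,14.19
61,65,16.2
66,70,18.9
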