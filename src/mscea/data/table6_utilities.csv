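state,literature,vas,eq5d,hui3
rrms_mild,0.68,0.79,0.76,0.68
rrms_mod,0.52,0.62,0.57,0.41
spms_mod,0.52,0.58,0.52,0.18
rrms_sev,0.17,0.38,0.18,0.08
spms_sev,0.17,0.18,0.02,0.06
relapse_loss,0.5,0.42,0.42,0.42
death,0,0,0,0
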