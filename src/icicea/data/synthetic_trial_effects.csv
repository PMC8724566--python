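trial_id,treatment,comparator,hr,ci_low,ci_high
SYNTH-A1,cemiplimab,chemotherapy,0.57,0.42,0.77
SYNTH-B1,pembrolizumab,chemotherapy,0.67,0.51,0.89
SYNTH-B2,pembrolizumab,chemotherapy,0.69,0.56,0.85
SYNTH-C1,atezolizumab,chemotherapy,0.59,0.4,0.89
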