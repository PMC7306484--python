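label,age_days,height_cm,weight_kg,hematocrit_pct,bsa_m2
1 day,1,49.75,3.55,56,0.22
1 month,30.4375,54.25,4.3,44,0.25
3 months,91.3125,60,5.75,35.5,0.31
6 months,182.625,66,7.55,36,0.37
1 year,365.25,74.75,9.9,36,0.46
2 years,730.5,86,12.35,36.5,0.54
5 years,1826.25,108.25,18.25,37,0.73
15 years,5478.75,166,54.25,42,1.59
Adult,12783.75,169.5,66.5,44,1.76
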