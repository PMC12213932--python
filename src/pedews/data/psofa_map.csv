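age_low_months,age_high_months,map_ll_mmhg
0,1,46
1,12,55
12,24,60
24,60,62
60,144,65
144,216,67
216,12000,70
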