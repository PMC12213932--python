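component,age_low_months,age_high_months,score,threshold,direction
respiratory,0,12000,1,292,lt
respiratory,0,12000,2,264,lt
respiratory,0,12000,3,221,lt
respiratory,0,12000,4,148,lt
coagulation,0,12000,1,150,lt
coagulation,0,12000,2,100,lt
coagulation,0,12000,3,50,lt
coagulation,0,12000,4,20,lt
hepatic,0,12000,1,20.5,ge
hepatic,0,12000,2,34.2,ge
hepatic,0,12000,3,102.6,ge
hepatic,0,12000,4,205.2,ge
neurological,0,12000,1,14,le
neurological,0,12000,2,12,le
neurological,0,12000,3,9,le
neurological,0,12000,4,5,le
renal,0,1,1,71,ge
renal,0,1,2,88,ge
renal,0,1,3,106,ge
renal,0,1,4,141,ge
renal,1,12,1,27,ge
renal,1,12,2,44,ge
renal,1,12,3,71,ge
renal,1,12,4,106,ge
renal,12,24,1,35,ge
renal,12,24,2,53,ge
renal,12,24,3,97,ge
renal,12,24,4,133,ge
renal,24,60,1,53,ge
renal,24,60,2,80,ge
renal,24,60,3,141,ge
renal,24,60,4,203,ge
renal,60,144,1,62,ge
renal,60,144,2,97,ge
renal,60,144,3,159,ge
renal,60,144,4,230,ge
renal,144,12000,1,88,ge
renal,144,12000,2,150,ge
renal,144,12000,3,256,ge
renal,144,12000,4,371,ge
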