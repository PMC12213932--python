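feature,strategy,parameter
hr,age_stratified_median,
rr,age_stratified_median,
sbp,age_stratified_median,
map,age_stratified_median,
spo2,global_median,
comfort,global_median,
crt,global_median,
fio2,assume_absent,0.21
vent_level,assume_absent,0
o2_flow,assume_absent,0
vis,assume_absent,0
dopamine,assume_absent,0
dobutamine,assume_absent,0
milrinone,assume_absent,0
epinephrine,assume_absent,0
norepinephrine,assume_absent,0
vasopressin,assume_absent,0
lactate,global_median,
platelets,global_median,
bilirubin,global_median,
creatinine,global_median,
sodium,global_median,
gcs,assume_absent,15
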