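alias,canonical,factor,priority,unit
hr_monitor,hr,1.0,1,bpm
ecg_hr,hr,1.0,2,bpm
rr_monitor,rr,1.0,1,breaths/min
abp_sys,sbp,1.0,1,mmHg
nibp_sys,sbp,1.0,2,mmHg
abp_map,map,1.0,1,mmHg
nibp_map,map,1.0,2,mmHg
spo2_monitor,spo2,1.0,1,%
comfort_score,comfort,1.0,1,score
crt_assessment,crt,1.0,1,s
fio2_device,fio2,1.0,1,fraction
vent_status,vent_level,1.0,1,ordinal
o2_flow,o2_flow,1.0,1,l/min
dopamine_rate,dopamine,1.0,1,ug/kg/min
dobutamine_rate,dobutamine,1.0,1,ug/kg/min
milrinone_rate,milrinone,1.0,1,ug/kg/min
epinephrine_rate,epinephrine,1.0,1,ug/kg/min
norepinephrine_rate,norepinephrine,1.0,1,ug/kg/min
vasopressin_rate,vasopressin,1.0,1,U/kg/min
lactate_blood,lactate,1.0,1,mmol/l
platelets_lab,platelets,1.0,1,10^9/l
bilirubin_lab,bilirubin,1.0,1,umol/l
creatinine_lab,creatinine,1.0,1,umol/l
sodium_lab,sodium,1.0,1,mmol/l
gcs_assessment,gcs,1.0,1,score
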