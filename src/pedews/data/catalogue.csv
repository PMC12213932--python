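feature,kind,centile_variable,weight_normalise
hr,timeseries,hr,0
rr,timeseries,rr,0
sbp,timeseries,sbp,0
map,timeseries,map,0
spo2,timeseries,,0
comfort,timeseries,,0
crt,timeseries,,0
fio2,timeseries,,0
vent_level,timeseries,,0
o2_flow,timeseries,,1
vis,timeseries,,0
lactate,lab,,0
platelets,lab,,0
bilirubin,lab,,0
creatinine,lab,,0
sodium,lab,,0
gcs,lab,,0
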