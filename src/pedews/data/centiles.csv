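variable,age_low_days,age_high_days,sex,c1,c10,c25,c50,c75,c90,c99
hr,0,30,any,90,107,120,140,160,175,190
hr,30,365,any,85,100,112,130,148,162,180
hr,365,730,any,75,90,100,115,130,145,165
hr,730,1825,any,65,78,88,100,115,128,145
hr,1825,4380,any,55,68,75,85,100,112,130
hr,4380,6570,any,48,58,65,75,88,100,118
rr,0,30,any,25,30,35,40,48,55,65
rr,30,365,any,22,26,30,35,42,48,58
rr,365,730,any,18,21,24,28,33,38,46
rr,730,1825,any,16,19,21,24,28,32,38
rr,1825,4380,any,13,15,17,20,23,26,32
rr,4380,6570,any,11,13,14,16,19,22,28
sbp,0,30,any,50,58,63,70,78,85,95
sbp,30,365,any,62,72,78,85,93,100,112
sbp,365,730,any,68,77,83,90,98,106,118
sbp,730,1825,any,72,82,88,95,104,112,125
sbp,1825,4380,any,80,90,97,105,114,122,136
sbp,4380,6570,any,88,99,106,115,125,134,148
map,0,30,any,35,42,46,50,56,62,72
map,30,365,any,43,50,55,60,66,72,82
map,365,730,any,48,55,59,65,71,77,88
map,730,1825,any,50,58,62,68,75,81,92
map,1825,4380,any,54,62,66,72,79,86,98
map,4380,6570,any,58,67,72,78,86,93,106
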