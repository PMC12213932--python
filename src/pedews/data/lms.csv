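measure,sex,age_days,L,M,S
weight,any,0,-0.2,3.4,0.14
weight,any,30,-0.2,4.4,0.14
weight,any,91,-0.2,5.8,0.13
weight,any,182,-0.2,7.5,0.13
weight,any,365,-0.2,9.5,0.12
weight,any,548,-0.2,10.8,0.12
weight,any,730,-0.2,12.0,0.12
weight,any,1095,-0.2,14.2,0.12
weight,any,1460,-0.2,16.3,0.13
weight,any,1825,-0.2,18.3,0.13
weight,any,2555,-0.2,22.4,0.14
weight,any,3285,-0.2,27.0,0.15
weight,any,4015,-0.2,32.5,0.16
weight,any,4380,-0.2,38.0,0.16
weight,any,5110,-0.2,46.0,0.16
weight,any,5840,-0.2,54.0,0.15
weight,any,6570,-0.2,61.0,0.14
height,any,0,1.0,50,0.04
height,any,30,1.0,54,0.04
height,any,91,1.0,60,0.04
height,any,182,1.0,66,0.04
height,any,365,1.0,75,0.04
height,any,548,1.0,81,0.04
height,any,730,1.0,86,0.04
height,any,1095,1.0,95,0.04
height,any,1460,1.0,102,0.04
height,any,1825,1.0,109,0.045
height,any,2555,1.0,121,0.045
height,any,3285,1.0,131,0.05
height,any,4015,1.0,140,0.05
height,any,4380,1.0,150,0.05
height,any,5110,1.0,160,0.05
height,any,5840,1.0,168,0.045
height,any,6570,1.0,172,0.04
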