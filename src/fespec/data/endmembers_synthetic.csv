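water_mass,T,S,O2,PO4,NO3NO2,SiO4
ESSW,12.5,34.90,25,2.20,26,25
SAMW,8.5,34.55,250,1.40,18,8
AAIW,4.5,34.30,280,1.90,28,30
UCDW,2.5,34.60,170,2.30,35,90
PDW,1.8,34.65,120,2.60,38,140
LCDW,1.2,34.72,190,2.20,33,125
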