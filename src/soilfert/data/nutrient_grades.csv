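# Six-grade soil-nutrient classification fixture (grade 1 = most fertile).
# Boundary values follow the thresholds commonly cited from the Chinese
# national soil-survey six-level nutrient classification; they are a
# configurable fixture, not an authoritative transcription -- edit freely
# or point the pipeline at your own standard file.
index,units,orientation,b1,b2,b3,b4,b5
SOM,%,higher_is_better,4.0,3.0,2.0,1.0,0.6
N_total,%,higher_is_better,0.2,0.15,0.1,0.075,0.05
P_total,%,higher_is_better,0.1,0.08,0.06,0.04,0.02
N_hydro,mg/kg,higher_is_better,150,120,90,60,30
P_avail,mg/kg,higher_is_better,40,20,10,5,3
K_avail,mg/kg,higher_is_better,200,150,100,50,30
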