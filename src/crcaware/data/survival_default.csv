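# Synthetic stage-specific CRC survival fixture (NOT published values).
# Annual CRC-death probability by Dukes' stage and year since diagnosis;
# "beyond" applies after year 5. Chosen so 5-year survival is ~94/81/48/10%
# for stages A-D, worsening strictly A -> D in every year band.
stage,year1,year2,year3,year4,year5,beyond
A,0.020,0.015,0.012,0.010,0.008,0.005
B,0.060,0.050,0.040,0.030,0.020,0.010
C,0.170,0.140,0.110,0.080,0.060,0.030
D,0.550,0.450,0.350,0.250,0.200,0.150
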