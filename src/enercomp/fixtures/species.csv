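species,guild,mean_mass_g
DS,kangaroo_rat,120.0
DM,kangaroo_rat,43.0
DO,kangaroo_rat,49.0
BA,small_granivore,8.0
PB,small_granivore,31.0
PH,small_granivore,31.0
PI,small_granivore,15.0
PP,small_granivore,17.0
PF,small_granivore,7.5
PE,small_granivore,20.0
PL,small_granivore,20.0
PM,small_granivore,22.0
RF,small_granivore,12.0
RM,small_granivore,10.5
RO,small_granivore,10.0
OT,other,24.0
OL,other,31.0
SH,other,70.0
SF,other,50.0
NEO,other,150.0
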