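species,phase,dgf_kj_per_mol,source
CH4,gas,-50.8,CRC standard thermodynamic properties
C2H6,gas,-32.0,CRC standard thermodynamic properties
C3H8,gas,-23.4,CRC standard thermodynamic properties
C4H10,gas,-17.0,CRC standard thermodynamic properties (n-butane)
CO2,gas,-394.36,CRC standard thermodynamic properties
CO2,aqueous,-386.0,biochemical compilation (Thauer-type)
H2O,liquid,-237.18,CRC standard thermodynamic properties
NO3-,aqueous,-111.3,biochemical compilation (Thauer-type)
NO2-,aqueous,-37.2,biochemical compilation (Thauer-type)
NH4+,aqueous,-79.37,biochemical compilation (Thauer-type)
N2,gas,0.0,reference-state element
H2,gas,0.0,reference-state element
O2,gas,0.0,reference-state element
H+,aqueous,0.0,convention (standard state 1 M)
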