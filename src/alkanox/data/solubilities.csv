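species,h_cp_mol_per_l_atm,vant_hoff_K,source
CH4,1.4e-3,1700,Sander Henry's-law compilation
C2H6,1.9e-3,2400,Sander Henry's-law compilation
C3H8,1.5e-3,2700,Sander Henry's-law compilation
C4H10,1.2e-3,3100,Sander Henry's-law compilation (n-butane)
CO2,3.3e-2,2400,Sander Henry's-law compilation
N2,6.4e-4,1300,Sander Henry's-law compilation
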