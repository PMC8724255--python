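# Tabulated generating thermodynamics for the dye/receptor/Zn/pyrophosphate
# sensing network.  Stoichiometry columns are over the component basis
# (ARS, 1, PPi, H, Zn); dH in J/mol, dS in J/(mol K).  The hydroxide-
# containing species carries proton coefficient -1 and its tabulated
# thermodynamics are read directly in that convention (basis=OH would
# instead compose the entry with the water autoprotolysis step at load).
species,ARS,1,PPi,H,Zn,dH,dS,basis,source
HARS,1,0,0,1,0,54334,393,H,protonation
H2ARS,1,0,0,2,0,52047,500,H,protonation
H1,0,1,0,1,0,44813,326,H,protonation
H21,0,1,0,2,0,64878,531,H,protonation
HPPi,0,0,1,1,0,55206,369,H,protonation
H2PPi,0,0,1,2,0,115430,704,H,protonation
H3PPi,0,0,1,3,0,101380,700,H,protonation
H4PPi,0,0,1,4,0,123460,806,H,protonation
ZnPPi,0,0,1,0,1,86322,441,H,zinc
ZnOHPPi,0,0,1,-1,1,99370,326,H,zinc
ZnHPPi,0,0,1,1,1,104390,625,H,zinc
ZnARS,1,0,0,0,1,102380,522,H,zinc
ZnARS2,2,0,0,0,1,34127,406,H,zinc
1Zn,0,1,0,0,1,80299,413,H,zinc
H1Zn,0,1,0,1,1,120450,709,H,zinc
H21Zn,0,1,0,2,1,100370,726,H,zinc
H31ZnPPi,0,1,1,3,1,100370,949,H,ternary
H3ARS1,1,1,0,3,0,104350,880,H,assembly
H2ARS1a,1,1,0,2,0,71633,691,H,assembly
H2ARS1b,1,1,0,2,0,37845,571,H,assembly
HARS1a,1,1,0,1,0,28935,351,H,assembly
H2ARS1Znc,1,1,0,2,1,100370,846,H,assembly
H4ARS1ZnPPia,1,1,1,4,1,100370,1269,H,ternary
H4ARS1ZnPPib,1,1,1,4,1,130490,1364,H,ternary
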