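# Default EJ2 + SR8 co-culture scenario: fitted weighing factors and the
# reference initial conditions (40 g/L of each sugar, 0.45 g DCW/L of each
# strain).  share_exponent is the single calibration constant of the
# coupling reconstruction, fixed against the published mixed-culture
# ethanol shortfall (single-strain sum = 1.38 x co-culture ethanol at the
# reference condition); 1.0 would give plain sugar-fraction x
# inoculum-fraction share factors.
ej2: ej2.yaml
sr8: sr8.yaml
r1: 3.75
r2: 1.76
r3: 1.44
r4: 2.48
r5: 1.82
r6: 4.29
S0_c: 40.0
S0_x: 40.0
X0_E: 0.45
X0_S: 0.45
share_exponent: 0.983
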