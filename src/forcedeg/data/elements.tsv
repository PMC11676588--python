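# forcedeg element mass table, v1
# symbol	monoisotopic_mass_Da	nominal_mass_Da	valence
# Monoisotopic masses: most abundant isotope, CODATA/IUPAC values.
# The special row "e-" carries the electron rest mass (valence/nominal 0).
H	1.00782503207	1	1
C	12.0	12	4
N	14.00307400443	14	3
O	15.99491461956	16	2
P	30.97376199842	31	3
S	31.9720711744	32	2
Na	22.98976928	23	1
Cl	34.968852682	35	1
e-	0.000548579909	0	0
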