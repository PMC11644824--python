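# Monoisotopic masses of the most abundant isotope (Da), CODATA/NIST.
# symbol	mass
H	1.00782503207
C	12.0
N	14.00307400
O	15.99491462
S	31.97207100
Na	22.98976928
P	30.97376163
F	18.99840322
Cl	34.96885268
K	38.96370668
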