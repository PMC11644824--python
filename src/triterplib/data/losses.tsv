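# Neutral losses observed in positive-mode triterpenoid MS2.
# Masses are computed from the formula at load time, never hard-coded.
# C5H8O2: dimethylacryloyl-type ester loss. C4H8: alkene elimination from alkyl esters.
# label	formula
H2O	H2O
CO	CO
HCOOH	CH2O2
C5H8O2	C5H8O2
C4H8	C4H8
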