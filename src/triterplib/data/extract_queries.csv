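# Plant-extract query features, transcribed from the published screening
# table (source, query RT, fragment ion list). The source table prints no
# precursor m/z; the precursor here is the library calc m/z of the matched
# (compound, adduct) — the value the vendor search matched within 0.005 Da.
# Label mapping: the published rows "Silymin_[Na]" and "Silymin A_[Na]" both
# map to the library compound "Silymin A" (the three-compound total implies
# they are the same standard).
# Background ions with strongly negative mass defects (220.9341, 288.9212,
# ...) are transcribed verbatim; they cannot be triterpenoid fragments.
source,rt,precursor_mz,adduct,fragments,expected_compound,printed_drift
Peganum harmala,10.53,575.4095,[M+H]+,220.9341,β-Neriursate,0.2
Camellia sinensis,11.18,527.4095,[M+H]+,425.3459;288.9212;220.9335;189.1656;175.1472;149.0973,Butyl ester of glycyrrhetinic acid,0.3
Aegle marmelos,9.94,597.3914,[M+Na]+,509.2737;288.9202;259.1144;215.0896;171.0639;155.0685,β-Neriursate,0.41
Adhatoda vasica,9.95,507.3081,[M+Na]+,421.2227;390.2389;243.1232;155.0704,Silymin A,0.08
Papaver somniferum,9.97,507.3081,[M+Na]+,155.0693,Silymin A,0.06
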