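# Positive-mode adducts. delta_mass is added to the neutral monoisotopic mass.
# [M+H]+  : proton mass.
# [M+Na]+ : Na atom minus one electron (sodium cation).
# name	delta_mass	charge
[M+H]+	1.00727646	1
[M+Na]+	22.98922070	1
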