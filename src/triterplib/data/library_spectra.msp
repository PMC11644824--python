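Name: β-Neriursate
Formula: C38H54O4
PrecursorMZ: 575.4095
Adduct: [M+H]+
RT: 10.35
SkeletonClass: ursane
CE: ramp 25.0-62.5
Mode: auto
Num Peaks: 4
220.9341 1000.0
529.4040 300.0
557.3989 200.0
575.4095 150.0

Name: β-Neriursate
Formula: C38H54O4
PrecursorMZ: 597.3914
Adduct: [M+Na]+
RT: 10.35
SkeletonClass: ursane
CE: ramp 25.0-62.5
Mode: auto
Num Peaks: 6
155.0685 850.0
171.0639 620.0
215.0896 540.0
259.1144 410.0
288.9202 900.0
509.2737 1200.0

Name: Butyl ester of glycyrrhetinic acid
Formula: C34H54O4
PrecursorMZ: 527.4095
Adduct: [M+H]+
RT: 10.89
SkeletonClass: oleanane
CE: 10
Mode: targeted
Num Peaks: 3
425.3459 300.0
509.3989 150.0
527.4095 5000.0

Name: Butyl ester of glycyrrhetinic acid
Formula: C34H54O4
PrecursorMZ: 527.4095
Adduct: [M+H]+
RT: 10.89
SkeletonClass: oleanane
CE: 20
Mode: targeted
Num Peaks: 3
189.1656 400.0
425.3459 1800.0
527.4095 900.0

Name: Butyl ester of glycyrrhetinic acid
Formula: C34H54O4
PrecursorMZ: 527.4095
Adduct: [M+H]+
RT: 10.89
SkeletonClass: oleanane
CE: 30
Mode: targeted
Num Peaks: 4
175.1472 700.0
220.9335 450.0
288.9212 520.0
425.3459 600.0

Name: Butyl ester of glycyrrhetinic acid
Formula: C34H54O4
PrecursorMZ: 527.4095
Adduct: [M+H]+
RT: 10.89
SkeletonClass: oleanane
CE: 40
Mode: targeted
Num Peaks: 3
149.0973 950.0
175.1472 800.0
189.1656 350.0

Name: Silymin A
Formula: C30H44O5
PrecursorMZ: 507.3081
Adduct: [M+Na]+
RT: 9.9
SkeletonClass: ursane
CE: ramp 25.0-62.5
Mode: auto
Num Peaks: 4
155.0699 1400.0
243.1232 380.0
390.2389 520.0
421.2227 760.0
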