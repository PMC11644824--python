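# Methods

## Mass arithmetic

Element monoisotopic masses are CODATA/NIST values shipped as a plain-text
table (`data/elements.tsv`): H 1.00782503207, C 12 (exact), N 14.003074,
O 15.99491462, S 31.972071, Na 22.98976928, plus P/F/Cl/K for generality.
Adduct deltas (`data/adducts.tsv`) follow cation conventions: `[M+H]+` adds
the proton mass (1.00727646 Da), not the hydrogen-atom mass; `[M+Na]+` adds
the sodium atom minus one electron (22.98922070 Da). With these constants
every internally consistent calculated m/z in the reference table reproduces
to ±0.0002 Da.

Two printed-data quirks are handled explicitly rather than silently:

* One compound row ("Oleanoic acid") prints a protonated calc m/z that
  contradicts its own formula and sodium row. The builder always recomputes
  calc m/z from the formula and surfaces such rows as warnings carrying the
  row identity; `--strict` turns them into a non-zero exit.
* Roughly half the printed ppm errors cannot be derived from the printed
  calc/meas pairs at any rounding — they were evidently computed from
  unprinted extra decimals. The reproducible convention is: round the
  calculated m/z to 4 decimals first, then
  `(calc − meas)/calc × 1e6`, rounded half-away-from-zero to 1 decimal
  (measured above calculated ⇒ negative). The 37 self-consistent rows all
  reproduce exactly under it; the inconsistent ones are excluded from
  assertions.

The formula parser accepts plain (`C30H46O4`) and underscore-subscript
(`C_30_H_46_O_4_`, `S_1_`) notation, with implicit count 1; parse →
Hill-order serialize → parse is the identity, and mass is additive over
formula union (property-tested).

## Library model and formats

A record = compound metadata (name, formula, Log p, RT, skeleton class) +
observed adducts (calc/meas m/z) + CE-indexed MS2 spectra. Skeleton class is
curated input, not inferred: the published census (18 oleanane, 14 ursane,
6 lupane, 1 friedelane, 4 limonoid, 1 unknown) refers to 44 standards while
the table prints 43 rows; our assignments tally 18/13/6/1/4/1, so the
missing row was presumably an ursane — recorded as a fixture provenance note
and never asserted.

The format of record is a versioned JSON archive that round-trips every
field bit-exactly (property-tested on 100 random libraries); MSP (NIST text
dialect) and MGF (via pyteomics) serve exchange. The MSP reader reports
malformed entries by ordinal and rejects peak blocks that contradict
`Num Peaks`; matchms is used in tests as an independent MSP reader to
cross-check the writer. The library's search index holds every record under
*every* configured adduct with m/z recomputed from the formula, because a
query may present an adduct that was not intense enough to be recorded when
the standard was measured (this is exactly how the sodium-adduct
identification in one extract arises).

Consensus spectra merge multi-CE acquisitions by single-linkage gap
clustering on sorted m/z (gap > tolerance starts a new cluster), reporting
intensity-weighted mean m/z and the **maximum** intensity across energies —
max (not mean) preserves diagnostic fragments that only appear at one
energy. Gap clustering guarantees adjacent output peaks exceed the
tolerance, making consensus idempotent, and coincides with all-pairs
transitive clustering on sorted data (oracle-tested).

## Fragment annotation

Neutral-loss series enumerate multisets of losses up to a depth (default 3
for annotation), deduplicated by total mass — H2O+CO and HCOOH coincide to a
micro-dalton and collapse to the fewer-loss label. The default loss table is
H2O, CO, HCOOH, C5H8O2 and C4H8; the alkene loss is included because alkyl
esters of triterpenoid acids eliminate the ester alkene before losing formic
acid (the butyl ester's measured m/z 425.3459 is `[M+H−C4H8−HCOOH]+`,
calc 425.3414). The annotation tolerance defaults to 0.01 Da — wider than
the 0.005 Da identification tolerance — because published measured fragment
values deviate from exact subtraction by up to ~0.011 Da; it is
configurable. Diagnostic RDA ions known to 4 decimals are matched at the Da
tolerance; those known only nominally (191/203/205) at ±0.5 Da. Matching is
greedy nearest-ion per peak with parsimony tie-break (fewer losses); it is
stable under peak permutation because spectra are kept m/z-sorted.

The electron-mass convention behind the 4-decimal RDA values (cation vs
neutral mass, ~0.0005 Da) is ambiguous in the source; they are matched at
the configured tolerance rather than resolved. Query fragment lists also
contain background ions with strongly negative mass defects (e.g. 220.9341)
that cannot be triterpenoid fragments; they are stored verbatim in the
curated spectra (so screening reproduces the published matches) but excluded
from annotation reasoning.

## Matching and screening

Defaults: precursor tolerance 0.005 Da (the published screening tolerance,
also reused for fragments as the conservative reading), RT window 0.5 min
(the source states only the observed maximum drift, 0.41 min; 0.5 covers it
with margin), `min_fragments` 1 (one published identification rests on a
single fragment ion). Level 1 = precursor ∧ RT ∧ fragments; level 2 =
precursor ∧ fragments; level 3 = precursor only. Ranking is by level, then
score (fraction of consensus peaks explained), then |ppm error|, then
|RT drift|, with a final name tie-break; RT proximity is included because
libraries legitimately contain isomers with identical formula and class
whose spectra are indistinguishable — retention time is then the only
discriminating evidence. Reported drift is unsigned, rounded to 2 decimals.
Unique-compound counts collapse adduct variants through the record name.

The screening fixture's precursors are the library calc m/z of the matched
(compound, adduct): the published feature table prints RTs and fragment
lists but no precursor values. Its two "Silymin"-labelled rows map to the
single library standard Silymin A, which the three-compound total implies.
The curated MSP spectra for the four identified (compound, adduct) pairs are
synthetic, built from exactly the published fragment lists.

## DDA simulator

Each (record, observed adduct) elutes as a Gaussian of σ 0.05 min centred at
the library RT plus a per-run drift. Per MS1 cycle (5 Hz), precursors above
the 1000-count threshold and not excluded trigger MS2, top-N per cycle with
N = floor(12 Hz / 5 Hz) = 2. Active exclusion — whose vendor semantics
(spectra per precursor vs precursors per cycle, release rule) are not fully
specified — is implemented as the simplest reading: excluded after 3
selections, released after one full cycle below threshold; an event-log
audit re-derives the rule from the stored run and is asserted on every
simulation. Fixed-CE mode walks 10 → 20 → 30 → 40 eV across successive
selections of the same precursor; ramp mode emits a single ramp-labelled
spectrum treated as the consensus of the fixed energies (the true intensity
dependence on energy is not modelled quantitatively).

Noise defaults (chosen once, on chromatographic/QTOF grounds): m/z jitter
σ 0.001 Da (~2 ppm at m/z 500), RT jitter σ 0.01 min — replicate-injection
repeatability on a 13-min UHPLC gradient; larger cross-matrix drift (like
the 0.41 min seen between extracts and standards) is a systematic effect the
matcher's RT window absorbs, and tests probing it pass explicit noise —
apex intensities log-normal (median 5 × 10⁴ counts, σ 0.8), background
decoy peaks Poisson (2 per MS1 scan, log-normal intensities, median 400).
Records without measured spectra receive deterministic theoretical
product-ion spectra (loss series + class diagnostics with an energy-
dependent intensity profile); these are stand-ins with the right peak
positions, not predictions of real intensities.

Feature export emulates extracted-ion-chromatogram feature generation: a
compound feature takes its RT from the MS1 apex and its precursor as the
MS1 intensity-weighted mean; fragments are the consensus of its MS2 events.
Grouping uses the simulator's own species identity — vendor feature-finding
is out of scope, so the simulator does not test it. Decoy events become
single-event features.

What passing the recovery experiments shows — and does not. Simulated runs
contain co-eluting isobars, dynamic-exclusion censoring, jitter and random
background, so recovering ≥95% of above-threshold compounds exercises the
index, tolerances, consensus matching and level logic end to end. They do
not contain chimeric MS2 spectra, matrix ion suppression, peak tailing or
real intensity structure, so the experiments say nothing about those
failure modes on real data.

## Problem sizes and numerical choices

Default simulations cover the elution span of the 43-standard library
(~1400 MS1 cycles, ~700 MS2 events, under a second per run); the recovery
acceptance averages 10 seeded runs. Random-library round-trip uses 100
libraries; index-vs-scan equivalence 200 queries; loss-series combinatorics
depths 1–4. Display rounding is half-away-from-zero (4 decimals m/z, 1 ppm,
2 RT drift), matching printed-table conventions. Degenerate inputs are
errors, not guesses: empty formulas, unknown elements/adducts/classes,
non-positive tolerances, empty libraries for simulation, precursor
disagreement in consensus building.

## Known limitations

No isotope patterns, multiple charging or negative mode; no in-silico
bond-breaking fragmentation (rules are class-level); friedelane/limonoid
diagnostic ions are a documented gap; no FDR estimation or quantification;
MSP/MGF round trips are lossy for record-level metadata (the JSON archive is
the lossless format); the simulator emits centroided peak lists only.
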