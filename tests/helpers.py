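"""Shared test utilities: random-library generation and equality."""

import random

from triterplib.chem import ADDUCTS, adduct_mz, parse_formula
from triterplib.library import (
    AdductEntry,
    LibraryRecord,
    SpectralLibrary,
    _record_to_dict,
)
from triterplib.spectra import Spectrum


def lib_equal(a: SpectralLibrary, b: SpectralLibrary) -> bool:
    return [_record_to_dict(r) for r in a.records] == [_record_to_dict(r) for r in b.records]


def random_library(rng: random.Random) -> SpectralLibrary:
    records = []
    for i in range(rng.randint(1, 3)):
        c, h, o = rng.randint(10, 40), rng.randint(20, 60), rng.randint(1, 8)
        formula = parse_formula(f"C{c}H{h}O{o}")
        adduct = rng.choice(list(ADDUCTS))
        rec = LibraryRecord(
            name=f"compound-{i}",
            formula=formula,
            logp=round(rng.uniform(0, 12), 2),
            rt=round(rng.uniform(5, 12), 2),
            skeleton_class=rng.choice(["oleanane", "ursane", "lupane", "other"]),
        )
        prec = adduct_mz(formula, adduct)
        rec.adducts.append(
            AdductEntry(adduct=adduct, calc_mz=prec, meas_mz=prec + rng.uniform(-2e-3, 2e-3))
        )
        for ce in ("10", "20")[: rng.randint(0, 2)]:
            peaks = sorted(
                {round(rng.uniform(60, prec), 4): round(rng.uniform(1, 1e4), 2)
                 for _ in range(rng.randint(1, 6))}.items()
            )
            rec.spectra.append(
                Spectrum(peaks=peaks, precursor_mz=prec, adduct=adduct,
                         collision_energy=ce, compound=rec.name)
            )
        records.append(rec)
    return SpectralLibrary(records=records, provenance="random")
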