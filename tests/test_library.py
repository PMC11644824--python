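"""Library building, archive/MSP/MGF round trips, and the precursor index."""

import random

import numpy as np
import pandas as pd
import pytest

from triterplib.chem import ADDUCTS, adduct_mz, parse_formula
from triterplib.library import (
    LibraryError,
    LibraryRecord,
    SpectralLibrary,
    _record_to_dict,
    build_library,
    read_library,
    write_library,
)
from triterplib.spectra import Spectrum


from helpers import lib_equal as _lib_equal, random_library as _random_library


def test_reference_library_has_43_records(reference_library):
    assert len(reference_library.records) == 43
    names = [r.name for r in reference_library.records]
    assert len(set(names)) == 43


def test_inconsistent_calc_mz_is_warned_not_fixed(reference_library):
    """The internally inconsistent row (formula says 455.3520, table prints
    457.3676) must surface as a warning, and the recomputed value wins."""
    assert any("Oleanoic acid" in w for w in reference_library.warnings)
    rec = reference_library["Oleanoic acid"]
    h = next(e for e in rec.adducts if e.adduct == "[M+H]+")
    assert h.calc_mz == pytest.approx(455.3520, abs=2e-4)


def test_build_library_ms1_only():
    df = pd.DataFrame(
        {"name": ["a"], "formula": ["C30H48O3"], "logp": [9.0], "rt": [10.5],
         "adduct": ["[M+H]+"]}
    )
    lib = build_library(df)
    assert len(lib) == 1
    assert lib.records[0].spectra == []
    assert lib.records[0].adducts[0].calc_mz == pytest.approx(457.3676, abs=2e-4)


def test_build_library_rejects_conflicting_duplicates():
    df = pd.DataFrame(
        {"name": ["a", "a"], "formula": ["C30H48O3", "C30H46O3"],
         "logp": [9.0, 9.0], "rt": [10.5, 10.5], "adduct": ["[M+H]+", "[M+Na]+"]}
    )
    with pytest.raises(LibraryError, match="conflicting formula"):
        build_library(df)
    df2 = pd.DataFrame(
        {"name": ["a", "a"], "formula": ["C30H48O3", "C30H48O3"],
         "logp": [9.0, 9.0], "rt": [10.5, 10.5], "adduct": ["[M+H]+", "[M+H]+"]}
    )
    with pytest.raises(LibraryError, match="duplicate adduct"):
        build_library(df2)


def test_build_library_names_bad_formula_row():
    df = pd.DataFrame(
        {"name": ["ok", "bad"], "formula": ["C30H48O3", "C30Q"], "logp": [1, 1],
         "rt": [1.0, 2.0], "adduct": ["[M+H]+", "[M+H]+"]}
    )
    with pytest.raises(LibraryError, match="bad"):
        build_library(df)


# ---------------------------------------------------------------------------
# round trips


def test_archive_round_trip_random_libraries(tmp_path):
    """Archive write -> read is the identity on 100 random libraries."""
    rng = random.Random(2024)
    for k in range(100):
        lib = _random_library(rng)
        path = tmp_path / f"lib{k}.json"
        write_library(lib, path, "archive")
        assert _lib_equal(read_library(path), lib)


def test_archive_round_trip_reference(reference_library, tmp_path):
    path = tmp_path / "ref.json"
    write_library(reference_library, path, "archive")
    assert _lib_equal(read_library(path), reference_library)


def test_write_empty_library_refused(tmp_path):
    with pytest.raises(LibraryError):
        write_library(SpectralLibrary(), tmp_path / "x.json")


def test_msp_format_contract(tmp_path):
    rec = LibraryRecord(name="x", formula=parse_formula("C30H48O3"), rt=10.5)
    rec.spectra.append(
        Spectrum(peaks=[(100.0, 1.0), (200.0, 2.0), (300.0, 3.0)],
                 precursor_mz=457.3676, adduct="[M+H]+", collision_energy="20",
                 compound="x")
    )
    from triterplib.library import AdductEntry

    rec.adducts.append(AdductEntry("[M+H]+", 457.3676))
    path = tmp_path / "one.msp"
    write_library(SpectralLibrary(records=[rec]), path, "msp")
    text = path.read_text()
    assert "Num Peaks: 3" in text
    back = read_library(path)
    assert back.records[0].spectra[0].peaks == rec.spectra[0].peaks
    assert back.records[0].rt == 10.5


def test_msp_round_trip_reference(reference_library, tmp_path):
    path = tmp_path / "ref.msp"
    write_library(reference_library, path, "msp")
    back = read_library(path)
    with_spectra = [r for r in reference_library.records if r.spectra]
    assert len(back.records) == len(with_spectra)
    for orig in with_spectra:
        got = back[orig.name]
        assert [s.peaks for s in got.spectra] == [s.peaks for s in orig.spectra]
        assert got.skeleton_class == orig.skeleton_class


def test_msp_cross_checked_with_matchms(reference_library, tmp_path):
    """Independent reader: matchms parses our MSP into the same peak lists."""
    matchms = pytest.importorskip("matchms")
    from matchms.importing import load_from_msp

    path = tmp_path / "ref.msp"
    write_library(reference_library, path, "msp")
    theirs = list(load_from_msp(str(path), metadata_harmonization=False))
    ours = [s for r in reference_library.records for s in r.spectra]
    assert len(theirs) == len(ours)
    for ms, s in zip(theirs, ours):
        assert np.allclose(ms.peaks.mz, [m for m, _ in s.peaks])


def test_msp_missing_rt_is_tolerated(tmp_path):
    path = tmp_path / "nort.msp"
    path.write_text(
        "Name: y\nFormula: C30H48O3\nPrecursorMZ: 457.3676\nNum Peaks: 1\n100.0 1.0\n"
    )
    lib = read_library(path)
    assert lib.records[0].rt is None  # still usable for mass-only matching
    assert lib.query_precursor(457.3676, 0.005)


def test_msp_truncation_and_count_mismatch_error(tmp_path):
    bad = tmp_path / "bad.msp"
    bad.write_text("Name: y\nFormula: C30H48O3\nNum Peaks: 3\n100.0 1.0\n")
    with pytest.raises(LibraryError, match="entry 1"):
        read_library(bad)


def test_mgf_round_trip_and_precursor_line(reference_library, tmp_path):
    path = tmp_path / "ref.mgf"
    write_library(reference_library, path, "mgf")
    text = path.read_text()
    # precursor lines equal the record calc m/z to 4 decimals
    assert "PEPMASS=575.4095" in text
    assert "PEPMASS=527.4095" in text
    back = read_library(path)
    orig = [r for r in reference_library.records if r.spectra]
    assert len(back.records) == len(orig)
    for o in orig:
        got = back[o.name]
        assert [s.peaks for s in got.spectra] == [s.peaks for s in o.spectra]
        assert got.rt == pytest.approx(o.rt)


def test_unknown_format_rejected(reference_library, tmp_path):
    with pytest.raises(ValueError):
        write_library(reference_library, tmp_path / "x.bin", "vendor")
    with pytest.raises(ValueError):
        read_library(tmp_path / "x.unknown")


def test_corrupt_archive_is_an_error_not_partial_load(tmp_path):
    path = tmp_path / "trunc.json"
    import json

    full = json.dumps({"format": "triterplib-archive", "version": 1, "records": []})
    path.write_text(full[: len(full) // 2])
    with pytest.raises(LibraryError):
        read_library(path)


# ---------------------------------------------------------------------------
# precursor index


def test_query_precursor_matches_brute_force(reference_library):
    """Sorted-index range queries agree with an exhaustive scan (200 random)."""
    lib = reference_library
    rng = np.random.default_rng(7)
    masses = [t[0] for t in lib.index()]
    queries = np.concatenate(
        [rng.uniform(400, 700, 150), rng.choice(masses, 50) + rng.normal(0, 0.003, 50)]
    )
    for q in queries:
        got = {(r.name, a) for r, a, _ in lib.query_precursor(float(q), 0.005)}
        brute = set()
        for rec in lib.records:
            for name in ADDUCTS:
                if abs(adduct_mz(rec.formula, name) - q) <= 0.005:
                    brute.add((rec.name, name))
        assert got == brute
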