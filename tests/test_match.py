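"""Precursor/RT/fragment matching, identification levels, and screening."""

import numpy as np
import pytest

from triterplib.chem import ADDUCTS, adduct_mz
from triterplib.match import (
    MatchParameters,
    QueryFeature,
    match_feature,
    match_precursor,
    screen_run,
)

SAFE_COMPOUNDS = [
    # unique (formula, skeleton class) combinations: no identical-spectrum twins
    "β-Neriursate",
    "Gedunin",
    "Azadiradione",
    "Nimbinolide",
    "Betulin",
    "Friedelin",
    "Lantanilic acid",
    "Bellerigenin B",
    "Intybusoloid",
    "Ursolaldehyde",
]


def test_match_parameters_validated():
    with pytest.raises(ValueError):
        MatchParameters(precursor_tol=0.0)
    with pytest.raises(ValueError):
        MatchParameters(min_fragments=0)


def test_shared_mass_yields_multiple_candidates(reference_library):
    """Four compounds share the C30H46O4 protonated mass 471.3469."""
    q = QueryFeature(source="s", precursor_mz=471.3469)
    cands = match_precursor(q, reference_library, MatchParameters())
    names = {r.name for r, _, _ in cands}
    assert len(cands) >= 3
    assert {"11-Oxooleanolic acid", "Ilelatifol D", "Glycyrrhetic acid", "Atriplicin"} <= names


def test_no_candidates_far_from_library(reference_library):
    q = QueryFeature(source="s", precursor_mz=1000.0)
    assert match_precursor(q, reference_library, MatchParameters()) == []


def test_adduct_hypothesis_restricts_candidates(reference_library):
    q = QueryFeature(source="s", precursor_mz=507.3081, adduct_hypothesis="[M+Na]+")
    cands = match_precursor(q, reference_library, MatchParameters())
    assert all(a == "[M+Na]+" for _, a, _ in cands)
    assert any(r.name == "Silymin A" for r, _, _ in cands)


def test_peganum_feature_identifies_beta_neriursate(reference_library, reference_queries):
    """The first plant-extract feature ranks the authentic standard first,
    with 0.18 min drift (printed 0.2 at one decimal)."""
    q = reference_queries[0]
    results = match_feature(q, reference_library)
    top = results[0]
    assert top.record_name == "β-Neriursate"
    assert top.level == 1
    assert top.rt_drift_abs == pytest.approx(0.18)
    assert round(top.rt_drift_abs, 1) == 0.2


def test_rt_outside_window_blocks_level_1(reference_library, reference_queries):
    q = reference_queries[0]
    far = QueryFeature(source=q.source, precursor_mz=q.precursor_mz,
                       rt=q.rt + 10.0, fragments=q.fragments)
    results = match_feature(far, reference_library)
    assert results and all(r.level != 1 for r in results)
    assert results[0].level == 2  # fragments still match


def test_score_bounds_and_exact_fragment_set(theo_library):
    p = MatchParameters()
    rec = theo_library["Gedunin"]
    cons = rec.consensus("[M+H]+", p.consensus_tol)
    q = QueryFeature(source="s", precursor_mz=adduct_mz(rec.formula, "[M+H]+"),
                     rt=rec.rt, fragments=[(m, None) for m in cons.mzs])
    top = match_feature(q, theo_library, p)[0]
    assert top.record_name == "Gedunin"
    assert top.score == 1.0
    for r in match_feature(q, theo_library, p):
        assert 0.0 <= r.score <= 1.0


def _planted_features(lib, names, rng, mz_sigma, rt_sigma, n_frag=4):
    feats = []
    for name in names:
        rec = lib[name]
        entry = rec.adducts[0]
        cons = rec.consensus(entry.adduct, 0.005)
        frag_mzs = [m for m, _ in sorted(cons.peaks, key=lambda p: -p[1])[:n_frag]]
        drift = float(np.clip(rng.normal(0, rt_sigma), -0.25, 0.25))
        feats.append(
            QueryFeature(
                source="planted",
                precursor_mz=entry.calc_mz + rng.normal(0, mz_sigma),
                rt=rec.rt + drift,
                fragments=[(m + rng.normal(0, mz_sigma), None) for m in frag_mzs],
            )
        )
    return feats


def _decoy_features(lib, rng, n=50):
    masses = np.array([t[0] for t in lib.index()])
    feats = []
    while len(feats) < n:
        x = float(rng.uniform(100, 900))
        if np.min(np.abs(masses - x)) > 3 * 0.005:
            feats.append(QueryFeature(source="decoy", precursor_mz=x, rt=float(rng.uniform(5, 12)),
                                      fragments=[(float(rng.uniform(60, 400)), None)]))
    return feats


def test_planted_features_recovered_no_false_level1(theo_library):
    """Ten compounds with realistic jitter are all recovered at level 1;
    fifty decoys outside every precursor window produce zero level-1 calls."""
    rng = np.random.default_rng(11)
    planted = _planted_features(theo_library, SAFE_COMPOUNDS, rng,
                                mz_sigma=0.001, rt_sigma=0.1)
    recovered = set()
    for q, name in zip(planted, SAFE_COMPOUNDS):
        top = match_feature(q, theo_library)[0]
        if top.level == 1:
            recovered.add(top.record_name)
        assert top.record_name == name
    assert recovered == set(SAFE_COMPOUNDS)
    for q in _decoy_features(theo_library, rng):
        results = match_feature(q, theo_library)
        assert all(r.level != 1 for r in results)


def test_recall_is_total_within_stated_noise(theo_library):
    """Over 20 seeded repeats, level-1 recall is 100% when m/z jitter stays
    below a third of the tolerance and RT drift below half the window, and
    no decoy beyond 3x the tolerance ever reaches level 1."""
    p = MatchParameters()
    for seed in range(20):
        rng = np.random.default_rng(seed)
        feats = _planted_features(theo_library, SAFE_COMPOUNDS, rng,
                                  mz_sigma=p.precursor_tol / 3 * 0.9, rt_sigma=0.1)
        tops = [match_feature(q, theo_library, p)[0] for q in feats]
        assert all(t.level == 1 for t in tops)
        assert {t.record_name for t in tops} == set(SAFE_COMPOUNDS)


def test_widening_windows_never_drops_level1(reference_library, reference_queries):
    base = MatchParameters()
    wide = MatchParameters(precursor_tol=0.05, rt_window=2.0)
    r1 = screen_run(reference_queries, reference_library, base)
    r2 = screen_run(reference_queries, reference_library, wide)
    hits1 = {(r.query.source, r.record_name) for r in r1.level1}
    hits2 = {(r.query.source, r.record_name) for r in r2.level1}
    assert hits1 <= hits2


def test_screening_reproduces_published_summary(reference_library, reference_queries):
    """Five plant-extract features resolve to exactly three compounds with a
    maximum RT drift of 0.41 min; sodium-adduct rows collapse to the parent."""
    report = screen_run(reference_queries, reference_library)
    assert report.n_sources == 5
    assert report.unique_compounds == sorted(
        ["β-Neriursate", "Butyl ester of glycyrrhetinic acid", "Silymin A"]
    )
    assert report.max_rt_drift == 0.41
    assert all(r.level == 1 for r in report.assignments)


def test_screening_empty_and_idempotent(reference_library, reference_queries):
    empty = screen_run([], reference_library)
    assert empty.n_features == 0 and empty.unique_compounds == []
    doubled = screen_run(list(reference_queries) * 2, reference_library)
    single = screen_run(reference_queries, reference_library)
    assert doubled.unique_compounds == single.unique_compounds


def test_report_roundtrips_to_disk(reference_library, reference_queries, tmp_path):
    import json

    report = screen_run(reference_queries, reference_library)
    tsv, js = report.write(tmp_path)
    assert tsv.exists()
    summary = json.loads(js.read_text())
    assert summary["n_unique_compounds"] == 3
    assert summary["max_rt_drift_min"] == 0.41
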