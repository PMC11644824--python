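"""Identify query features against the spectral library.

A query feature (precursor m/z, optional RT and adduct hypothesis, fragment
list) is matched in three stages:

1. **Precursor**: every (record, adduct) whose calculated m/z lies within
   ``precursor_tol`` (default 0.005 Da) of the query precursor, via a sorted
   range query over the library index.
2. **Retention time**: drift = query RT − library RT, compared to
   ``rt_window`` (default 0.5 min, chosen to cover the largest drift
   observed between plant-extract runs and standards, 0.41 min).
3. **Fragments**: query fragments are matched within ``fragment_tol``
   against the record's consensus spectrum for the candidate adduct; the
   score is the fraction of consensus peaks explained.

Identification levels follow metabolomics convention: level 1 requires
precursor AND retention time AND at least ``min_fragments`` matched
fragments against the authentic-standard spectrum; level 2 drops the RT
requirement; level 3 is a precursor-only match.  Candidates are ranked by
(level, score, |ppm error|, |RT drift|) with a final deterministic
tie-break on record name.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .chem import ppm_error, round_display
from .library import LibraryRecord, SpectralLibrary
from .spectra import Spectrum

LEVEL_NONE = "none"


@dataclass
class QueryFeature:
    """One detected feature from a sample run."""

    source: str
    precursor_mz: float
    rt: Optional[float] = None
    adduct_hypothesis: Optional[str] = None
    fragments: List[Tuple[float, Optional[float]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rt is not None and self.rt < 0:
            raise ValueError("rt must be non-negative")
        self.fragments = sorted(self.fragments, key=lambda p: p[0])


@dataclass
class MatchParameters:
    precursor_tol: float = 0.005  # Da
    rt_window: float = 0.5  # min
    fragment_tol: float = 0.005  # Da
    min_fragments: int = 1
    consensus_tol: float = 0.005  # Da, for building the search spectrum

    def __post_init__(self) -> None:
        for name in ("precursor_tol", "rt_window", "fragment_tol", "consensus_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.min_fragments < 1:
            raise ValueError("min_fragments must be >= 1")


@dataclass
class MatchResult:
    query: QueryFeature
    record_name: str
    adduct: str
    calc_mz: float
    mass_error_ppm: float
    rt_drift: Optional[float]  # query - library, signed; reported unsigned
    matched_fragments: List[Tuple[float, float, float]]  # (query, library, delta)
    score: float  # fraction of consensus peaks matched, in [0, 1]
    level: Union[int, str]  # 1 | 2 | 3 | "none"

    @property
    def rt_drift_abs(self) -> Optional[float]:
        return None if self.rt_drift is None else round_display(abs(self.rt_drift), 2)


def match_precursor(
    q: QueryFeature, lib: SpectralLibrary, p: MatchParameters
) -> List[Tuple[LibraryRecord, str, float]]:
    """All (record, adduct, calc m/z) candidates within the precursor window."""
    cands = lib.query_precursor(q.precursor_mz, p.precursor_tol)
    if q.adduct_hypothesis:
        cands = [c for c in cands if c[1] == q.adduct_hypothesis]
    return cands


def _match_fragments(
    q: QueryFeature, consensus: Optional[Spectrum], tol: float
) -> Tuple[List[Tuple[float, float, float]], float]:
    if consensus is None or not consensus.peaks:
        return [], 0.0
    matched = []
    qmzs = [mz for mz, _ in q.fragments]
    for lib_mz, _ in consensus.peaks:
        best = None
        for qm in qmzs:
            d = qm - lib_mz
            if abs(d) <= tol and (best is None or abs(d) < abs(best[1])):
                best = (qm, d)
        if best is not None:
            matched.append((best[0], lib_mz, best[1]))
    return matched, len(matched) / len(consensus.peaks)


def _level(rt_ok: Optional[bool], frag_ok: bool) -> Union[int, str]:
    if rt_ok and frag_ok:
        return 1
    if frag_ok:
        return 2
    return 3


def match_feature(
    q: QueryFeature, lib: SpectralLibrary, p: Optional[MatchParameters] = None
) -> List[MatchResult]:
    """Ranked identification candidates for one query feature."""
    p = p or MatchParameters()
    results = []
    for record, adduct, calc in match_precursor(q, lib, p):
        drift = None if (q.rt is None or record.rt is None) else q.rt - record.rt
        rt_ok = drift is not None and abs(drift) <= p.rt_window
        consensus = record.consensus(adduct, p.consensus_tol)
        matched, score = _match_fragments(q, consensus, p.fragment_tol)
        frag_ok = len(matched) >= p.min_fragments
        results.append(
            MatchResult(
                query=q,
                record_name=record.name,
                adduct=adduct,
                calc_mz=calc,
                mass_error_ppm=ppm_error(calc, q.precursor_mz),
                rt_drift=drift,
                matched_fragments=matched,
                score=score,
                level=_level(rt_ok, frag_ok),
            )
        )
    level_rank = {1: 0, 2: 1, 3: 2, LEVEL_NONE: 3}
    results.sort(
        key=lambda r: (
            level_rank[r.level],
            -r.score,
            abs(r.mass_error_ppm),
            abs(r.rt_drift) if r.rt_drift is not None else float("inf"),
            r.record_name,
        )
    )
    return results


@dataclass
class ScreeningReport:
    """Per-source best assignments plus the cross-run summary."""

    assignments: List[MatchResult]
    n_features: int
    n_sources: int

    @property
    def level1(self) -> List[MatchResult]:
        return [r for r in self.assignments if r.level == 1]

    @property
    def unique_compounds(self) -> List[str]:
        """Distinct identified compounds; adduct variants collapse to one
        identity because results carry the parent record name."""
        return sorted({r.record_name for r in self.level1})

    @property
    def max_rt_drift(self) -> Optional[float]:
        drifts = [r.rt_drift_abs for r in self.level1 if r.rt_drift_abs is not None]
        return max(drifts) if drifts else None

    def summary(self) -> dict:
        return {
            "n_features": self.n_features,
            "n_sources": self.n_sources,
            "n_level1": len(self.level1),
            "unique_compounds": self.unique_compounds,
            "n_unique_compounds": len(self.unique_compounds),
            "max_rt_drift_min": self.max_rt_drift,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.assignments:
            rows.append(
                {
                    "source": r.query.source,
                    "query_rt": r.query.rt,
                    "precursor_mz": r.query.precursor_mz,
                    "compound": r.record_name,
                    "adduct": r.adduct,
                    "calc_mz": round_display(r.calc_mz, 4),
                    "mass_error_ppm": round_display(r.mass_error_ppm, 1),
                    "rt_drift_min": r.rt_drift_abs,
                    "n_matched_fragments": len(r.matched_fragments),
                    "score": r.score,
                    "level": r.level,
                }
            )
        return pd.DataFrame(rows)

    def write(self, outdir: Union[str, Path], stem: str = "screening") -> Tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tsv = outdir / f"{stem}.tsv"
        js = outdir / f"{stem}_summary.json"
        self.to_frame().to_csv(tsv, sep="\t", index=False)
        js.write_text(json.dumps(self.summary(), indent=2, ensure_ascii=False) + "\n")
        return tsv, js


def screen_run(
    features: Sequence[QueryFeature],
    lib: SpectralLibrary,
    p: Optional[MatchParameters] = None,
) -> ScreeningReport:
    """Best assignment per feature, grouped by source, with summary counts."""
    p = p or MatchParameters()
    assignments: List[MatchResult] = []
    sources = []
    for q in features:
        if q.source not in sources:
            sources.append(q.source)
        ranked = match_feature(q, lib, p)
        if ranked:
            assignments.append(ranked[0])
    return ScreeningReport(
        assignments=assignments, n_features=len(features), n_sources=len(sources)
    )


def read_query_table(path: Union[str, Path]) -> List[QueryFeature]:
    """Load query features from CSV/TSV.

    Columns: ``source, rt, precursor_mz`` and optionally ``adduct`` and
    ``fragments`` (semicolon-separated m/z list).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    return features_from_frame(df)


def features_from_frame(df: pd.DataFrame) -> List[QueryFeature]:
    features = []
    for row in df.itertuples(index=False):
        frags: List[Tuple[float, Optional[float]]] = []
        raw = getattr(row, "fragments", None)
        if isinstance(raw, str) and raw.strip():
            frags = [(float(tok), None) for tok in raw.split(";") if tok.strip()]
        rt = getattr(row, "rt", None)
        adduct = getattr(row, "adduct", None)
        features.append(
            QueryFeature(
                source=str(row.source),
                precursor_mz=float(row.precursor_mz),
                rt=None if pd.isna(rt) else float(rt),
                adduct_hypothesis=None if (adduct is None or pd.isna(adduct)) else str(adduct),
                fragments=frags,
            )
        )
    return features


def load_reference_queries() -> List[QueryFeature]:
    """The packaged plant-extract query fixture (five sources)."""
    import io

    from .library import packaged_path

    df = pd.read_csv(io.StringIO(packaged_path("extract_queries.csv").read_text()), comment="#")
    return features_from_frame(df)
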