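"""Synthetic LC-MS/MS runs under data-dependent acquisition (DDA).

Each library compound elutes as a Gaussian chromatographic peak centred at
its library retention time plus a small per-run drift.  MS1 scans sample the
chromatogram at ``ms1_rate``; in every MS1 cycle the most intense precursors
above ``intensity_threshold`` that are not actively excluded trigger MS2
events (top-N per cycle, N = floor(ms2_rate / ms1_rate)).  Active exclusion
follows the simplest rule consistent with a per-precursor exclusion count of
3: a precursor is excluded after ``active_exclusion_count`` selections and
released once it has spent one full MS1 cycle below the intensity threshold.

MS2 spectra are the compound's library spectrum at the selected collision
energy (or a deterministic theoretical product-ion spectrum when the record
has none), intensity-scaled to the triggering precursor abundance, with
Gaussian m/z jitter and random background (decoy) peaks.  Everything is
reproducible from the seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .annotate import diagnostic_ions, loss_series
from .library import LibraryRecord, SpectralLibrary
from .match import QueryFeature
from .spectra import SCAN_RANGE, Spectrum, consensus_spectrum


@dataclass
class AcquisitionSettings:
    """Instrument acquisition parameters for the simulated DDA method."""

    ms1_rate: float = 5.0  # Hz
    ms2_rate: float = 12.0  # Hz
    intensity_threshold: float = 1000.0  # counts
    active_exclusion_count: int = 3
    scan_range: Tuple[float, float] = SCAN_RANGE
    ce_mode: str = "fixed"  # "fixed" | "ramp"
    fixed_ces: Tuple[float, ...] = (10.0, 20.0, 30.0, 40.0)
    ramp: Tuple[float, float] = (25.0, 62.5)

    def __post_init__(self) -> None:
        if self.ms1_rate <= 0 or self.ms2_rate <= 0:
            raise ValueError("scan rates must be positive")
        if self.intensity_threshold < 0:
            raise ValueError("intensity threshold must be >= 0")
        if self.scan_range[0] >= self.scan_range[1]:
            raise ValueError("scan_range low must be < high")
        if self.ce_mode not in ("fixed", "ramp"):
            raise ValueError(f"unknown ce_mode {self.ce_mode!r}")

    @property
    def top_n(self) -> int:
        """MS2 selections per MS1 cycle, implied by the scan-rate ratio."""
        return max(1, int(self.ms2_rate // self.ms1_rate))

    @property
    def ramp_label(self) -> str:
        return f"ramp {self.ramp[0]}-{self.ramp[1]}"


@dataclass
class NoiseSpec:
    """Generative noise model for a simulated run.

    ``rt_sigma`` models replicate-injection retention-time repeatability
    (systematic cross-matrix drift is the matcher's RT window's job);
    ``mz_sigma`` is per-peak QTOF mass jitter (~2 ppm at m/z 500);
    ``intensity_sigma`` is the log-normal spread of apex abundances;
    ``decoy_rate`` is the Poisson mean of background peaks per MS1 scan.
    """

    mz_sigma: float = 0.001  # Da
    rt_sigma: float = 0.01  # min
    intensity_sigma: float = 0.8  # log-normal sigma of apex intensity
    decoy_rate: float = 2.0  # background peaks per MS1 scan
    apex_intensity_median: float = 5e4  # counts
    decoy_intensity_median: float = 400.0  # counts
    peak_width_sigma: float = 0.05  # min, chromatographic Gaussian sigma
    apex_overrides: Dict[str, float] = field(default_factory=dict)  # by compound name


@dataclass
class TruthEntry:
    compound: str
    adduct: str
    mz: float
    apex_rt: float
    apex_intensity: float


@dataclass
class MS2Event:
    time: float  # min
    species: str  # "compound|adduct" or "decoy-<cycle>-<j>"
    adduct: Optional[str]
    precursor_mz: float  # observed (jittered)
    precursor_intensity: float
    collision_energy: str
    spectrum: Spectrum
    is_decoy: bool


@dataclass
class Cycle:
    time: float  # min
    ms1: List[Tuple[str, float, float]]  # (species, observed m/z, intensity)
    ms2_events: List[MS2Event] = field(default_factory=list)


@dataclass
class SimulatedRun:
    cycles: List[Cycle]
    truth: List[TruthEntry]
    settings: AcquisitionSettings
    noise: NoiseSpec
    seed: int

    @property
    def ms2_events(self) -> List[MS2Event]:
        return [e for c in self.cycles for e in c.ms2_events]


class ExclusionViolation(AssertionError):
    pass


# ---------------------------------------------------------------------------
# theoretical product-ion spectra


def theoretical_spectrum(
    record: LibraryRecord, adduct: str, precursor_mz: float, ce: str
) -> Spectrum:
    """Deterministic product-ion spectrum from loss series + class diagnostics.

    Fragment prevalence shifts with collision energy: deeper multi-loss ions
    and ring-cleavage diagnostics gain intensity at higher energy, the intact
    precursor fades — a qualitative stand-in for measured energy dependence.
    """
    try:
        energy = float(ce)
    except ValueError:
        energy = 40.0  # ramp: treat like a high-energy composite
    prefix = "M+Na" if adduct == "[M+Na]+" else "M+H"
    peaks: List[Tuple[float, float]] = []
    for ion in loss_series(precursor_mz, max_depth=2, precursor_label=prefix):
        inten = 1000.0 * np.exp(-0.5 * (ion.n_losses - energy / 15.0) ** 2)
        peaks.append((ion.mz, float(inten)))
    for d in diagnostic_ions(record.skeleton_class):
        peaks.append((d.mz, 800.0 * energy / 40.0))
    peaks.append((precursor_mz, 2000.0 * np.exp(-energy / 20.0)))
    lo, hi = SCAN_RANGE
    peaks = [(m, i) for m, i in peaks if lo <= m <= hi]
    return Spectrum(
        peaks=peaks,
        precursor_mz=precursor_mz,
        adduct=adduct,
        collision_energy=ce,
        mode="targeted",
        compound=record.name,
    )


def attach_theoretical_spectra(
    lib: SpectralLibrary, ces: Sequence[float] = (10.0, 20.0, 30.0, 40.0)
) -> SpectralLibrary:
    """Return a copy of ``lib`` where records without MS2 spectra carry
    deterministic theoretical spectra for each observed adduct."""
    out = copy.deepcopy(lib)
    for rec in out.records:
        if rec.spectra:
            continue
        for entry in rec.adducts:
            for ce in ces:
                rec.spectra.append(
                    theoretical_spectrum(rec, entry.adduct, entry.calc_mz, f"{ce:g}")
                )
    return out


# ---------------------------------------------------------------------------
# the simulator


def simulate_run(
    lib: SpectralLibrary,
    settings: Optional[AcquisitionSettings] = None,
    noise: Optional[NoiseSpec] = None,
    seed: int = 0,
    t_span: Optional[Tuple[float, float]] = None,
) -> SimulatedRun:
    """Simulate one DDA run of every library compound. Reproducible from seed."""
    settings = settings or AcquisitionSettings()
    noise = noise or NoiseSpec()
    if not lib.records:
        raise ValueError("cannot simulate an empty library")
    rng = np.random.default_rng(seed)

    # species: one chromatographic peak per (record, observed adduct)
    recs: List[LibraryRecord] = []
    adducts: List[str] = []
    mzs: List[float] = []
    for rec in lib.records:
        if rec.rt is None:
            continue
        for entry in rec.adducts:
            recs.append(rec)
            adducts.append(entry.adduct)
            mzs.append(entry.calc_mz)
    if not recs:
        raise ValueError("no records with retention times to simulate")
    n = len(recs)
    mz_arr = np.array(mzs)
    rt_arr = np.array([r.rt for r in recs]) + rng.normal(0.0, noise.rt_sigma, n)
    apex = noise.apex_intensity_median * np.exp(rng.normal(0.0, noise.intensity_sigma, n))
    for i, rec in enumerate(recs):
        if rec.name in noise.apex_overrides:
            apex[i] = noise.apex_overrides[rec.name]
    labels = [f"{r.name}|{a}" for r, a in zip(recs, adducts)]

    if t_span is None:
        t_span = (float(rt_arr.min()) - 0.25, float(rt_arr.max()) + 0.25)
    dt = 1.0 / (settings.ms1_rate * 60.0)  # min per MS1 cycle
    times = np.arange(t_span[0], t_span[1], dt)

    width = noise.peak_width_sigma
    sel_count = np.zeros(n, dtype=int)
    excluded = np.zeros(n, dtype=bool)
    spec_cache: Dict[Tuple[int, str], Spectrum] = {}
    lo, hi = settings.scan_range

    cycles: List[Cycle] = []
    for t in times:
        inten = apex * np.exp(-0.5 * ((t - rt_arr) / width) ** 2)
        visible = np.nonzero(inten >= 1.0)[0]
        ms1: List[Tuple[str, float, float]] = []
        cands: List[Tuple[float, int]] = []  # (intensity, species idx); decoys idx < 0
        decoy_info: List[Tuple[str, float, float]] = []
        for i in visible:
            mz_obs = mz_arr[i] + rng.normal(0.0, noise.mz_sigma)
            ms1.append((labels[i], float(mz_obs), float(inten[i])))
            if inten[i] >= settings.intensity_threshold and not excluded[i]:
                cands.append((float(inten[i]), i))
        n_decoy = rng.poisson(noise.decoy_rate)
        for j in range(n_decoy):
            dmz = rng.uniform(lo, hi)
            dint = noise.decoy_intensity_median * np.exp(rng.normal(0.0, 1.0))
            label = f"decoy-{len(cycles)}-{j}"
            ms1.append((label, float(dmz), float(dint)))
            if dint >= settings.intensity_threshold:
                decoy_info.append((label, dmz, dint))
                cands.append((float(dint), -len(decoy_info)))

        cands.sort(key=lambda c: (-c[0], c[1]))
        cycle = Cycle(time=float(t), ms1=ms1)
        for inten_sel, i in cands[: settings.top_n]:
            if i >= 0:
                rec, adduct, mz = recs[i], adducts[i], mz_arr[i]
                if settings.ce_mode == "fixed":
                    ce = f"{settings.fixed_ces[sel_count[i] % len(settings.fixed_ces)]:g}"
                else:
                    ce = settings.ramp_label
                base = _base_spectrum(spec_cache, i, rec, adduct, mz, ce, settings)
                spectrum = _noisy_copy(base, rng, noise, inten_sel, settings)
                cycle.ms2_events.append(
                    MS2Event(
                        time=float(t),
                        species=labels[i],
                        adduct=adduct,
                        precursor_mz=float(mz + rng.normal(0.0, noise.mz_sigma)),
                        precursor_intensity=inten_sel,
                        collision_energy=ce,
                        spectrum=spectrum,
                        is_decoy=False,
                    )
                )
                sel_count[i] += 1
                if sel_count[i] >= settings.active_exclusion_count:
                    excluded[i] = True
            else:
                label, dmz, dint = decoy_info[-i - 1]
                k = 3 + int(rng.integers(0, 4))
                frag_mz = np.sort(rng.uniform(lo, max(lo + 1.0, dmz), k))
                frag_int = dint * np.exp(rng.normal(0.0, 1.0, k))
                ce = (
                    settings.ramp_label
                    if settings.ce_mode == "ramp"
                    else f"{settings.fixed_ces[0]:g}"
                )
                cycle.ms2_events.append(
                    MS2Event(
                        time=float(t),
                        species=label,
                        adduct=None,
                        precursor_mz=float(dmz),
                        precursor_intensity=float(dint),
                        collision_energy=ce,
                        spectrum=Spectrum(
                            peaks=_dedupe(list(zip(frag_mz, frag_int))),
                            precursor_mz=float(dmz),
                            collision_energy=ce,
                            mode="auto",
                        ),
                        is_decoy=True,
                    )
                )
        cycles.append(cycle)
        # exclusion release: one full cycle below threshold resets the counter
        below = inten < settings.intensity_threshold
        release = excluded & below
        excluded[release] = False
        sel_count[release] = 0

    truth = [
        TruthEntry(
            compound=r.name,
            adduct=a,
            mz=float(m),
            apex_rt=float(rt),
            apex_intensity=float(ap),
        )
        for r, a, m, rt, ap in zip(recs, adducts, mz_arr, rt_arr, apex)
    ]
    run = SimulatedRun(cycles=cycles, truth=truth, settings=settings, noise=noise, seed=seed)
    audit_exclusion(run)  # invariant: asserted on every simulated run
    return run


def _base_spectrum(cache, i, rec, adduct, mz, ce, settings) -> Spectrum:
    key = (i, ce)
    if key not in cache:
        for s in rec.spectra_for(adduct):
            if s.collision_energy == ce:
                cache[key] = s
                break
        else:
            spectra = rec.spectra_for(adduct)
            if spectra:
                cache[key] = consensus_spectrum(spectra, 0.005)
            else:
                cache[key] = theoretical_spectrum(rec, adduct, float(mz), ce)
    return cache[key]


def _noisy_copy(base, rng, noise, precursor_intensity, settings) -> Spectrum:
    top = max((i for _, i in base.peaks), default=1.0) or 1.0
    scale = precursor_intensity / top
    peaks = [
        (m + rng.normal(0.0, noise.mz_sigma), i * scale)
        for m, i in base.peaks
    ]
    lo, hi = settings.scan_range
    peaks = [(m, i) for m, i in peaks if lo <= m <= hi]
    return Spectrum(
        peaks=_dedupe(peaks),
        precursor_mz=base.precursor_mz,
        adduct=base.adduct,
        collision_energy=base.collision_energy,
        mode=base.mode,
        compound=base.compound,
    )


def _dedupe(peaks: List[Tuple[float, float]]) -> List[Tuple[float, float]]:
    peaks = sorted(peaks)
    out: List[Tuple[float, float]] = []
    for m, i in peaks:
        if out and m - out[-1][0] < 1e-6:
            out[-1] = (out[-1][0], max(out[-1][1], i))
        else:
            out.append((m, i))
    return out


def audit_exclusion(run: SimulatedRun) -> Dict[str, int]:
    """Verify the active-exclusion rule from the event log alone.

    Within every contiguous above-threshold episode of a precursor, the
    number of MS2 events must not exceed ``active_exclusion_count``.
    Raises :class:`ExclusionViolation` on breach; returns events per species.
    """
    thr = run.settings.intensity_threshold
    k = run.settings.active_exclusion_count
    species = {t.compound + "|" + t.adduct for t in run.truth}
    by_cycle = [{lab: i for lab, _, i in c.ms1} for c in run.cycles]
    counts: Dict[str, int] = {}
    for sp in species:
        episode_events = 0
        above_prev = False
        total = 0
        for cycle, ms1_map in zip(run.cycles, by_cycle):
            above = ms1_map.get(sp, 0.0) >= thr
            if above and not above_prev:
                episode_events = 0
            n_ev = sum(1 for e in cycle.ms2_events if e.species == sp)
            total += n_ev
            if above:
                episode_events += n_ev
                if episode_events > k:
                    raise ExclusionViolation(
                        f"{sp}: {episode_events} MS2 events in one above-threshold "
                        f"episode (limit {k}) at t={cycle.time:.3f}"
                    )
            elif n_ev:
                raise ExclusionViolation(f"{sp}: MS2 event while below threshold")
            above_prev = above
        counts[sp] = total
    return counts


# ---------------------------------------------------------------------------
# export


def export_run(
    run: SimulatedRun, format: str, path: Union[str, Path], source: str = "simulated"
) -> Path:
    """Write a run as ``mgf`` (one block per MS2 event, TITLE encodes truth)
    or as a ``feature-table`` TSV aggregating events into query features."""
    path = Path(path)
    if format == "mgf":
        entries = []
        for k, ev in enumerate(run.ms2_events):
            entries.append(
                {
                    "params": {
                        "title": (
                            f"event={k} time={ev.time:.5f} species={ev.species} "
                            f"decoy={int(ev.is_decoy)}"
                        ),
                        "pepmass": round(ev.precursor_mz, 6),
                        "rtinseconds": round(ev.time * 60.0, 4),
                        "charge": "1+",
                        "collisionenergy": ev.collision_energy,
                    },
                    "m/z array": [round(m, 6) for m in ev.spectrum.mzs],
                    "intensity array": [round(i, 4) for _, i in ev.spectrum.peaks],
                }
            )
        with open(path, "w") as fh:
            _mgf.write(entries, fh, write_charges=False)
        return path
    if format == "feature-table":
        df = feature_table(run, source)
        df.to_csv(path, sep="\t", index=False)
        return path
    raise ValueError(f"unknown export format {format!r}")


def feature_table(run: SimulatedRun, source: str = "simulated") -> pd.DataFrame:
    """Aggregate MS2 events into one feature row per precursor species.

    Compound features take their RT from the MS1 chromatogram apex and their
    precursor m/z as the MS1 intensity-weighted mean — emulating extracted-
    ion-chromatogram feature generation; fragments are the consensus of the
    species' MS2 spectra.  Decoy events become single-event features.
    """
    triggered = {}
    for ev in run.ms2_events:
        triggered.setdefault(ev.species, []).append(ev)
    # MS1 traces for compound species
    traces: Dict[str, List[Tuple[float, float, float]]] = {}
    for cycle in run.cycles:
        for lab, mz, inten in cycle.ms1:
            if lab in triggered and not lab.startswith("decoy-"):
                traces.setdefault(lab, []).append((cycle.time, mz, inten))
    rows = []
    for sp, events in sorted(triggered.items()):
        if sp.startswith("decoy-"):
            ev = events[0]
            rows.append(
                {
                    "source": source,
                    "rt": round(ev.time, 4),
                    "precursor_mz": round(ev.precursor_mz, 6),
                    "adduct": "",
                    "fragments": ";".join(f"{m:.6f}" for m in ev.spectrum.mzs),
                    "truth_compound": "",
                    "truth_adduct": "",
                    "is_decoy": 1,
                }
            )
            continue
        trace = traces[sp]
        t_apex = max(trace, key=lambda p: p[2])[0]
        wsum = sum(i for _, _, i in trace)
        mz_mean = sum(m * i for _, m, i in trace) / wsum
        frags = consensus_spectrum([e.spectrum for e in events], 0.005)
        compound, adduct = sp.rsplit("|", 1)
        rows.append(
            {
                "source": source,
                "rt": round(t_apex, 4),
                "precursor_mz": round(mz_mean, 6),
                "adduct": "",
                "fragments": ";".join(f"{m:.6f}" for m in frags.mzs),
                "truth_compound": compound,
                "truth_adduct": adduct,
                "is_decoy": 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "source",
            "rt",
            "precursor_mz",
            "adduct",
            "fragments",
            "truth_compound",
            "truth_adduct",
            "is_decoy",
        ],
    )


def features_from_run(run: SimulatedRun, source: str = "simulated") -> List[QueryFeature]:
    """Query features for the matcher (truth columns dropped)."""
    df = feature_table(run, source)
    out = []
    for row in df.itertuples(index=False):
        frags = [(float(tok), None) for tok in str(row.fragments).split(";") if tok]
        out.append(
            QueryFeature(
                source=row.source,
                precursor_mz=float(row.precursor_mz),
                rt=float(row.rt),
                adduct_hypothesis=None,
                fragments=frags,
            )
        )
    return out


def truth_table(run: SimulatedRun) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound": t.compound,
                "adduct": t.adduct,
                "mz": round(t.mz, 6),
                "apex_rt": round(t.apex_rt, 4),
                "apex_intensity": round(t.apex_intensity, 2),
            }
            for t in run.truth
        ]
    )
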