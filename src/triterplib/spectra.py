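"""Product-ion spectra and multi-collision-energy consensus building."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

SCAN_RANGE = (50.0, 1200.0)  # TOF scan range, m/z


@dataclass
class Spectrum:
    """One MS2 peak list with its precursor and acquisition metadata.

    ``collision_energy`` is either a scalar energy rendered as text ("20")
    or a ramp descriptor ("ramp 25.0-62.5"); ramp and fixed-CE spectra are
    treated identically downstream.
    """

    peaks: List[Tuple[float, float]]
    precursor_mz: float
    adduct: Optional[str] = None
    collision_energy: str = ""
    mode: str = "targeted"  # "targeted" | "auto"
    compound: Optional[str] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks = sorted((float(m), float(i)) for m, i in self.peaks)
        lo, hi = SCAN_RANGE
        for j, (mz, inten) in enumerate(self.peaks):
            if inten < 0:
                raise ValueError(f"negative intensity at peak {j}")
            if not (lo <= mz <= hi):
                raise ValueError(f"peak m/z {mz} outside scan range {SCAN_RANGE}")
            if j and mz - self.peaks[j - 1][0] < 1e-6:
                raise ValueError(f"duplicate m/z near {mz} (within 1e-6)")

    @property
    def mzs(self) -> List[float]:
        return [m for m, _ in self.peaks]

    def __len__(self) -> int:
        return len(self.peaks)


def consensus_spectrum(spectra: Sequence[Spectrum], mz_tol: float = 0.005) -> Spectrum:
    """Merge spectra of one precursor acquired at several collision energies.

    Pooled peaks are clustered by single-linkage on sorted m/z (a gap larger
    than ``mz_tol`` starts a new cluster); each cluster is reported at its
    intensity-weighted mean m/z with the *maximum* intensity across energies,
    so diagnostic fragments that only appear at one energy survive.  Gap
    clustering guarantees adjacent output peaks are > ``mz_tol`` apart, which
    makes the operation idempotent.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    prec = [s.precursor_mz for s in spectra]
    if max(prec) - min(prec) > mz_tol:
        raise ValueError(
            f"precursor disagreement {max(prec) - min(prec):.4f} Da exceeds tolerance {mz_tol}"
        )
    pooled = sorted(p for s in spectra for p in s.peaks)
    merged: List[Tuple[float, float]] = []
    cluster: List[Tuple[float, float]] = []

    def _flush() -> None:
        if not cluster:
            return
        wsum = sum(i for _, i in cluster)
        if wsum > 0:
            mz = sum(m * i for m, i in cluster) / wsum
        else:  # all-zero intensities: plain mean
            mz = sum(m for m, _ in cluster) / len(cluster)
        merged.append((mz, max(i for _, i in cluster)))

    for mz, inten in pooled:
        if cluster and mz - cluster[-1][0] > mz_tol:
            _flush()
            cluster = []
        cluster.append((mz, inten))
    _flush()

    first = spectra[0]
    ces = sorted({s.collision_energy for s in spectra})
    return Spectrum(
        peaks=merged,
        precursor_mz=sum(prec) / len(prec),
        adduct=first.adduct,
        collision_energy=ces[0] if len(ces) == 1 else "consensus " + "+".join(ces),
        mode=first.mode,
        compound=first.compound,
    )
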