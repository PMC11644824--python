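"""Rule-based annotation of triterpenoid MS2 peaks.

Two sources of theoretical ions are combined:

* **Neutral-loss series** — multiset combinations (up to a configurable
  depth) of the common losses H2O, CO, HCOOH, C5H8O2 (dimethylacryloyl-type
  ester loss) and C4H8 (alkene elimination from alkyl esters), subtracted
  from the precursor m/z.  Loss masses come from formulas via
  :mod:`triterplib.chem`; nothing is hard-coded.
* **Skeleton-class diagnostic ions** — retro-Diels-Alder (RDA) ring-cleavage
  products characteristic of pentacyclic triterpenoid subclasses.  Oleanane
  diagnostics are known to 4 decimals (249.1856, 203.1807, 191.1803) and are
  matched at the configured Da tolerance; ursane (205, 203) and lupane
  (191, 203) diagnostics are nominal unit masses matched at +-0.5 Da.
  Lupane skeletons lack the ring-C unsaturation required for RDA, so their
  ions are flagged as arising from other pathways.  Friedelane and limonoid
  skeletons have no diagnostic set here (documented gap).

Annotation is greedy nearest-ion per peak with ties broken toward the
explanation with fewer losses (parsimony).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Dict, List, Optional, Sequence, Tuple

from .chem import MolecularFormula, monoisotopic_mass, parse_formula
from .library import LibraryRecord
from .spectra import SCAN_RANGE, Spectrum

#: Default annotation tolerance (Da).  Deliberately wider than the 0.005 Da
#: identification tolerance: published measured fragment values deviate from
#: exact loss arithmetic by up to ~0.011 Da.
DEFAULT_TOL = 0.01

NOMINAL_TOL = 0.5  # for diagnostics known only to unit mass


@dataclass(frozen=True)
class NeutralLoss:
    label: str
    formula: MolecularFormula

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula)


def _load_losses() -> Dict[str, NeutralLoss]:
    from .chem import _load_table

    out = {}
    for label, formula in _load_table("losses.tsv"):
        out[label] = NeutralLoss(label, parse_formula(formula))
    return out


#: Default neutral-loss table, editable via ``data/losses.tsv``.
NEUTRAL_LOSSES: Dict[str, NeutralLoss] = _load_losses()


@dataclass(frozen=True)
class DiagnosticIon:
    mz: float
    nominal: bool  # known only to unit mass -> matched at +-0.5 Da
    rda: bool  # produced by retro-Diels-Alder ring cleavage
    label: str


_DIAGNOSTICS: Dict[str, List[DiagnosticIon]] = {
    "oleanane": [
        DiagnosticIon(249.1856, False, True, "RDA 249.1856"),
        DiagnosticIon(203.1807, False, True, "RDA [M+H-H2O]+ 203.1807"),
        DiagnosticIon(191.1803, False, True, "RDA [M+H-2H2O-CO]+ 191.1803"),
    ],
    "ursane": [
        DiagnosticIon(205.0, True, True, "RDA m/z 205"),
        DiagnosticIon(203.0, True, True, "RDA m/z 203"),
    ],
    "lupane": [
        # no ring-C unsaturation: fragments arise from non-RDA pathways
        DiagnosticIon(191.0, True, False, "non-RDA m/z 191"),
        DiagnosticIon(203.0, True, False, "non-RDA m/z 203"),
    ],
    "friedelane": [],  # documented gap: no diagnostic set established
    "limonoid": [],  # documented gap: class-specific rules out of scope
    "other": [],  # documented gap
}


def diagnostic_ions(skeleton_class: str) -> List[DiagnosticIon]:
    """Class-diagnostic product ions; empty (documented gap) for classes
    without an established rule set.  Unknown class names are an error."""
    try:
        return list(_DIAGNOSTICS[skeleton_class])
    except KeyError:
        raise ValueError(
            f"unknown skeleton class {skeleton_class!r}; known: {sorted(_DIAGNOSTICS)}"
        ) from None


@dataclass(frozen=True)
class TheoreticalIon:
    label: str
    mz: float
    n_losses: int  # 0 for diagnostic ions
    nominal: bool = False


def loss_series(
    precursor_mz: float,
    losses: Optional[Sequence[NeutralLoss]] = None,
    max_depth: int = 2,
    precursor_label: str = "M+H",
) -> List[TheoreticalIon]:
    """Enumerate all multisets of up to ``max_depth`` neutral losses.

    Combinations are deduplicated by total loss mass (e.g. H2O+CO equals
    HCOOH to a micro-dalton; the fewer-loss label wins, then lighter first);
    ions falling below the scan floor are dropped.  Labels list losses
    sorted by increasing mass: ``[M+H-H2O-CO]+``.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if losses is None:
        losses = list(NEUTRAL_LOSSES.values())
    if not losses:
        raise ValueError("losses must be non-empty")
    seen: Dict[int, TheoreticalIon] = {}
    order: List[int] = []
    for depth in range(1, max_depth + 1):
        for combo in combinations_with_replacement(sorted(losses, key=lambda l: l.mass), depth):
            total = sum(l.mass for l in combo)
            key = round(total * 1e6)
            if key in seen:
                continue
            mz = precursor_mz - total
            if mz < SCAN_RANGE[0]:
                continue
            label = f"[{precursor_label}−" + "−".join(l.label for l in combo) + "]+"
            seen[key] = TheoreticalIon(label=label, mz=mz, n_losses=depth)
            order.append(key)
    return [seen[k] for k in order]


@dataclass
class PeakAnnotation:
    mz: float
    intensity: float
    label: Optional[str] = None
    theoretical_mz: Optional[float] = None
    delta: Optional[float] = None

    @property
    def annotated(self) -> bool:
        return self.label is not None


def annotate_spectrum(
    spectrum: Spectrum,
    record: LibraryRecord,
    tol: float = DEFAULT_TOL,
    max_depth: int = 3,
    losses: Optional[Sequence[NeutralLoss]] = None,
) -> List[PeakAnnotation]:
    """Annotate each peak with its nearest theoretical ion within ``tol``.

    Theoretical ions are the loss series from the spectrum's precursor plus
    the record's class-diagnostic ions.  One annotation per peak; peaks with
    no ion in range come back unlabeled.  Ties (equal |delta|) resolve
    toward the fewer-loss explanation.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    prefix = "M+Na" if spectrum.adduct == "[M+Na]+" else "M+H"
    theor: List[TheoreticalIon] = loss_series(
        spectrum.precursor_mz, losses, max_depth, precursor_label=prefix
    )
    for d in diagnostic_ions(record.skeleton_class):
        theor.append(TheoreticalIon(label=d.label, mz=d.mz, n_losses=0, nominal=d.nominal))

    out: List[PeakAnnotation] = []
    for mz, inten in spectrum.peaks:
        best: Optional[TheoreticalIon] = None
        best_delta = None
        for ion in theor:
            ion_tol = NOMINAL_TOL if ion.nominal else tol
            delta = mz - ion.mz
            if abs(delta) > ion_tol:
                continue
            if (
                best is None
                or abs(delta) < abs(best_delta) - 1e-12
                or (abs(abs(delta) - abs(best_delta)) <= 1e-12 and ion.n_losses < best.n_losses)
            ):
                best, best_delta = ion, delta
        if best is None:
            out.append(PeakAnnotation(mz=mz, intensity=inten))
        else:
            out.append(
                PeakAnnotation(
                    mz=mz,
                    intensity=inten,
                    label=best.label,
                    theoretical_mz=best.mz,
                    delta=best_delta,
                )
            )
    return out


def annotations_to_rows(annotations: Sequence[PeakAnnotation]) -> List[dict]:
    """Flatten annotations for TSV export."""
    return [
        {
            "mz": a.mz,
            "intensity": a.intensity,
            "label": a.label or "",
            "theoretical_mz": a.theoretical_mz,
            "delta": a.delta,
        }
        for a in annotations
    ]
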