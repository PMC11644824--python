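"""Molecular formulas, monoisotopic masses, adduct m/z and ppm errors.

This is the numeric bedrock of the package. Element masses live in a packaged
plain-text table (``data/elements.tsv``); adduct definitions in
``data/adducts.tsv``. The formula parser accepts both the plain notation
(``C30H46O4``) and the underscore-subscript dialect that compound tables are
often typeset in (``C_30_H_46_O_4_``, including explicit unit counts such as
``S_1_``).

Conventions
-----------
* ``[M+H]+`` adds the proton mass (1.00727646 Da), not the H-atom mass;
  ``[M+Na]+`` adds the sodium atom minus one electron.  These choices
  reproduce standard QTOF software output to 4 decimals.
* ppm error is ``(calc - meas) / calc * 1e6``: a measured value *above* the
  calculated one gives a *negative* error.
* Display rounding is round-half-away-from-zero: 4 decimals for m/z, 1 for
  ppm (:func:`round_display`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from typing import Dict, Iterator, Mapping

__all__ = [
    "FormulaError",
    "MolecularFormula",
    "AdductSpec",
    "ELEMENT_MASSES",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "round_display",
]

PROTON_MASS = 1.00727646
ELECTRON_MASS = 0.00054858


class FormulaError(ValueError):
    """Raised for malformed or unknown-element formula strings."""


def _load_table(name: str) -> list[list[str]]:
    text = resources.files("triterplib.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def _load_element_masses() -> Mapping[str, float]:
    return {sym: float(mass) for sym, mass in _load_table("elements.tsv")}


#: Immutable element -> monoisotopic mass table (Da).
ELEMENT_MASSES: Mapping[str, float] = _load_element_masses()


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged positive-mode adduct.

    ``delta_mass`` is added to the neutral monoisotopic mass to obtain m/z.
    """

    name: str
    delta_mass: float
    charge: int = 1


def _load_adducts() -> Mapping[str, AdductSpec]:
    out = {}
    for name, delta, charge in _load_table("adducts.tsv"):
        out[name] = AdductSpec(name, float(delta), int(charge))
    return out


#: Registry of supported adducts, keyed by label ("[M+H]+", "[M+Na]+").
ADDUCTS: Mapping[str, AdductSpec] = _load_adducts()

_TOKEN = re.compile(r"([A-Z][a-z]?)_?(\d*)_?")


@dataclass(frozen=True)
class MolecularFormula(Mapping):
    """Element -> count map with Hill-order serialization.

    Behaves as a read-only mapping; equal iff the counts are equal.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sym, n in self.counts.items():
            if sym not in ELEMENT_MASSES:
                raise FormulaError(f"unknown element {sym!r}")
            if not isinstance(n, int) or n < 1:
                raise FormulaError(f"count for {sym} must be a positive integer, got {n!r}")
        object.__setattr__(self, "counts", dict(self.counts))

    def __getitem__(self, sym: str) -> int:
        return self.counts[sym]

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged: Dict[str, int] = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return MolecularFormula(merged)

    def hill(self) -> str:
        """Serialize in Hill order (C, H, then alphabetical)."""
        syms = sorted(self.counts)
        if "C" in self.counts:
            head = ["C"] + (["H"] if "H" in self.counts else [])
            syms = head + [s for s in syms if s not in ("C", "H")]
        return "".join(s + (str(self.counts[s]) if self.counts[s] != 1 else "") for s in syms)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse ``C30H46O4`` or ``C_30_H_46_O_4_`` into a :class:`MolecularFormula`.

    An omitted count means 1 (``C_30_H_50_O``); explicit unit counts
    (``S_1_``) are allowed. Malformed input raises :class:`FormulaError`
    naming the offending position.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    s = text.strip()
    counts: Dict[str, int] = {}
    i = 0
    while i < len(s):
        m = _TOKEN.match(s, i)
        if m is None or m.end() == i:
            raise FormulaError(
                f"malformed formula {text!r}: unexpected character {s[i]!r} at position {i}"
            )
        sym, num = m.group(1), m.group(2)
        if sym not in ELEMENT_MASSES:
            raise FormulaError(
                f"unknown element {sym!r} at position {m.start(1)} in {text!r}"
            )
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        i = m.end()
    return MolecularFormula(counts)


def monoisotopic_mass(f: MolecularFormula | Mapping[str, int]) -> float:
    """Neutral monoisotopic mass (Da): sum of count x element mass."""
    if not isinstance(f, MolecularFormula):
        f = MolecularFormula(dict(f))
    return sum(n * ELEMENT_MASSES[sym] for sym, n in f.counts.items())


def adduct_mz(f: MolecularFormula | Mapping[str, int], adduct: AdductSpec | str) -> float:
    """m/z of a singly charged adduct: neutral mass + adduct delta.

    Full precision; use :func:`round_display` (4 decimals) for reporting.
    """
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise ValueError(f"unknown adduct {adduct!r}; known: {sorted(ADDUCTS)}") from None
    if adduct.charge != 1:
        raise ValueError(f"unsupported charge {adduct.charge} for {adduct.name}")
    return monoisotopic_mass(f) + adduct.delta_mass


def ppm_error(calc: float, meas: float) -> float:
    """Relative mass error in ppm: ``(calc - meas) / calc * 1e6``.

    Measured above calculated gives a negative value.
    """
    if calc <= 0:
        raise ValueError(f"calculated m/z must be positive, got {calc}")
    return (calc - meas) / calc * 1e6


def round_display(x: float, ndigits: int) -> float:
    """Round half away from zero, matching printed-table conventions."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
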