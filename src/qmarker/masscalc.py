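"""Molecular-formula parsing and exact-mass / ppm arithmetic.

High-resolution orbitrap identification rests on three small pieces of
arithmetic: the monoisotopic mass of an ion formula, the relative deviation
(ppm) between an observed and a theoretical m/z, and a tolerance gate built
on that deviation.  This module provides all three, together with the
round-half-up helpers needed to reproduce published tables digit-for-digit.

Conventions
-----------
All ions are treated as singly charged, so m/z equals the ion mass in Da.
The default "theoretical m/z" of an ion formula is its *plain* monoisotopic
formula mass -- the formula is taken as already de/protonated and no
electron-mass correction is applied.  This is the convention vendor software
commonly prints and the one that reproduces reference tables of
[M-H]-/[M+H]+ values computed from the ion formula as written.  The
physically rigorous convention (subtract one electron mass for a cation,
add it for an anion) is available behind ``electron_correction=True``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Dict, Mapping

__all__ = [
    "ELECTRON_MASS",
    "ElementCounts",
    "FormulaError",
    "IonSpecies",
    "MONOISOTOPIC_MASS",
    "formula_to_string",
    "monoisotopic_mz",
    "parse_formula",
    "ppm_error",
    "ppm_error_printed",
    "round_half_up",
    "within_tolerance",
]

#: Rest mass of the electron, Da (CODATA).
ELECTRON_MASS = 0.000548579909

#: Element -> count map for a parsed molecular formula.  Present elements
#: always have count >= 1; absent elements have no entry.
ElementCounts = Dict[str, int]


class FormulaError(ValueError):
    """Raised for unparsable molecular formulas or unknown elements."""


def _load_atomic_masses() -> Dict[str, float]:
    """Monoisotopic atomic masses, Da, from the packaged isotope table."""
    masses: Dict[str, float] = {}
    text = resources.files("qmarker.data").joinpath("atomic_masses.csv").read_text()
    for line in text.strip().splitlines()[1:]:
        symbol, mass = line.split(",")
        masses[symbol] = float(mass)
    return masses


#: Monoisotopic mass of the most abundant isotope of each supported element
#: (IUPAC values; C is exactly 12 by definition).  Immutable by convention.
MONOISOTOPIC_MASS: Mapping[str, float] = _load_atomic_masses()

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementCounts:
    """Parse a Hill-style molecular formula such as ``"C42H67O13"``.

    Element symbols may appear in any order and repeat; counts are summed.
    An omitted count means 1.  Parentheses, charges and isotope labels are
    not supported (ion formulas are written out in full, already
    de/protonated).

    Raises
    ------
    FormulaError
        If the string is empty, contains anything but element tokens, or
        names an element missing from :data:`MONOISOTOPIC_MASS`.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty molecular formula")
    text = text.strip()
    counts: ElementCounts = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(
                f"unparsable token {text[pos:m.start()]!r} in formula {text!r}"
            )
        symbol, digits = m.group(1), m.group(2)
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element {symbol!r} in formula {text!r}")
        n = int(digits) if digits else 1
        if n < 1:
            raise FormulaError(f"non-positive count for {symbol!r} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"unparsable token {text[pos:]!r} in formula {text!r}")
    return counts


def formula_to_string(counts: Mapping[str, int]) -> str:
    """Write an element-count map back in Hill order (C, H, then alphabetic)."""
    order = [e for e in ("C", "H") if e in counts]
    order += sorted(e for e in counts if e not in ("C", "H"))
    return "".join(f"{e}{counts[e] if counts[e] != 1 else ''}" for e in order)


@dataclass(frozen=True)
class IonSpecies:
    """A singly charged ion: the formula as written plus its polarity.

    The formula is already de/protonated; polarity only fixes the sign used
    by the optional electron-mass correction.
    """

    formula: ElementCounts
    polarity: str  # "negative" | "positive"

    def __post_init__(self) -> None:
        if self.polarity not in ("negative", "positive"):
            raise ValueError(f"polarity must be negative/positive, got {self.polarity!r}")
        if not self.formula or sum(self.formula.values()) < 1:
            raise FormulaError("ion formula must contain at least one atom")

    @classmethod
    def from_string(cls, text: str, polarity: str) -> "IonSpecies":
        return cls(parse_formula(text), polarity)


def monoisotopic_mz(ion: IonSpecies, electron_correction: bool = False) -> float:
    """Monoisotopic m/z of a singly charged ion, Da, at full precision.

    By default this is the plain formula mass sum(count_e * mass_e).  With
    ``electron_correction`` the electron mass is subtracted for cations and
    added for anions.
    """
    try:
        mass = sum(n * MONOISOTOPIC_MASS[e] for e, n in ion.formula.items())
    except KeyError as exc:
        raise FormulaError(f"no monoisotopic mass for element {exc.args[0]!r}") from exc
    if electron_correction:
        mass += ELECTRON_MASS if ion.polarity == "negative" else -ELECTRON_MASS
    return mass


def round_half_up(value: float, ndigits: int = 4) -> float:
    """Round with ties away from zero, as printed tables do (not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def ppm_error(observed: float, theoretical: float) -> float:
    """|observed - theoretical| / theoretical * 1e6, full precision.

    The theoretical value is the denominator: the deviation is expressed
    relative to the reference mass, not the measurement.
    """
    if observed <= 0 or theoretical <= 0:
        raise ValueError("m/z values must be positive")
    return abs(observed - theoretical) / theoretical * 1e6


def ppm_error_printed(observed: float, theoretical: float) -> float:
    """ppm error as a printed table computes it.

    Both inputs are first rounded half-up to 4 decimals (the precision at
    which m/z values are printed), the deviation is computed from the
    rounded pair, and the result is rounded half-up to 4 decimals.
    """
    obs4 = round_half_up(observed, 4)
    theo4 = round_half_up(theoretical, 4)
    return round_half_up(ppm_error(obs4, theo4), 4)


def within_tolerance(observed: float, theoretical: float, tol_ppm: float) -> bool:
    """True iff the ppm error between the two m/z values is <= ``tol_ppm``."""
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    return ppm_error(observed, theoretical) <= tol_ppm
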