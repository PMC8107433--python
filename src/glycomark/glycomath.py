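"""Monoisotopic mass arithmetic over glycan compositions.

A glycan *composition* counts residue classes without regard to linkage:
hexoses (Hex: Man, Glc, Gal, ...), N-acetylhexosamines (HexNAc: GlcNAc, ...),
pentoses (Pent: Ara, Xyl), deoxyhexoses (dHex: Fuc) and O-methyl groups.
Two textual conventions are supported:

* the 4-digit ``os`` code used for methylated microalgal N-glycans —
  ``os2221`` means 2 Hex, 2 HexNAc, 2 Pent, 1 methyl;
* the letter code common for mammalian/plant glycans — ``H5N4F1`` means
  5 Hex, 4 HexNAc, 1 dHex (F = fucose), optionally ``P`` for pentose.

The central arithmetic fact exploited throughout this package is the
deoxyhexose isobar::

    mass(dHex) = mass(Pent) + mass(CH2)     (146.05791 = 132.04226 + 14.01565)

so e.g. Hex2 HexNAc2 Pent2 Me1 (os2221) and Hex2 HexNAc2 Pent1 dHex1
(the bromelain MUXF3 composition) have bit-identical monoisotopic masses.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace

__all__ = [
    "ParseError",
    "Composition",
    "Adduct",
    "ResidueMassTable",
    "MASSES",
    "SODIUM",
    "PROTON",
    "DEPROTONATION",
    "ADDUCTS",
    "parse_oscode",
    "format_oscode",
    "format_composition",
    "neutral_mass",
    "ion_mz",
]


class ParseError(ValueError):
    """A composition or structure string could not be parsed."""


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic residue (dehydrated) masses in Da.

    ``dhex == pent + methyl`` holds exactly for the default values; this is
    the isobar on which the whole composition ambiguity rests, so the
    relation is checked at construction time.
    """

    hex: float = 162.05282
    hexnac: float = 203.07937
    pent: float = 132.04226
    dhex: float = 146.05791
    methyl: float = 14.01565
    water: float = 18.01056
    alditol: float = 2.01565  # 2 H added by borohydride reduction

    def __post_init__(self) -> None:
        if self.dhex != self.pent + self.methyl:
            raise ValueError(
                "residue mass table violates the dHex = Pent + CH2 isobar: "
                f"{self.dhex} != {self.pent} + {self.methyl}"
            )


#: Default residue mass table (standard monoisotopic values).
MASSES = ResidueMassTable()


def exact_mass_sum(terms) -> float:
    """Sum mass constants so that equal multiset sums are bit-identical.

    All default constants carry exactly five decimals, so each term is lifted
    to integer units of 1e-5 Da, summed exactly, and divided once. Isobaric
    term multisets (e.g. one dHex vs one Pent + one CH2) therefore produce
    the *same float*, not merely close ones. Terms that are not exact
    5-decimal values fall back to a correctly rounded float sum.
    """
    terms = list(terms)
    units = []
    for t in terms:
        u = round(t * 1e5)
        if u / 1e5 != t:
            return math.fsum(terms)
        units.append(u)
    return sum(units) / 1e5


@dataclass(frozen=True)
class Composition:
    """Residue-class counts of a glycan, plus the reduced-end state.

    ``reduced=True`` marks a borohydride-reduced glycan whose reducing-end
    residue is an alditol (+2.01565 Da). Compositions add field-wise
    (``a + b``); addition merges residue pools and keeps a single water,
    matching condensation bookkeeping.
    """

    hex: int = 0
    hexnac: int = 0
    pent: int = 0
    dhex: int = 0
    methyl: int = 0
    reduced: bool = False

    def __post_init__(self) -> None:
        for name in ("hex", "hexnac", "pent", "dhex", "methyl"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} count must be a non-negative integer, got {v!r}")
        if self.methyl > 3 * self.residue_count:
            raise ValueError(
                f"{self.methyl} methyl groups cannot sit on {self.residue_count} residues"
            )

    @property
    def residue_count(self) -> int:
        return self.hex + self.hexnac + self.pent + self.dhex

    def __add__(self, other: "Composition") -> "Composition":
        if not isinstance(other, Composition):
            return NotImplemented
        return Composition(
            hex=self.hex + other.hex,
            hexnac=self.hexnac + other.hexnac,
            pent=self.pent + other.pent,
            dhex=self.dhex + other.dhex,
            methyl=self.methyl + other.methyl,
            reduced=self.reduced or other.reduced,
        )

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.hex, self.hexnac, self.pent, self.dhex, self.methyl)

    def __str__(self) -> str:
        return format_composition(self)


@dataclass(frozen=True)
class Adduct:
    """An ionizing adduct: label, charge per unit and mass shift per unit (Da)."""

    label: str
    charge: int
    mass_shift: float


SODIUM = Adduct("sodium", +1, +22.98922)
PROTON = Adduct("proton", +1, +1.00728)
DEPROTONATION = Adduct("deprotonation", -1, -1.00728)

ADDUCTS: dict[str, Adduct] = {a.label: a for a in (SODIUM, PROTON, DEPROTONATION)}

_OS_RE = re.compile(r"^os(\d)(\d)(\d)(\d)$")
_LETTER_RE = re.compile(r"^(?:[HNFP]\d+)+$")
_LETTER_TOKEN = re.compile(r"([HNFP])(\d+)")


def parse_oscode(code: str) -> Composition:
    """Parse an ``os``-style 4-digit code or an H/N/F/P letter code.

    ``os2221`` -> Hex2 HexNAc2 Pent2 Me1; ``H5N4F1`` -> Hex5 HexNAc4 dHex1.
    Letter codes map F to deoxyhexose and P to pentose. The reduced flag is
    always False; reduction is a preparation detail, not part of the code.
    """
    if not isinstance(code, str):
        raise ParseError(f"composition code must be a string, got {code!r}")
    text = code.strip()
    m = _OS_RE.match(text)
    if m:
        h, n, p, me = (int(g) for g in m.groups())
        try:
            return Composition(hex=h, hexnac=n, pent=p, methyl=me)
        except ValueError as exc:
            raise ParseError(f"invalid os-code {text!r}: {exc}") from exc
    if text.lower().startswith("os"):
        raise ParseError(
            f"malformed os-code {text!r}: expected 'os' followed by exactly 4 digits"
        )
    if _LETTER_RE.match(text):
        counts = {"H": 0, "N": 0, "F": 0, "P": 0}
        seen: set[str] = set()
        for letter, digits in _LETTER_TOKEN.findall(text):
            if letter in seen:
                raise ParseError(f"malformed code {text!r}: letter {letter!r} repeated")
            seen.add(letter)
            counts[letter] = int(digits)
        return Composition(
            hex=counts["H"], hexnac=counts["N"], pent=counts["P"], dhex=counts["F"]
        )
    raise ParseError(f"unrecognized composition code {text!r}")


def format_oscode(c: Composition) -> str:
    """Format as a 4-digit os-code. Requires dhex == 0 and single-digit counts."""
    if c.dhex != 0:
        raise ValueError("os-codes cannot express deoxyhexoses; use format_composition")
    if max(c.hex, c.hexnac, c.pent, c.methyl) > 9:
        raise ValueError("os-codes carry one digit per class")
    return f"os{c.hex}{c.hexnac}{c.pent}{c.methyl}"


def format_composition(c: Composition) -> str:
    """os-code when possible, otherwise an H/N/P/F(+me) letter code."""
    if c.dhex == 0 and max(c.hex, c.hexnac, c.pent, c.methyl) <= 9:
        return format_oscode(c)
    parts = []
    for letter, count in (("H", c.hex), ("N", c.hexnac), ("P", c.pent), ("F", c.dhex)):
        if count:
            parts.append(f"{letter}{count}")
    if c.methyl:
        parts.append(f"Me{c.methyl}")
    return "".join(parts) or "H0"


def neutral_mass(c: Composition, table: ResidueMassTable = MASSES) -> float:
    """Neutral monoisotopic mass in Da: residue sum + water (+2H if reduced).

    Summation goes through :func:`exact_mass_sum`, so it is independent of
    addend order — in particular, swapping one dHex for one Pent + one methyl
    leaves the result bit-identical.
    """
    terms = (
        [table.hex] * c.hex
        + [table.hexnac] * c.hexnac
        + [table.pent] * c.pent
        + [table.dhex] * c.dhex
        + [table.methyl] * c.methyl
        + [table.water]
    )
    if c.reduced:
        terms.append(table.alditol)
    return exact_mass_sum(terms)


def ion_mz(
    c: Composition,
    adduct: Adduct = SODIUM,
    z: int = 1,
    table: ResidueMassTable = MASSES,
) -> float:
    """m/z of the z-fold adduct ion: (M + z * shift) / z.

    For deprotonation the shift is negative, giving the [M-zH]^z- m/z.
    """
    if not isinstance(z, int) or z < 1:
        raise ValueError(f"charge count z must be a positive integer, got {z!r}")
    return (neutral_mass(c, table) + z * adduct.mass_shift) / z


def without_reduction(c: Composition) -> Composition:
    """The same composition with the reduced-end flag cleared."""
    return replace(c, reduced=False)
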