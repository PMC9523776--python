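"""Elemental-composition arithmetic for sodiated/potassiated lipid ions.

Everything downstream — the oxidation-product library, Kendrick mass defects,
peak annotation — reduces to exact monoisotopic mass arithmetic over a tiny
element set: C (with the ¹³C isotope tracked separately for isotopologue
bookkeeping), H, O, Na and K.  Heteroatom classes in this analysis have the
general form ``C_c H_{2c-Z} O_w Na_x K_y`` where the hydrogen-deficiency
integer ``Z`` relates to double-bond equivalents by ``Z = 2*(DBE - 1)``.

Conventions
-----------
* Ion m/z subtracts the electron mass (0.7 ppm at m/z 800 — comparable to the
  ±2 ppm annotation tolerance, so it cannot be neglected).
* DBE and Z are properties of the *neutral parent*: the cationizing Na/K must
  be removed before calling :func:`dbe`; a salt-forming Na/K (e.g. the sodium
  of a sodium carboxylate) counts as one H.  This reproduces DBE = 1 for the
  disodiated fatty-acid class and DBE = 3 for saturated triacylglycerols
  (three ester groups).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from types import MappingProxyType
from typing import Iterator

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "C13_C12_DELTA",
    "ElementalComposition",
    "HeteroatomClass",
    "monoisotopic_mass",
    "ion_mz",
    "dbe",
    "z_value",
]

#: Monoisotopic atomic masses in Da (CODATA/IUPAC, pinned to >=6 decimals so
#: that printed reference m/z values reproduce to <=0.0005 Da).
MONOISOTOPIC_MASS = MappingProxyType(
    {
        "H": 1.00782503207,
        "C": 12.0,
        "13C": 13.00335483507,
        "O": 15.99491461956,
        "Na": 22.9897692809,
        "K": 38.96370668,
    }
)

#: Electron rest mass in Da.
ELECTRON_MASS = 0.00054857991

#: Mass difference between one 13C and one 12C (~1.003355 Da).
C13_C12_DELTA = MONOISOTOPIC_MASS["13C"] - MONOISOTOPIC_MASS["C"]


class CompositionError(ValueError):
    """Raised for invalid elemental compositions or convention violations."""


@dataclass(frozen=True, order=True)
class ElementalComposition:
    """Integer atom counts for C/H/O/Na/K with ¹³C tracked separately.

    The text form follows a Hill-like fixed order C, [13C], H, O, Na, K,
    e.g. ``"C51H98O6Na"`` or ``"C51[13C]2H96O6Na"``; :meth:`from_formula`
    and :meth:`formula` round-trip bit-exactly.
    """

    n_C: int = 0
    n_H: int = 0
    n_O: int = 0
    n_Na: int = 0
    n_K: int = 0
    n_13C: int = 0

    def __post_init__(self) -> None:
        for name in ("n_C", "n_H", "n_O", "n_Na", "n_K", "n_13C"):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise CompositionError(
                    f"atom count {name}={value!r} must be a non-negative integer"
                )

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            self.n_C + other.n_C,
            self.n_H + other.n_H,
            self.n_O + other.n_O,
            self.n_Na + other.n_Na,
            self.n_K + other.n_K,
            self.n_13C + other.n_13C,
        )

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        try:
            return ElementalComposition(
                self.n_C - other.n_C,
                self.n_H - other.n_H,
                self.n_O - other.n_O,
                self.n_Na - other.n_Na,
                self.n_K - other.n_K,
                self.n_13C - other.n_13C,
            )
        except CompositionError as exc:
            raise CompositionError(
                f"subtracting {other.formula()} from {self.formula()} "
                "gives a negative atom count"
            ) from exc

    def __mul__(self, k: int) -> "ElementalComposition":
        if not isinstance(k, int) or k < 0:
            raise CompositionError("multiplier must be a non-negative integer")
        return ElementalComposition(
            self.n_C * k, self.n_H * k, self.n_O * k, self.n_Na * k,
            self.n_K * k, self.n_13C * k,
        )

    __rmul__ = __mul__

    def __iter__(self) -> Iterator[tuple[str, int]]:
        yield "C", self.n_C
        yield "13C", self.n_13C
        yield "H", self.n_H
        yield "O", self.n_O
        yield "Na", self.n_Na
        yield "K", self.n_K

    # -- derived quantities -------------------------------------------------

    @property
    def total_carbon(self) -> int:
        """Carbon count irrespective of isotope (the class carbon number c)."""
        return self.n_C + self.n_13C

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def replace_na_with_k(self) -> "ElementalComposition":
        """Swap one Na for K (the potassium-adduct twin of a sodiated ion)."""
        if self.n_Na < 1:
            raise CompositionError("no Na to substitute with K")
        return ElementalComposition(
            self.n_C, self.n_H, self.n_O, self.n_Na - 1, self.n_K + 1, self.n_13C
        )

    # -- text form ----------------------------------------------------------

    _TOKEN = re.compile(r"(\[13C\]|Na|K|C|H|O)(\d*)")

    def formula(self) -> str:
        parts = []
        for symbol, count in self:
            if count == 0:
                continue
            written = "[13C]" if symbol == "13C" else symbol
            parts.append(written if count == 1 else f"{written}{count}")
        return "".join(parts)

    @classmethod
    def from_formula(cls, text: str) -> "ElementalComposition":
        counts = {"C": 0, "13C": 0, "H": 0, "O": 0, "Na": 0, "K": 0}
        pos = 0
        for match in cls._TOKEN.finditer(text):
            if match.start() != pos:
                raise CompositionError(f"cannot parse formula {text!r} at {pos}")
            symbol = "13C" if match.group(1) == "[13C]" else match.group(1)
            counts[symbol] += int(match.group(2) or 1)
            pos = match.end()
        if pos != len(text):
            raise CompositionError(f"cannot parse formula {text!r} at {pos}")
        return cls(
            n_C=counts["C"], n_H=counts["H"], n_O=counts["O"],
            n_Na=counts["Na"], n_K=counts["K"], n_13C=counts["13C"],
        )


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Sum of atom-count x monoisotopic atomic mass, in Da."""
    return (
        comp.n_C * MONOISOTOPIC_MASS["C"]
        + comp.n_13C * MONOISOTOPIC_MASS["13C"]
        + comp.n_H * MONOISOTOPIC_MASS["H"]
        + comp.n_O * MONOISOTOPIC_MASS["O"]
        + comp.n_Na * MONOISOTOPIC_MASS["Na"]
        + comp.n_K * MONOISOTOPIC_MASS["K"]
    )


def ion_mz(comp: ElementalComposition, charge: int = 1) -> float:
    """m/z of the intact cation ``comp`` (adducted Na/K included) at ``charge``.

    The electron mass is subtracted once per charge.
    """
    if not isinstance(charge, int) or charge < 1:
        raise CompositionError(f"charge must be a positive integer, got {charge!r}")
    return (monoisotopic_mass(comp) - charge * ELECTRON_MASS) / charge


def _effective_hydrogens(comp: ElementalComposition) -> int:
    # Neutral-parent convention: a salt-forming Na/K stands in for one H.
    return comp.n_H + comp.n_Na + comp.n_K


def dbe(comp: ElementalComposition) -> int:
    """Double-bond equivalents of a neutral parent: ``C + 1 - H_eff/2``.

    The composition must be the neutral parent molecule — strip the
    cationizing Na/K first.  A non-integer result means the caller passed an
    ion (odd effective hydrogen count) and raises.
    """
    twice = 2 * comp.total_carbon + 2 - _effective_hydrogens(comp)
    if twice % 2:
        raise CompositionError(
            f"{comp.formula()} gives non-integer DBE; pass the neutral parent "
            "(cationizing Na/K removed)"
        )
    return twice // 2


def z_value(comp: ElementalComposition) -> int:
    """Hydrogen deficiency ``Z = 2c - H_eff`` of a neutral parent (even)."""
    z = 2 * comp.total_carbon - _effective_hydrogens(comp)
    if z % 2:
        raise CompositionError(
            f"{comp.formula()} gives odd Z; pass the neutral parent"
        )
    return z


@dataclass(frozen=True)
class HeteroatomClass:
    """One heteroatom class ``C_c H_{2c-Z} O_w Na_x K_y`` at fixed Z.

    Members of the class differ only by CH2 count and therefore align
    horizontally in a Kendrick-mass-defect plot.
    """

    label: str
    n_O: int
    n_Na: int
    n_K: int
    z: int
    substrate: str
    product_tag: str

    def __post_init__(self) -> None:
        if self.z % 2 or self.z < 0:
            raise CompositionError(f"class Z must be even and >= 0, got {self.z}")

    @property
    def dbe(self) -> int:
        return self.z // 2 + 1

    def member(self, carbon_number: int) -> ElementalComposition:
        """Ion composition of the class member with ``c`` carbons."""
        n_h = 2 * carbon_number - self.z - (self.n_Na + self.n_K - 1)
        if n_h < 0:
            raise CompositionError(
                f"class {self.label} has no member at c={carbon_number}"
            )
        return ElementalComposition(
            n_C=carbon_number, n_H=n_h, n_O=self.n_O, n_Na=self.n_Na, n_K=self.n_K
        )
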