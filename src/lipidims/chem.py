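"""Elemental formulas and exact monoisotopic masses.

Every ion m/z in the package derives from :class:`ElementalFormula` plus an
adduct shift.  Masses are CODATA/NIST monoisotopic values for the most
abundant isotope; deuterium (``D``) and ``13C`` are available as explicit
isotope labels because the internal standards used in targeted acyl-carnitine
work are deuterated.
"""

from __future__ import annotations

import re
from collections.abc import Mapping
from typing import Iterator

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ElementalFormula",
]

#: Monoisotopic masses in Da (NIST). Keys are element symbols; ``D`` is 2H.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "D": 2.01410177785,
    "C": 12.0,
    "13C": 13.0033548378,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}

ELECTRON_MASS = 0.00054857990946  # Da
#: Mass of a proton; used for [M+H]+ / [M-H]- so that electron bookkeeping is
#: exact (a protonated molecule gains H+ = H atom minus one electron).
PROTON_MASS = 1.00727646688  # Da

_TOKEN = re.compile(r"(13C|[A-Z][a-z]?)(\d*)")


class ElementalFormula(Mapping):
    """Immutable element -> count map with an exact monoisotopic mass.

    Parameters
    ----------
    counts
        Mapping of element symbol (including the isotope labels ``D`` and
        ``13C``) to a non-negative integer count.  Unknown symbols and
        negative or non-integer counts are rejected.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean: dict[str, int] = {}
        for symbol, count in (counts or {}).items():
            if symbol not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {symbol!r}")
            if not float(count).is_integer() or count < 0:
                raise ValueError(
                    f"count for {symbol} must be a non-negative integer, got {count!r}"
                )
            if count:
                clean[symbol] = int(count)
        self._counts = clean

    # -- Mapping interface -------------------------------------------------
    def __getitem__(self, symbol: str) -> int:
        return self._counts[symbol]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __eq__(self, other) -> bool:
        if isinstance(other, ElementalFormula):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        merged = dict(self._counts)
        for symbol, count in other._counts.items():
            merged[symbol] = merged.get(symbol, 0) + count
        return ElementalFormula(merged)

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da (additive over elements)."""
        return sum(MONOISOTOPIC_MASS[s] * n for s, n in self._counts.items())

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a plain formula string such as ``"C11H14D7NO4"``.

        Counts default to 1; the isotope token ``13C`` is matched before
        single-letter symbols so ``C13C2`` parses as one C and two 13C.
        """
        counts: dict[str, int] = {}
        pos = 0
        for match in _TOKEN.finditer(text):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
            symbol, digits = match.groups()
            if symbol not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {symbol!r}")
            counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        return cls(counts)

    def __str__(self) -> str:
        # 13C leads so the string re-parses unambiguously (C12 13C2 written
        # "C1213C2" would read as C1213)
        order = ["13C", "C", "H", "D"] + sorted(
            s for s in self._counts if s not in {"C", "13C", "H", "D"}
        )
        parts = []
        for symbol in order:
            n = self._counts.get(symbol, 0)
            if n:
                parts.append(symbol if n == 1 else f"{symbol}{n}")
        return "".join(parts)

    def __repr__(self) -> str:
        return f"ElementalFormula({self._counts!r})"


def monoisotopic_mass(formula: ElementalFormula | Mapping[str, int] | str) -> float:
    """Monoisotopic mass (Da) of a formula, mapping or formula string."""
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    elif not isinstance(formula, ElementalFormula):
        formula = ElementalFormula(formula)
    return formula.mass


__all__.append("monoisotopic_mass")
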