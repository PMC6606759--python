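"""Elemental formulas and monoisotopic masses.

An :class:`ElementalFormula` is an immutable multiset of element symbols —
the universal currency of the toolkit.  Masses are monoisotopic: the sum of
the exact masses of the most abundant isotope of each constituent atom,
taken from a versioned table shipped with the package
(``data/isotope_masses.csv``).  All arithmetic is carried out at full double
precision; rounding to the 4-decimal presentation customary in accurate-mass
work is strictly an output concern.
"""

from __future__ import annotations

import csv
import re
from collections.abc import Iterator, Mapping
from importlib import resources

__all__ = [
    "PROTON_MASS_DA",
    "ElementalFormula",
    "IsotopeMassTable",
    "combine",
    "format_formula",
    "monoisotopic_mass",
    "parse_formula",
]

#: Mass of a proton in Da (CODATA).  The charge carrier for [M+H]-style
#: adducts is a proton, not a hydrogen atom: M+H m/z = M + 1.00727646.
PROTON_MASS_DA = 1.00727646

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically impossible formulas."""


class ElementalFormula(Mapping):
    """Immutable element -> count multiset.

    Stored counts are always >= 1; zero-count elements are dropped so that
    two formulas are equal iff they denote the same multiset.  Behaves as a
    read-only mapping; missing elements read as absent (use ``.get(sym, 0)``).
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged: dict[str, int] = {}
        for source in (counts or {}), kwargs:
            for sym, cnt in source.items():
                merged[sym] = merged.get(sym, 0) + int(cnt)
        for sym, cnt in merged.items():
            if cnt < 0:
                raise FormulaError(f"negative count for element {sym!r}: {cnt}")
        self._counts = {s: c for s, c in sorted(merged.items()) if c > 0}

    # -- mapping protocol ---------------------------------------------------
    def __getitem__(self, sym: str) -> int:
        return self._counts[sym]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalFormula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == dict(other)
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __repr__(self) -> str:
        return f"ElementalFormula({format_formula(self)!r})"

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other: Mapping[str, int]) -> "ElementalFormula":
        return combine(self, other)

    def __sub__(self, other: Mapping[str, int]) -> "ElementalFormula":
        return combine(self, {s: -c for s, c in other.items()})

    def __mul__(self, k: int) -> "ElementalFormula":
        if k < 0:
            raise FormulaError("cannot multiply a formula by a negative integer")
        return ElementalFormula({s: c * k for s, c in self._counts.items()})

    __rmul__ = __mul__

    @property
    def counts(self) -> dict[str, int]:
        """A defensive copy of the underlying element -> count map."""
        return dict(self._counts)


class IsotopeMassTable:
    """Element symbol -> (most-abundant isotope label, exact mass in Da).

    The default table covers H, C, N, O, S, Se plus the 13 catalog metals,
    with exact masses stored to 8 decimal places.
    """

    def __init__(self, entries: Mapping[str, tuple[str, float]]):
        self.entries = dict(entries)
        for sym, (label, mass) in self.entries.items():
            if mass <= 0:
                raise ValueError(f"non-positive mass for {sym}: {mass}")
            nominal = int(re.match(r"(\d+)", label).group(1))
            if abs(mass - nominal) > 0.5:
                raise ValueError(
                    f"{sym}: mass {mass} inconsistent with isotope {label}"
                )

    @classmethod
    def from_csv(cls, path) -> "IsotopeMassTable":
        entries: dict[str, tuple[str, float]] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                entries[row["element"]] = (
                    row["isotope_label"],
                    float(row["exact_mass_da"]),
                )
        return cls(entries)

    _default: "IsotopeMassTable | None" = None

    @classmethod
    def default(cls) -> "IsotopeMassTable":
        """The packaged table (cached)."""
        if cls._default is None:
            ref = resources.files("pycdb.data").joinpath("isotope_masses.csv")
            with resources.as_file(ref) as path:
                cls._default = cls.from_csv(path)
        return cls._default

    def mass(self, sym: str) -> float:
        try:
            return self.entries[sym][1]
        except KeyError:
            raise FormulaError(f"element {sym!r} not in isotope mass table") from None

    def isotope_label(self, sym: str) -> str:
        return self.entries[sym][0]

    def __contains__(self, sym: str) -> bool:
        return sym in self.entries


def parse_formula(text: str, table: IsotopeMassTable | None = None) -> ElementalFormula:
    """Parse a Hill-notation formula string such as ``"C18H29N5O10S2"``.

    Whitespace and underscores (as appear in markup like ``C_18_H_29_...``)
    are tolerated and stripped.  Element symbols must be known to *table*
    (default: the packaged isotope table); an implicit count is 1.
    """
    if table is None:
        table = IsotopeMassTable.default()
    cleaned = re.sub(r"[\s_]+", "", text)
    if not cleaned:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN_RE.match(cleaned, pos)
        if m is None or not m.group(1):
            raise FormulaError(
                f"malformed formula {text!r}: unexpected character "
                f"{cleaned[pos]!r} at position {pos}"
            )
        sym, digits = m.group(1), m.group(2)
        if sym not in table:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        cnt = int(digits) if digits else 1
        if cnt == 0:
            raise FormulaError(
                f"malformed count 0 for element {sym!r} at position {pos} in {text!r}"
            )
        counts[sym] = counts.get(sym, 0) + cnt
        pos = m.end()
    return ElementalFormula(counts)


def format_formula(f: Mapping[str, int]) -> str:
    """Format in Hill order: C, then H, then all other elements alphabetically.

    With no carbon present, all elements are ordered alphabetically.  A count
    of 1 is omitted.
    """
    counts = dict(f)
    symbols = sorted(counts)
    if "C" in counts:
        symbols = ["C"] + (["H"] if "H" in counts else []) + [
            s for s in symbols if s not in ("C", "H")
        ]
    return "".join(
        s if counts[s] == 1 else f"{s}{counts[s]}" for s in symbols if counts[s] > 0
    )


def combine(f: Mapping[str, int], delta: Mapping[str, int]) -> ElementalFormula:
    """Element-wise sum of a formula and a signed delta.

    A negative resulting count signals a chemically impossible construction
    (e.g. removing more hydrogens than are present) and raises
    :class:`FormulaError` naming the element.
    """
    counts = dict(f)
    for sym, d in delta.items():
        counts[sym] = counts.get(sym, 0) + d
        if counts[sym] < 0:
            raise FormulaError(
                f"combining would give a negative count for element {sym!r}"
            )
    return ElementalFormula(counts)


def monoisotopic_mass(
    f: Mapping[str, int], table: IsotopeMassTable | None = None
) -> float:
    """Sum of count(e) * most-abundant-isotope mass(e), in Da."""
    if table is None:
        table = IsotopeMassTable.default()
    return sum(cnt * table.mass(sym) for sym, cnt in f.items())
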