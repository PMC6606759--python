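"""Enumeration of phytochelatin (PyC) and PyC-metal complex species.

Phytochelatins are glutathione-derived polypeptides of n = 2-11 repeating
gamma-Glu-Cys units ending in a variable C-terminal residue (Gly, Ala/beta-Ala,
Gln, Ser, Glu, or none).  Their cysteine thiols chelate soft metal ions: a
divalent ion displaces two thiol protons (-2 H per ion), monovalent Ag
displaces one (-1 H), and selenium binds two thiolates as a selenotrisulfide
(-S-Se-S-, treated as formally divalent, -2 H).  Oxidation forms up to five
intramolecular disulfide bonds, each removing 2 H and consuming two thiols.
Every bound ion requires two free (non-disulfide) thiols, so a species with
n repeats and m disulfides retains n - 2m free thiols and can hold at most
floor((n - 2m) / 2) ions.  Two-metal complexes additionally occur with a
bridging sulfido (+S), disulfido (+2 S) or selenido (+Se) atom, by analogy
with iron-sulfur clusters.

:func:`enumerate_catalog` generates every species reachable under these
rules, deterministically ordered, with the default configuration producing
240 metal-free and 46 020 metal-bound formulas (46 260 unique formulas).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Sequence

from .formula import (
    ElementalFormula,
    IsotopeMassTable,
    combine,
    format_formula,
    monoisotopic_mass,
)

__all__ = [
    "BRIDGES",
    "METALS",
    "TERMINALS",
    "EnumerationConfig",
    "MetalSpec",
    "PyCSpecies",
    "SpeciesCatalog",
    "TerminalResidue",
    "apply_disulfides",
    "base_formula",
    "base_species",
    "bind_metals",
    "bridge_variants",
    "enumerate_catalog",
    "free_thiol_count",
    "species_name",
]

N_MIN, N_MAX = 2, 11
MAX_DISULFIDES = 5
THIOLS_PER_ION = 2

#: One condensed gamma-Glu-Cys repeat unit.
REPEAT_UNIT = ElementalFormula(C=8, H=12, N=2, O=4, S=1)
#: Water completing the free-acid backbone of the condensed chain.
_WATER = ElementalFormula(H=2, O=1)


@dataclass(frozen=True)
class TerminalResidue:
    """A C-terminal residue, as an elemental delta over the bare backbone."""

    label: str
    delta: ElementalFormula
    aliases: tuple[str, ...] = ()
    suffix: str = ""  # appended to the species name, e.g. "-Gly"


# Formula-distinct terminal residues; Ala and beta-Ala share one record
# because their elemental compositions (hence masses) are identical.
TERMINALS: tuple[TerminalResidue, ...] = (
    TerminalResidue("Gly", ElementalFormula(C=2, H=3, N=1, O=1), suffix="-Gly"),
    TerminalResidue(
        "Ala",
        ElementalFormula(C=3, H=5, N=1, O=1),
        aliases=("beta-Ala",),
        suffix="-Ala",
    ),
    TerminalResidue("none", ElementalFormula()),
    TerminalResidue("Gln", ElementalFormula(C=5, H=8, N=2, O=2), suffix="-Gln"),
    TerminalResidue("Ser", ElementalFormula(C=3, H=5, N=1, O=2), suffix="-Ser"),
    TerminalResidue("Glu", ElementalFormula(C=5, H=7, N=1, O=3), suffix="-Glu"),
)

_TERMINAL_INDEX = {t.label: i for i, t in enumerate(TERMINALS)}
_TERMINAL_ALIASES = {a: t.label for t in TERMINALS for a in t.aliases}


def get_terminal(label: str | TerminalResidue) -> TerminalResidue:
    if isinstance(label, TerminalResidue):
        return label
    key = _TERMINAL_ALIASES.get(label, label)
    try:
        return TERMINALS[_TERMINAL_INDEX[key]]
    except KeyError:
        raise ValueError(
            f"unknown terminal residue {label!r}; expected one of "
            f"{sorted(_TERMINAL_INDEX)} (or alias beta-Ala)"
        ) from None


@dataclass(frozen=True)
class MetalSpec:
    """A chelatable metal (or metalloid) in its most abundant isotope.

    ``h_loss_per_ion`` is the number of thiol protons displaced on binding:
    2 for the divalent class (including Se as a formal divalent in the
    selenotrisulfide linkage), 1 for monovalent Ag.  Every bound ion engages
    two free thiols regardless of class.
    """

    symbol: str
    isotope_label: str
    exact_mass_da: float
    h_loss_per_ion: int = 2
    thiols_required_per_ion: int = THIOLS_PER_ION


def _build_metal_registry() -> dict[str, MetalSpec]:
    table = IsotopeMassTable.default()
    divalent = ("Cd", "Co", "Cu", "Fe", "Pb", "Mn", "Hg", "Ni", "Zn", "Ca", "Mg", "Se")
    registry = {
        sym: MetalSpec(sym, table.isotope_label(sym), table.mass(sym), h_loss_per_ion=2)
        for sym in divalent
    }
    registry["Ag"] = MetalSpec(
        "Ag", table.isotope_label("Ag"), table.mass("Ag"), h_loss_per_ion=1
    )
    return dict(sorted(registry.items()))


#: The 13-entry metal registry, keyed by element symbol.
METALS: dict[str, MetalSpec] = _build_metal_registry()

#: Bridge type -> elemental delta; bridges apply only to two-metal species.
BRIDGES: dict[str, ElementalFormula] = {
    "none": ElementalFormula(),
    "sulfido": ElementalFormula(S=1),
    "disulfido": ElementalFormula(S=2),
    "selenido": ElementalFormula(Se=1),
}
_BRIDGE_ORDER = {name: i for i, name in enumerate(BRIDGES)}
_BRIDGE_SUFFIX = {"none": "", "sulfido": "(S)", "disulfido": "(S2)", "selenido": "(Se)"}


@dataclass(frozen=True)
class PyCSpecies:
    """One catalog entry: a PyC or PyC-metal complex."""

    terminal: TerminalResidue
    n: int
    m: int
    metals: tuple[str, ...]
    bridge: str
    formula: ElementalFormula
    mass: float
    name: str

    @property
    def formula_str(self) -> str:
        return format_formula(self.formula)

    @property
    def aliases(self) -> tuple[str, ...]:
        """Alternative names arising from terminal-residue aliases."""
        return tuple(
            self.name.replace(self.terminal.suffix, f"-{alias}")
            for alias in self.terminal.aliases
        )

    def sort_key(self):
        return (
            _TERMINAL_INDEX[self.terminal.label],
            self.n,
            self.m,
            len(self.metals),
            self.metals,
            _BRIDGE_ORDER[self.bridge],
        )


def free_thiol_count(n: int, m: int) -> int:
    """Cysteine thiols not consumed by the m disulfide bonds: n - 2m."""
    if m > n // 2:
        raise ValueError(f"{m} disulfides impossible with {n} cysteines")
    return n - 2 * m


def base_formula(terminal: str | TerminalResidue, n: int) -> ElementalFormula:
    """Elemental formula of the reduced (all-thiol) PyC with n repeats.

    The condensed backbone contributes n * C8H12N2O4S + H2O; the terminal
    residue adds its delta (e.g. Gly: +C2H3NO).
    """
    if not N_MIN <= n <= N_MAX:
        raise ValueError(f"repeat count n={n} outside supported range {N_MIN}-{N_MAX}")
    return combine(n * REPEAT_UNIT + _WATER, get_terminal(terminal).delta)


def species_name(
    terminal: str | TerminalResidue,
    n: int,
    m: int = 0,
    metals: Sequence[str] = (),
    bridge: str = "none",
) -> str:
    """Abbreviated species name, e.g. ``"(S-S)2PyC6-Gly-Cd(2)(S)"``.

    Grammar: optional ``(S-S)``/``(S-S)k`` disulfide prefix, ``PyC{n}``, the
    terminal-residue suffix (absent for the no-terminal form), a metal suffix
    (``-Cd``, ``-Cd(2)`` or ``-CdZn``), and a bridge suffix (``(S)``, ``(S2)``
    or ``(Se)``).
    """
    term = get_terminal(terminal)
    prefix = "" if m == 0 else ("(S-S)" if m == 1 else f"(S-S){m}")
    mets = tuple(sorted(metals))
    if not mets:
        metal_part = ""
    elif len(mets) == 1:
        metal_part = f"-{mets[0]}"
    elif mets[0] == mets[1]:
        metal_part = f"-{mets[0]}(2)"
    else:
        metal_part = f"-{mets[0]}{mets[1]}"
    return f"{prefix}PyC{n}{term.suffix}{metal_part}{_BRIDGE_SUFFIX[bridge]}"


def _finish(
    terminal: TerminalResidue,
    n: int,
    m: int,
    metals: tuple[str, ...],
    bridge: str,
    formula: ElementalFormula,
    table: IsotopeMassTable,
) -> PyCSpecies:
    return PyCSpecies(
        terminal=terminal,
        n=n,
        m=m,
        metals=metals,
        bridge=bridge,
        formula=formula,
        mass=monoisotopic_mass(formula, table),
        name=species_name(terminal, n, m, metals, bridge),
    )


def base_species(
    terminal: str | TerminalResidue, n: int, table: IsotopeMassTable | None = None
) -> PyCSpecies:
    """The reduced, metal-free PyC species (m = 0)."""
    term = get_terminal(terminal)
    table = table or IsotopeMassTable.default()
    return _finish(term, n, 0, (), "none", base_formula(term, n), table)


def apply_disulfides(species: PyCSpecies, k: int) -> PyCSpecies:
    """Oxidize a reduced species to its k-disulfide form (-2k H).

    k is capped at min(floor(n/2), 5): each bond pairs two cysteines, and
    only up to five disulfides occur over the supported chain lengths.
    """
    if species.m != 0 or species.metals:
        raise ValueError("disulfides are applied to the reduced metal-free species")
    cap = min(species.n // 2, MAX_DISULFIDES)
    if not 0 <= k <= cap:
        raise ValueError(
            f"{k} disulfides exceed the cap min(floor({species.n}/2), "
            f"{MAX_DISULFIDES}) = {cap}"
        )
    if k == 0:
        return species
    formula = combine(species.formula, {"H": -2 * k})
    return replace(
        species,
        m=k,
        formula=formula,
        mass=monoisotopic_mass(formula),
        name=species_name(species.terminal, species.n, k),
    )


def bind_metals(species: PyCSpecies, metals: Iterable[str | MetalSpec]) -> PyCSpecies:
    """Bind one or two metal ions to a (possibly oxidized) metal-free species.

    Each ion removes its class-specific hydrogen count (2 for divalents and
    Se, 1 for Ag) and adds one metal atom; each ion engages two free thiols,
    so n - 2m must be at least 2 per ion or the complex cannot form.
    """
    if species.metals:
        raise ValueError("species already carries bound metals")
    specs = [METALS[m] if isinstance(m, str) else m for m in metals]
    if not 1 <= len(specs) <= 2:
        raise ValueError("a complex binds one or two metal ions")
    needed = sum(s.thiols_required_per_ion for s in specs)
    available = free_thiol_count(species.n, species.m)
    if available < needed:
        raise ValueError(
            f"insufficient free thiols for {species.name} + "
            f"{'+'.join(s.symbol for s in specs)}: need {needed}, have {available}"
        )
    delta: dict[str, int] = {"H": -sum(s.h_loss_per_ion for s in specs)}
    for s in specs:
        delta[s.symbol] = delta.get(s.symbol, 0) + 1
    formula = combine(species.formula, delta)
    symbols = tuple(sorted(s.symbol for s in specs))
    return replace(
        species,
        metals=symbols,
        formula=formula,
        mass=monoisotopic_mass(formula),
        name=species_name(species.terminal, species.n, species.m, symbols),
    )


def bridge_variants(species: PyCSpecies) -> list[PyCSpecies]:
    """The four bridge forms of a two-metal complex: plain, +S, +2S, +Se.

    No combined S+Se bridge and no diselenido form is generated; bridges
    never apply to zero- or one-metal species.
    """
    if len(species.metals) != 2:
        raise ValueError("bridged forms exist only for two-metal complexes")
    out = [species]
    for bridge in ("sulfido", "disulfido", "selenido"):
        formula = combine(species.formula, BRIDGES[bridge])
        out.append(
            replace(
                species,
                bridge=bridge,
                formula=formula,
                mass=monoisotopic_mass(formula),
                name=species_name(
                    species.terminal, species.n, species.m, species.metals, bridge
                ),
            )
        )
    return out


@dataclass(frozen=True)
class EnumerationConfig:
    """Catalog generation parameters; the defaults produce the full catalog."""

    terminals: tuple[str, ...] = tuple(t.label for t in TERMINALS)
    n_min: int = N_MIN
    n_max: int = N_MAX
    metals: tuple[str, ...] = tuple(METALS)
    max_metals: int = 2
    include_bridges: bool = True
    max_disulfides: int = MAX_DISULFIDES

    def __post_init__(self):
        object.__setattr__(
            self, "terminals", tuple(get_terminal(t).label for t in self.terminals)
        )
        object.__setattr__(self, "metals", tuple(sorted(set(self.metals))))
        for sym in self.metals:
            if sym not in METALS:
                raise ValueError(f"unknown metal symbol {sym!r}")
        if not (N_MIN <= self.n_min <= self.n_max <= N_MAX):
            raise ValueError(
                f"n range {self.n_min}-{self.n_max} outside {N_MIN}-{N_MAX}"
            )
        if self.max_metals not in (0, 1, 2):
            raise ValueError("max_metals must be 0, 1 or 2")


class SpeciesCatalog:
    """An ordered collection of species with unique elemental formulas."""

    def __init__(self, species: Iterable[PyCSpecies]):
        self.species: list[PyCSpecies] = list(species)
        self.by_formula: dict[str, PyCSpecies] = {}
        for sp in self.species:
            key = sp.formula_str
            if key in self.by_formula:
                raise ValueError(
                    f"formula collision: {key} is both "
                    f"{self.by_formula[key].name} and {sp.name}"
                )
            self.by_formula[key] = sp

    def __len__(self) -> int:
        return len(self.species)

    def __iter__(self) -> Iterator[PyCSpecies]:
        return iter(self.species)

    def __getitem__(self, i: int) -> PyCSpecies:
        return self.species[i]

    def metal_free(self) -> list[PyCSpecies]:
        return [sp for sp in self.species if not sp.metals]

    def metal_bound(self) -> list[PyCSpecies]:
        return [sp for sp in self.species if sp.metals]


def enumerate_catalog(config: EnumerationConfig | None = None) -> SpeciesCatalog:
    """Generate the complete species catalog for a configuration.

    Iteration order is deterministic: terminal family (Gly, Ala, none, Gln,
    Ser, Glu), then n, then disulfide count m, then metal multiset
    (alphabetical, unordered pairs with repetition), then bridge
    (none, sulfido, disulfido, selenido).
    """
    cfg = config or EnumerationConfig()
    table = IsotopeMassTable.default()
    out: list[PyCSpecies] = []
    for label in cfg.terminals:
        for n in range(cfg.n_min, cfg.n_max + 1):
            reduced = base_species(label, n, table)
            for m in range(0, min(n // 2, cfg.max_disulfides) + 1):
                scaffold = apply_disulfides(reduced, m)
                out.append(scaffold)
                free = free_thiol_count(n, m)
                if cfg.max_metals >= 1 and free >= THIOLS_PER_ION:
                    for sym in cfg.metals:
                        out.append(bind_metals(scaffold, (sym,)))
                if cfg.max_metals >= 2 and free >= 2 * THIOLS_PER_ION:
                    for a, b in itertools.combinations_with_replacement(
                        cfg.metals, 2
                    ):
                        pair = bind_metals(scaffold, (a, b))
                        if cfg.include_bridges:
                            out.extend(bridge_variants(pair))
                        else:
                            out.append(pair)
    return SpeciesCatalog(out)
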