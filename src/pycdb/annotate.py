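"""Accurate-mass annotation of experimental m/z values against the catalog.

Theoretical m/z of an adduct is (neutral mass + adduct mass delta) / z, with
the proton (1.00727646 Da) as the charge carrier for M+H-style adducts.
A query matches a (species, adduct) pair when the signed relative error
1e6 * (observed - theoretical) / theoretical is within the ppm tolerance in
absolute value.  An optional NOPS filter discards species whose nitrogen,
oxygen, phosphorus and sulfur to carbon ratios fall outside the common
ranges observed for small biomolecules; ratios are computed on the neutral
formula and bound metals never enter them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .catalog import PyCSpecies, SpeciesCatalog, get_terminal
from .formula import PROTON_MASS_DA

__all__ = [
    "ADDUCT_REGISTRY",
    "DEFAULT_ADDUCTS",
    "DEFAULT_NOPS",
    "DEFAULT_TOLERANCE_PPM",
    "Adduct",
    "AnnotationMatch",
    "NOPSRule",
    "adduct_mz",
    "annotate_masses",
    "get_adduct",
    "nops_check",
    "ppm_difference",
]

_ELECTRON_MASS_DA = 0.00054858
_NA23 = 22.98976928
_K39 = 38.96370649


@dataclass(frozen=True)
class Adduct:
    """A charged adduct form: m/z = (M + mass_delta) / z."""

    name: str
    mass_delta: float
    z: int

    def __post_init__(self):
        if self.z < 1:
            raise ValueError("charge state z must be >= 1")


#: All known adducts.  Deltas for cation adducts are ion masses (atom minus
#: one electron); M-H is the deprotonated anion observed in negative mode.
ADDUCT_REGISTRY: dict[str, Adduct] = {
    a.name: a
    for a in (
        Adduct("M+H", PROTON_MASS_DA, 1),
        Adduct("M+2H", 2 * PROTON_MASS_DA, 2),
        Adduct("M+3H", 3 * PROTON_MASS_DA, 3),
        Adduct("M+Na", _NA23 - _ELECTRON_MASS_DA, 1),
        Adduct("M+K", _K39 - _ELECTRON_MASS_DA, 1),
        Adduct("M-H", -PROTON_MASS_DA, 1),
    )
}

#: Protonated adducts searched by default.
DEFAULT_ADDUCTS: tuple[Adduct, ...] = (
    ADDUCT_REGISTRY["M+H"],
    ADDUCT_REGISTRY["M+2H"],
    ADDUCT_REGISTRY["M+3H"],
)

DEFAULT_TOLERANCE_PPM = 5.0


def get_adduct(name: str | Adduct) -> Adduct:
    if isinstance(name, Adduct):
        return name
    try:
        return ADDUCT_REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown adduct {name!r}; known: {sorted(ADDUCT_REGISTRY)}"
        ) from None


def adduct_mz(neutral_mass: float, adduct: Adduct | str) -> float:
    """Theoretical m/z of *adduct* for a neutral monoisotopic mass in Da."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    a = get_adduct(adduct)
    return (neutral_mass + a.mass_delta) / a.z


def ppm_difference(observed: float, theoretical: float) -> float:
    """Signed mass error in parts per million, relative to the theoretical m/z."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class NOPSRule:
    """Maximum heteroatom-to-carbon ratios for a plausible formula.

    Defaults follow the common-range heuristics used in formula-filtering
    practice: N/C <= 1.3, O/C <= 1.2, P/C <= 0.3, S/C <= 0.8.
    """

    max_n_to_c: float = 1.3
    max_o_to_c: float = 1.2
    max_p_to_c: float = 0.3
    max_s_to_c: float = 0.8

    def __post_init__(self):
        if min(self.max_n_to_c, self.max_o_to_c, self.max_p_to_c, self.max_s_to_c) <= 0:
            raise ValueError("NOPS ratio maxima must be positive")


DEFAULT_NOPS = NOPSRule()


def nops_check(formula, rule: NOPSRule = DEFAULT_NOPS) -> bool:
    """True iff N/C, O/C, P/C and S/C are all within the rule's maxima.

    Carbon-free formulas fail closed.  Metals are ignored: only the N, O, P
    and S counts relative to carbon are examined.
    """
    c = formula.get("C", 0)
    if c == 0:
        return False
    return (
        formula.get("N", 0) / c <= rule.max_n_to_c
        and formula.get("O", 0) / c <= rule.max_o_to_c
        and formula.get("P", 0) / c <= rule.max_p_to_c
        and formula.get("S", 0) / c <= rule.max_s_to_c
    )


@dataclass(frozen=True)
class AnnotationMatch:
    """One (query, species, adduct) match within tolerance."""

    query_mz: float
    query_index: int
    species: PyCSpecies
    adduct: Adduct
    theoretical_mz: float
    ppm_error: float


def _passes_filters(
    sp: PyCSpecies,
    metals: frozenset[str] | None,
    terminals: frozenset[str] | None,
    n_range: tuple[int, int] | None,
) -> bool:
    if metals is not None:
        # A metal filter selects metal-bound species only: every bound metal
        # must be in the chosen subset (and at least one metal must be bound).
        if not sp.metals or not set(sp.metals) <= metals:
            return False
    if terminals is not None and sp.terminal.label not in terminals:
        return False
    if n_range is not None and not n_range[0] <= sp.n <= n_range[1]:
        return False
    return True


def annotate_masses(
    queries: Sequence[float],
    catalog: SpeciesCatalog,
    adducts: Iterable[Adduct | str] | None = None,
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
    metals: Iterable[str] | None = None,
    terminals: Iterable[str] | None = None,
    n_range: tuple[int, int] | None = None,
    nops: bool = False,
    nops_rule: NOPSRule = DEFAULT_NOPS,
) -> list[AnnotationMatch]:
    """Match experimental m/z values against the catalog.

    Every (query, species, adduct) combination whose absolute ppm error is
    within *tolerance_ppm* is reported — a query may have zero or many
    matches, and no best-hit collapsing or confidence scoring is applied.
    Results are sorted by (query m/z, |ppm error|).

    Filters restrict the searched species: *metals* keeps metal-bound species
    whose bound metals all lie in the subset, *terminals* and *n_range*
    restrict the scaffold, and *nops* applies the heteroatom-ratio check.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    if len(queries) == 0:
        raise ValueError("query list is empty")
    if adducts is None:
        adducts = DEFAULT_ADDUCTS
    adduct_list = [get_adduct(a) for a in adducts]
    if not adduct_list:
        raise ValueError("adduct list is empty")

    metal_set = frozenset(metals) if metals is not None else None
    term_set = (
        frozenset(get_terminal(t).label for t in terminals)
        if terminals is not None
        else None
    )
    candidates = [
        sp
        for sp in catalog
        if _passes_filters(sp, metal_set, term_set, n_range)
        and (not nops or nops_check(sp.formula, nops_rule))
    ]
    if not candidates:
        return []

    # Flat arrays over (species, adduct) pairs, sorted by theoretical m/z.
    theo = np.array(
        [adduct_mz(sp.mass, a) for sp in candidates for a in adduct_list]
    )
    order = np.argsort(theo)
    theo_sorted = theo[order]
    n_add = len(adduct_list)

    rel = tolerance_ppm * 1e-6
    matches: list[AnnotationMatch] = []
    for qi, q in enumerate(queries):
        q = float(q)
        # |q - t| <= rel * t  <=>  q / (1 + rel) <= t <= q / (1 - rel)
        lo = np.searchsorted(theo_sorted, q / (1 + rel), side="left")
        hi = np.searchsorted(theo_sorted, q / (1 - rel), side="right")
        for flat in order[lo:hi]:
            sp = candidates[flat // n_add]
            a = adduct_list[flat % n_add]
            t = theo[flat]
            ppm = ppm_difference(q, t)
            if abs(ppm) <= tolerance_ppm:
                matches.append(AnnotationMatch(q, qi, sp, a, t, ppm))
    matches.sort(key=lambda m: (m.query_mz, abs(m.ppm_error)))
    return matches
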