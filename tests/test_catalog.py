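"""Species construction rules and the combinatorial catalog enumeration."""

import itertools

import pytest

from pycdb import (
    EnumerationConfig,
    apply_disulfides,
    base_formula,
    base_species,
    bind_metals,
    bridge_variants,
    enumerate_catalog,
    free_thiol_count,
    species_name,
)
from pycdb.annotate import adduct_mz
from pycdb.formula import format_formula, parse_formula

# ---------------------------------------------------------------------------
# Independent brute-force oracle: plain-dict arithmetic over every
# (terminal, n, m, metal multiset, bridge) tuple, filtered by the
# two-free-thiols-per-ion rule.  Shares no code with the enumerator.
# ---------------------------------------------------------------------------

_REPEAT = {"C": 8, "H": 12, "N": 2, "O": 4, "S": 1}
_TERMS = {
    "Gly": {"C": 2, "H": 3, "N": 1, "O": 1},
    "Ala": {"C": 3, "H": 5, "N": 1, "O": 1},
    "none": {},
    "Gln": {"C": 5, "H": 8, "N": 2, "O": 2},
    "Ser": {"C": 3, "H": 5, "N": 1, "O": 2},
    "Glu": {"C": 5, "H": 7, "N": 1, "O": 3},
}
_H_LOSS = {"Ag": 1}  # every other metal (incl. Se) loses 2 H per ion
_ORACLE_METALS = ["Ag", "Ca", "Cd", "Co", "Cu", "Fe", "Hg", "Mg", "Mn", "Ni",
                  "Pb", "Se", "Zn"]
_BRIDGE_DELTAS = {"none": {}, "S": {"S": 1}, "S2": {"S": 2}, "Se": {"Se": 1}}


def _oracle_formula(term, n, m, metals, bridge):
    counts = {}
    for delta, k in [(_REPEAT, n), ({"H": 2, "O": 1}, 1), (_TERMS[term], 1)]:
        for sym, c in delta.items():
            counts[sym] = counts.get(sym, 0) + c * k
    counts["H"] -= 2 * m
    for sym in metals:
        counts["H"] -= _H_LOSS.get(sym, 2)
        counts[sym] = counts.get(sym, 0) + 1
    for sym, c in _BRIDGE_DELTAS[bridge].items():
        counts[sym] = counts.get(sym, 0) + c
    return "".join(
        f"{s}{counts[s]}" for s in sorted(counts) if counts[s] > 0
    )


def _oracle_catalog(metal_symbols=_ORACLE_METALS):
    """Yield (n_metals_stratum, canonical formula string) for every species."""
    for term in _TERMS:
        for n in range(2, 12):
            for m in range(0, min(n // 2, 5) + 1):
                free = n - 2 * m
                yield 0, _oracle_formula(term, n, m, (), "none")
                if free >= 2:
                    for sym in metal_symbols:
                        yield 1, _oracle_formula(term, n, m, (sym,), "none")
                if free >= 4:
                    for pair in itertools.combinations_with_replacement(
                        metal_symbols, 2
                    ):
                        for bridge in _BRIDGE_DELTAS:
                            yield 2, _oracle_formula(term, n, m, pair, bridge)


def _canonical(formula_str):
    counts = parse_formula(formula_str).counts
    return "".join(f"{s}{counts[s]}" for s in sorted(counts))


# ---------------------------------------------------------------------------
# Unit-level construction rules
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "terminal, n, expected",
    [
        ("Gly", 2, "C18H29N5O10S2"),
        ("none", 2, "C16H26N4O9S2"),
        ("Gly", 3, "C26H41N7O14S3"),
        ("Ala", 2, "C19H31N5O10S2"),
        ("beta-Ala", 2, "C19H31N5O10S2"),  # alias resolves to the Ala record
        ("Gln", 2, "C21H34N6O11S2"),
        ("Ser", 2, "C19H31N5O11S2"),
        ("Glu", 2, "C21H33N5O12S2"),
    ],
)
def test_base_formula(terminal, n, expected):
    assert format_formula(base_formula(terminal, n)) == expected


@pytest.mark.parametrize("n", [1, 12, 0])
def test_base_formula_rejects_out_of_range(n):
    with pytest.raises(ValueError):
        base_formula("Gly", n)


def test_base_formula_repeat_increment():
    for n in range(2, 11):
        diff = base_formula("Gly", n + 1) - base_formula("Gly", n)
        assert format_formula(diff) == "C8H12N2O4S"


def test_apply_disulfides():
    sp = base_species("Gly", 2)
    oxidized = apply_disulfides(sp, 1)
    assert oxidized.formula_str == "C18H27N5O10S2"
    assert oxidized.name == "(S-S)PyC2-Gly"
    assert apply_disulfides(sp, 0) is sp
    with pytest.raises(ValueError):
        apply_disulfides(base_species("Gly", 3), 2)  # floor(3/2) = 1 cap
    with pytest.raises(ValueError):
        apply_disulfides(base_species("Gly", 11), 6)  # hard cap of 5


@pytest.mark.parametrize("n, m, expected", [(2, 0, 2), (6, 2, 2), (4, 2, 0)])
def test_free_thiol_count(n, m, expected):
    assert free_thiol_count(n, m) == expected


def test_bind_metals():
    cd = bind_metals(base_species("Gly", 2), ["Cd"])
    assert cd.formula_str == "C18H27CdN5O10S2"
    assert round(adduct_mz(cd.mass, "M+H"), 4) == 652.0306

    hg2 = bind_metals(base_species("Gly", 4), ["Hg", "Hg"])
    assert round(adduct_mz(hg2.mass, "M+H"), 4) == 1404.1564

    # Ag loses one H per ion instead of two
    ag = bind_metals(base_species("Gly", 2), ["Ag"])
    assert ag.formula_str == "C18H28AgN5O10S2"

    # 0 free thiols left after the disulfide: complex cannot form
    with pytest.raises(ValueError, match="insufficient free thiols"):
        bind_metals(apply_disulfides(base_species("Gly", 2), 1), ["Zn"])


def test_bridge_variants():
    pair = bind_metals(base_species("Gly", 4), ["Cd", "Cd"])
    variants = bridge_variants(pair)
    assert [v.bridge for v in variants] == ["none", "sulfido", "disulfido", "selenido"]
    deltas = [(v.formula.get("S", 0) - pair.formula["S"],
               v.formula.get("Se", 0) - pair.formula.get("Se", 0))
              for v in variants]
    assert deltas == [(0, 0), (1, 0), (2, 0), (0, 1)]
    with pytest.raises(ValueError):
        bridge_variants(bind_metals(base_species("Gly", 4), ["Cd"]))


@pytest.mark.parametrize(
    "args, expected",
    [
        (("Gly", 2, 1), "(S-S)PyC2-Gly"),
        (("Gly", 6, 2), "(S-S)2PyC6-Gly"),
        (("Gly", 4, 0, ("Cd", "Cd")), "PyC4-Gly-Cd(2)"),
        (("Gly", 4, 0, ("Zn", "Cd")), "PyC4-Gly-CdZn"),
        (("none", 2, 0), "PyC2"),
        (("Ser", 5, 0, ("Hg",)), "PyC5-Ser-Hg"),
        (("Glu", 4, 0, ("Cd", "Cd"), "selenido"), "PyC4-Glu-Cd(2)(Se)"),
    ],
)
def test_species_name_grammar(args, expected):
    assert species_name(*args) == expected


# ---------------------------------------------------------------------------
# Catalog-level counts and the oracle equivalence
# ---------------------------------------------------------------------------

def test_default_catalog_counts(full_catalog):
    assert len(full_catalog.metal_free()) == 240
    assert len(full_catalog.metal_bound()) == 46020
    assert len(full_catalog) == 46260
    one_metal = [sp for sp in full_catalog if len(sp.metals) == 1]
    two_metal = [sp for sp in full_catalog if len(sp.metals) == 2]
    assert len(one_metal) == 2340   # 6 families x 30 scaffolds x 13 metals
    assert len(two_metal) == 43680  # 6 x 20 x 91 pairs x 4 bridge forms


def test_catalog_formulas_unique(full_catalog):
    # SpeciesCatalog raises on collision; the index must cover every species.
    assert len(full_catalog.by_formula) == len(full_catalog)


def test_enumerator_matches_brute_force_oracle(full_catalog):
    oracle = list(_oracle_catalog())
    by_stratum = {k: set() for k in (0, 1, 2)}
    for stratum, formula in oracle:
        by_stratum[stratum].add(formula)
    assert len(by_stratum[0]) == 240
    assert len(by_stratum[1]) == 2340
    assert len(by_stratum[2]) == 43680

    enum_by_stratum = {k: set() for k in (0, 1, 2)}
    for sp in full_catalog:
        enum_by_stratum[len(sp.metals)].add(_canonical(sp.formula_str))
    assert enum_by_stratum == by_stratum


@pytest.mark.parametrize("metals", [("Cd",), ("Cd", "Hg"), ("Ag", "Cd", "Se", "Zn")])
def test_restricted_metal_subset_counts(metals):
    k = len(metals)
    catalog = enumerate_catalog(EnumerationConfig(metals=metals))
    assert len(catalog.metal_free()) == 240
    assert sum(1 for sp in catalog if len(sp.metals) == 1) == 6 * 30 * k
    assert (
        sum(1 for sp in catalog if len(sp.metals) == 2)
        == 6 * 20 * (k * (k + 1) // 2) * 4
    )


def test_restricted_config_gly_n2_no_metals():
    cfg = EnumerationConfig(terminals=("Gly",), n_min=2, n_max=2, max_metals=0)
    catalog = enumerate_catalog(cfg)
    assert [sp.name for sp in catalog] == ["PyC2-Gly", "(S-S)PyC2-Gly"]


def test_catalog_order_deterministic(small_catalog):
    keys = [sp.sort_key() for sp in small_catalog]
    assert keys == sorted(keys)
    rebuilt = enumerate_catalog(
        EnumerationConfig(metals=("Cd", "Hg", "Pb", "Zn"))
    )
    assert [sp.name for sp in rebuilt] == [sp.name for sp in small_catalog]
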