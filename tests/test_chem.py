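"""Formula algebra, masses, isotope patterns, and stoichiometry."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patrace import chem
from patrace.chem import (
    ADDUCTS,
    DERIVATIVES,
    ElementalFormula,
    IsotopePattern,
    apply_derivative,
    convolve_patterns,
    ion_mz,
    monoisotopic_mass,
    natural_isotope_pattern,
    nominal_mass,
    odd_chain_beta_oxidation,
    parse_formula,
)

# -- parsing ---------------------------------------------------------------


@pytest.mark.parametrize(
    "text,expected",
    [
        ("H2O", {"H": 2, "O": 1}),
        ("C24H40N7O17P3S", {"C": 24, "H": 40, "N": 7, "O": 17, "P": 3, "S": 1}),
        ("C0", {}),
        ("[13C]3H6O2", {"[13C]": 3, "H": 6, "O": 2}),
        ("C4HD7O2", {"C": 4, "H": 1, "D": 7, "O": 2}),
    ],
)
def test_parse_formula(text, expected):
    assert parse_formula(text).counts == expected


def test_parse_roundtrips_through_formatting():
    f = parse_formula("C6H12O6")
    assert parse_formula(f.formatted()) == f


@pytest.mark.parametrize("bad", ["Xx2", "C3h6", "2H6", "C-1"])
def test_parse_rejects_malformed(bad):
    with pytest.raises(ValueError):
        parse_formula(bad)


def test_subtraction_underflow_names_element():
    with pytest.raises(ValueError, match="O"):
        parse_formula("CH4") - parse_formula("O")


# -- masses ----------------------------------------------------------------


@pytest.mark.parametrize(
    "text,mass",
    [
        ("H2O", 18),
        ("C3H6O2", 74),          # propionic acid
        ("C24H40N7O17P3S", 823),  # propionyl-CoA -> [M+H]+ 824
        ("[13C]3H6O2", 77),       # fully 13C-labeled propionate
    ],
)
def test_nominal_mass(text, mass):
    assert nominal_mass(parse_formula(text)) == mass


def test_monoisotopic_mass_examples():
    assert monoisotopic_mass(parse_formula("C6H12O6")) == pytest.approx(180.0634, abs=5e-4)
    assert monoisotopic_mass(parse_formula("H2O")) == pytest.approx(18.0106, abs=5e-4)
    assert monoisotopic_mass(ElementalFormula()) == 0.0


@st.composite
def formulas(draw):
    els = draw(
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "P", "S", "Si", "D", "[13C]"]),
            st.integers(min_value=0, max_value=30),
            max_size=5,
        )
    )
    return ElementalFormula(els)


@given(formulas(), formulas())
@settings(max_examples=100, deadline=None)
def test_nominal_mass_additive(f, g):
    assert nominal_mass(f + g) == nominal_mass(f) + nominal_mass(g)


def test_monoisotopic_within_half_dalton_of_nominal():
    for text in ["C6H12O6", "C3H6O2", "C7H15NO3", "C9H17NO4"]:
        f = parse_formula(text)
        assert abs(monoisotopic_mass(f) - nominal_mass(f)) < 0.5


# -- derivatives and adducts -----------------------------------------------


def test_3nph_derivative_of_acetic_acid():
    out = apply_derivative(parse_formula("C2H4O2"), "3NPH")
    assert out == parse_formula("C8H9N3O3")
    assert nominal_mass(out) == 195
    assert ion_mz(out, "[M-H]-") == 194


def test_methyl_ester_of_carnitine():
    out = apply_derivative(parse_formula("C7H15NO3"), "methyl_ester")
    assert out == parse_formula("C8H17NO3")
    assert ion_mz(out, "[M+H]+") == 176


def test_derivative_count_zero_is_identity():
    f = parse_formula("C6H12O6")
    assert apply_derivative(f, "TBDMS", count=0) == f


def test_derivative_underflow_raises():
    strip_o = chem.DerivativeSpec("strip_O", ElementalFormula(), parse_formula("O"))
    with pytest.raises(ValueError, match="O"):
        apply_derivative(parse_formula("CH4"), strip_o)


@pytest.mark.parametrize(
    "formula,adduct,mz",
    [
        ("C25H40N7O19P3S", "[M+H]+", 868),   # methylmalonyl-CoA
        ("H2O", "[M+H]+", 19),
    ],
)
def test_ion_mz_nominal(formula, adduct, mz):
    assert ion_mz(parse_formula(formula), adduct) == mz


def test_hexanoate_3nph_deprotonated():
    out = apply_derivative(parse_formula("C6H12O2"), "3NPH")
    assert ion_mz(out, "[M-H]-") == 250


@given(formulas())
@settings(max_examples=50, deadline=None)
def test_deprotonated_mz_is_nominal_minus_one(f):
    if f["H"] >= 1:
        assert ion_mz(f, "[M-H]-") == nominal_mass(f) - 1


def test_glucose_sodium_adduct_monoisotopic():
    mz = ion_mz(parse_formula("C6H12O6"), "[M+Na]+", mode="monoisotopic")
    assert mz == pytest.approx(203.053, abs=2e-3)


def test_multiply_charged_adducts_rejected():
    with pytest.raises(ValueError):
        chem.AdductSpec("[M+2H]2+", parse_formula("H2"), ElementalFormula(), 2)


# -- isotope patterns ------------------------------------------------------


def brute_force_pattern(f, table, K):
    """Independent oracle: exhaustive enumeration of per-element isotope
    compositions with multinomial weights (not convolution)."""

    def element_patterns(abund, n):
        k = len(abund)
        out = {}
        for combo in itertools.product(range(n + 1), repeat=k):
            if sum(combo) != n:
                continue
            w = math.factorial(n)
            p = 1.0
            for cnt, a in zip(combo, abund):
                w //= math.factorial(cnt)
                p *= a**cnt
            shift = sum(i * cnt for i, cnt in enumerate(combo))
            out[shift] = out.get(shift, 0.0) + w * p
        return out

    total = {0: 1.0}
    for el, n in f.counts.items():
        per = element_patterns(table[el], n)
        nxt = {}
        for s1, p1 in total.items():
            for s2, p2 in per.items():
                nxt[s1 + s2] = nxt.get(s1 + s2, 0.0) + p1 * p2
        total = nxt
    vec = np.zeros(K + 1)
    for s, p in total.items():
        if s <= K:
            vec[s] = p
    return vec


@pytest.mark.parametrize("text", ["C1", "C6H12O6", "C3H6O2", "C2H4O2S"])
def test_natural_pattern_matches_enumeration_oracle(text, nat_table):
    f = parse_formula(text)
    K = 6
    pat = natural_isotope_pattern(f, nat_table, K)
    oracle = brute_force_pattern(f, nat_table, K)
    assert np.abs(pat.fractions - oracle).max() < 1e-9


def test_empty_formula_is_delta(nat_table):
    pat = natural_isotope_pattern(ElementalFormula(), nat_table, 3)
    assert pat.fractions[0] == 1.0 and pat.fractions[1:].sum() == 0.0


def test_single_carbon_pattern(nat_table):
    pat = natural_isotope_pattern(parse_formula("C1"), nat_table, 1)
    assert pat.fractions == pytest.approx([0.9893, 0.0107])


def test_principal_only_table_gives_delta(principal_table):
    pat = natural_isotope_pattern(parse_formula("C24H40N7O17P3S"), principal_table, 4)
    assert pat.fractions[0] == pytest.approx(1.0)


def test_pattern_mass_conservation(nat_table):
    pat = natural_isotope_pattern(parse_formula("C40H80O10S2Si3"), nat_table, 3)
    assert pat.tail >= 0
    assert pat.fractions.sum() + pat.tail == pytest.approx(1.0, abs=1e-9)


def test_convolution_identity_and_shift():
    delta0 = IsotopePattern(np.array([1.0]))
    p = IsotopePattern(np.array([0.5, 0.5]))
    assert np.allclose(convolve_patterns(p, delta0).fractions, p.fractions)
    d1 = IsotopePattern(np.array([0.0, 1.0]))
    d2 = IsotopePattern(np.array([0.0, 0.0, 1.0]))
    out = convolve_patterns(d1, d2)
    assert out.fractions[3] == pytest.approx(1.0)
    hand = convolve_patterns(p, p)
    assert hand.fractions == pytest.approx([0.25, 0.5, 0.25])


def test_convolution_commutes(nat_table):
    p = natural_isotope_pattern(parse_formula("C6H12O6"), nat_table, 4)
    q = natural_isotope_pattern(parse_formula("C3H6O2"), nat_table, 4)
    assert np.allclose(
        convolve_patterns(p, q).fractions, convolve_patterns(q, p).fractions
    )


# -- beta-oxidation stoichiometry ------------------------------------------


@pytest.mark.parametrize("c,expected", [(17, (7, 1)), (3, (0, 1)), (16, (8, 0)), (2, (1, 0))])
def test_odd_chain_beta_oxidation(c, expected):
    assert odd_chain_beta_oxidation(c) == expected


@given(st.integers(min_value=2, max_value=40))
def test_beta_oxidation_conserves_carbon(c):
    a, p = odd_chain_beta_oxidation(c)
    assert 2 * a + 3 * p == c


def test_beta_oxidation_rejects_short_chain():
    with pytest.raises(ValueError):
        odd_chain_beta_oxidation(1)
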