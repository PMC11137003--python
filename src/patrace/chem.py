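"""Formula algebra, masses, and natural-isotope patterns.

The unit-resolution mass bookkeeping used throughout the package lives
here: elemental formulas (including explicitly labeled heavy atoms such as
``[13C]`` or ``D``), nominal and monoisotopic masses, derivatization and
adduct arithmetic for MRM precursor ions, natural-abundance isotope
patterns obtained by convolution over atoms, and the odd-chain
beta-oxidation stoichiometry.

Heavy tracer atoms are first-class element symbols (``D``/``[2H]``,
``[13C]``, ``[15N]``) with their own mass numbers and *no* natural spread,
so derivative arithmetic and tracer math share one formula type.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ElementalFormula",
    "IsotopeAbundanceTable",
    "IsotopePattern",
    "DerivativeSpec",
    "AdductSpec",
    "DERIVATIVES",
    "ADDUCTS",
    "parse_formula",
    "nominal_mass",
    "monoisotopic_mass",
    "apply_derivative",
    "ion_mz",
    "natural_isotope_pattern",
    "convolve_patterns",
    "odd_chain_beta_oxidation",
]

# ---------------------------------------------------------------------------
# Element data
# ---------------------------------------------------------------------------

#: Mass number of the most abundant isotope; heavy labels carry their own.
NOMINAL_MASS: dict[str, int] = {
    "H": 1, "C": 12, "N": 14, "O": 16, "P": 31, "S": 32, "Si": 28, "Na": 23,
    "Cl": 35, "K": 39,
    "D": 2, "[2H]": 2, "[13C]": 13, "[15N]": 15,
}

#: Exact mass of the principal isotope (heavy labels: their exact mass).
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503, "C": 12.0, "N": 14.00307401, "O": 15.99491462,
    "P": 30.97376200, "S": 31.97207117, "Si": 27.97692653, "Na": 22.98976928,
    "Cl": 34.96885268, "K": 38.96370649,
    "D": 2.01410178, "[2H]": 2.01410178,
    "[13C]": 13.00335484, "[15N]": 15.00010890,
}

_TOKEN = re.compile(r"(\[\d+[A-Z][a-z]?\]|[A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Element-symbol -> count mapping with element-wise arithmetic.

    Counts are non-negative; subtraction that would underflow raises
    ``ValueError`` naming the offending element. Zero counts are elided.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for element {el!r}")
            if n > 0:
                clean[el] = n
        object.__setattr__(self, "counts", clean)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            have = merged.get(el, 0)
            if n > have:
                raise ValueError(
                    f"formula subtraction underflows element {el!r} "
                    f"({have} - {n})"
                )
            merged[el] = have - n
        return ElementalFormula(merged)

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def formatted(self) -> str:
        """Hill-order string (C, H, then alphabetical; labels as tokens)."""
        def key(el: str) -> tuple[int, str]:
            order = {"C": 0, "H": 1}
            return (order.get(el, 2), el)

        parts = []
        for el in sorted(self.counts, key=key):
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.formatted()


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string into an :class:`ElementalFormula`.

    Isotope labels use bracket notation (``[13C]3H6O2``); ``D`` is accepted
    as an alias for ``[2H]``. Unknown element symbols raise ``ValueError``.

    >>> parse_formula("H2O").counts
    {'H': 2, 'O': 1}
    """
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            raise ValueError(f"malformed formula token at {text[pos:]!r}")
        el, num = m.group(1), m.group(2)
        if el == "[2H]":
            el = "D"
        if el not in NOMINAL_MASS:
            raise ValueError(f"unknown element symbol {el!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    return ElementalFormula(counts)


# ---------------------------------------------------------------------------
# Masses
# ---------------------------------------------------------------------------

def nominal_mass(f: ElementalFormula) -> int:
    """Integer mass: sum of mass numbers of each element's principal isotope.

    Matches the unit-resolution MRM bookkeeping of quadrupole instruments;
    heavy labels are counted at their own mass numbers.
    """
    try:
        return sum(NOMINAL_MASS[el] * n for el, n in f.counts.items())
    except KeyError as exc:  # pragma: no cover - guarded by parse
        raise ValueError(f"no nominal mass for element {exc.args[0]!r}") from exc


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Exact mass: sum of principal-isotope exact masses (0.0 for empty)."""
    try:
        return float(sum(MONOISOTOPIC_MASS[el] * n for el, n in f.counts.items()))
    except KeyError as exc:
        raise ValueError(f"no exact mass for element {exc.args[0]!r}") from exc


# ---------------------------------------------------------------------------
# Derivatives and adducts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DerivativeSpec:
    """A derivatization as a formula delta (atoms added, atoms removed)."""

    name: str
    added: ElementalFormula
    removed: ElementalFormula = field(default_factory=ElementalFormula)


#: Derivatizations used by the assays: 3-NPH acylhydrazide formation on
#: carboxylic acids (condensation, loses water), acid methyl esterification
#: (HCl/methanol, net +CH2), TBDMS silylation of an exchangeable H, and
#: methoximation of a carbonyl (net +CH3N).
DERIVATIVES: dict[str, DerivativeSpec] = {
    "3NPH": DerivativeSpec("3NPH", parse_formula("C6H7N3O2"), parse_formula("H2O")),
    "methyl_ester": DerivativeSpec("methyl_ester", parse_formula("CH2")),
    "TBDMS": DerivativeSpec("TBDMS", parse_formula("C6H15Si"), parse_formula("H")),
    "methoxime": DerivativeSpec("methoxime", parse_formula("CH3N")),
}


@dataclass(frozen=True)
class AdductSpec:
    """Singly-charged ionization adduct as a formula delta + charge sign."""

    name: str
    added: ElementalFormula
    removed: ElementalFormula
    charge: int

    def __post_init__(self) -> None:
        if abs(self.charge) != 1:
            raise ValueError("only singly charged adducts are supported")


ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", parse_formula("H"), ElementalFormula(), +1),
    "[M-H]-": AdductSpec("[M-H]-", ElementalFormula(), parse_formula("H"), -1),
    "[M+Na]+": AdductSpec("[M+Na]+", parse_formula("Na"), ElementalFormula(), +1),
}


def apply_derivative(
    f: ElementalFormula, d: DerivativeSpec | str, count: int = 1
) -> ElementalFormula:
    """Apply a derivatization delta ``count`` times (count=0 is identity)."""
    if isinstance(d, str):
        d = DERIVATIVES[d]
    if count < 0:
        raise ValueError("derivative count must be >= 0")
    out = f
    for _ in range(count):
        out = (out + d.added) - d.removed
    return out


def ion_mz(
    f: ElementalFormula, a: AdductSpec | str, mode: str = "nominal"
) -> float:
    """m/z of the adduct ion of ``f`` (charge 1) under nominal or exact mass."""
    if isinstance(a, str):
        a = ADDUCTS[a]
    ion = (f + a.added) - a.removed
    if mode == "nominal":
        return float(nominal_mass(ion))
    if mode == "monoisotopic":
        return monoisotopic_mass(ion)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Isotope patterns
# ---------------------------------------------------------------------------

class IsotopeAbundanceTable:
    """Per-element natural isotope abundances keyed by integer mass shift.

    Shifts are contiguous from 0 and each element's abundances sum to 1.
    The default table ships as a packaged CSV of representative terrestrial
    values and may be overridden by a user CSV of identical schema
    (``element, mass_shift, abundance``).
    """

    def __init__(self, patterns: Mapping[str, np.ndarray], provenance: str = "user"):
        self.provenance = provenance
        self._patterns: dict[str, np.ndarray] = {}
        for el, vec in patterns.items():
            vec = np.asarray(vec, dtype=float)
            if vec.ndim != 1 or vec.size == 0 or np.any(vec < 0):
                raise ValueError(f"invalid abundance vector for {el!r}")
            if abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"abundances for {el!r} sum to {vec.sum()!r}, not 1"
                )
            self._patterns[el] = vec

    def __contains__(self, el: str) -> bool:
        return el in self._patterns

    def __getitem__(self, el: str) -> np.ndarray:
        try:
            return self._patterns[el]
        except KeyError:
            raise KeyError(f"element {el!r} missing from abundance table") from None

    def elements(self) -> Iterable[str]:
        return self._patterns.keys()

    @classmethod
    def from_csv(cls, path, provenance: str = "user") -> "IsotopeAbundanceTable":
        df = pd.read_csv(path)
        patterns = {}
        for el, sub in df.groupby("element", sort=False):
            sub = sub.sort_values("mass_shift")
            shifts = sub["mass_shift"].to_numpy()
            if not np.array_equal(shifts, np.arange(len(shifts))):
                raise ValueError(f"mass shifts for {el!r} not contiguous from 0")
            patterns[el] = sub["abundance"].to_numpy(dtype=float)
        return cls(patterns, provenance=provenance)

    @classmethod
    def default(cls) -> "IsotopeAbundanceTable":
        """Representative natural abundances from the packaged CSV."""
        ref = resources.files("patrace").joinpath("data/isotopes.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path, provenance="default")

    @classmethod
    def principal_only(cls) -> "IsotopeAbundanceTable":
        """Degenerate table with every atom at its principal isotope
        (useful as an identity control for correction matrices)."""
        return cls(
            {el: np.array([1.0]) for el in NOMINAL_MASS},
            provenance="principal-only",
        )


@dataclass(frozen=True)
class IsotopePattern:
    """Probability vector over integer mass shifts 0..K.

    ``tail`` is the probability mass lost to truncation at K; the stored
    fractions plus the tail sum to 1 within 1e-9.
    """

    fractions: np.ndarray
    tail: float = 0.0

    def __post_init__(self) -> None:
        vec = np.asarray(self.fractions, dtype=float)
        if np.any(vec < -1e-12):
            raise ValueError("isotope pattern has negative entries")
        object.__setattr__(self, "fractions", np.clip(vec, 0.0, None))
        if self.tail < -1e-12:
            raise ValueError("negative truncation tail")
        total = float(self.fractions.sum() + self.tail)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pattern mass {total!r} != 1")

    def __len__(self) -> int:
        return len(self.fractions)


def convolve_patterns(p: IsotopePattern, q: IsotopePattern) -> IsotopePattern:
    """Discrete convolution of two shift distributions (commutative;
    the delta at shift 0 is the identity)."""
    frac = np.convolve(p.fractions, q.fractions)
    # cross terms with either tail are unresolvable; fold them into the tail
    tail = 1.0 - float(frac.sum())
    return IsotopePattern(frac, tail=max(tail, 0.0))


def _single_element_pattern(abund: np.ndarray, n: int, K: int) -> np.ndarray:
    """Shift distribution of n i.i.d. atoms, truncated at K (untracked tail)."""
    out = np.zeros(K + 1)
    out[0] = 1.0
    # repeated truncated convolution; K is small so this is cheap
    for _ in range(n):
        out = np.convolve(out, abund)[: K + 1]
    return out


def natural_isotope_pattern(
    f: ElementalFormula,
    table: IsotopeAbundanceTable | None = None,
    K: int | None = None,
) -> IsotopePattern:
    """Natural-abundance isotopologue pattern of a formula.

    The pattern is the convolution over all atoms of the per-element
    single-atom shift distributions, truncated at shift ``K`` (default:
    untruncated, i.e. the maximum possible shift). The empty formula gives
    the delta at 0; an all-principal-isotope table likewise.
    """
    if table is None:
        table = IsotopeAbundanceTable.default()
    max_shift = sum(
        (len(table[el]) - 1) * n for el, n in f.counts.items()
    )
    if K is None:
        K = max_shift
    if K < 0:
        raise ValueError("K must be >= 0")
    out = np.zeros(K + 1)
    out[0] = 1.0
    for el, n in f.counts.items():
        out = np.convolve(out, _single_element_pattern(table[el], n, K))[: K + 1]
    tail = max(1.0 - float(out.sum()), 0.0)
    return IsotopePattern(out, tail=tail)


# ---------------------------------------------------------------------------
# Odd-chain beta-oxidation stoichiometry
# ---------------------------------------------------------------------------

def odd_chain_beta_oxidation(chain_carbons: int) -> tuple[int, int]:
    """Acetyl-CoA / propionyl-CoA yield of complete beta-oxidation.

    An odd-chain fatty acid with C carbons yields ((C-3)/2 acetyl-CoA,
    1 propionyl-CoA); an even chain yields (C/2, 0). Carbon is conserved:
    2*acetyl + 3*propionyl = C. Heptadecanoate (C17) gives (7, 1).
    """
    if chain_carbons < 2:
        raise ValueError("chain must have at least 2 carbons")
    if chain_carbons % 2 == 1:
        return ((chain_carbons - 3) // 2, 1)
    return (chain_carbons // 2, 0)
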