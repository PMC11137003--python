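"""Natural-abundance correction of mass isotopologue distributions.

Measured MIDs of derivatized fragments mix tracer labeling with the
natural heavy-isotope background of every atom in the measured ion
(backbone, derivative groups, silicon of TBDMS, ...). This module builds
the correction matrix whose column j is the expected measured pattern of
the species carrying j tracer atoms, deconvolves measured vectors back to
tracer-only isotopologue fractions by non-negative least squares, and
computes the average-carbon-labeling summary statistic

    avg labeling = (m1*1 + m2*2 + ... + mn*n) / n

used to report fractional carbon incorporation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .chem import (
    DERIVATIVES,
    DerivativeSpec,
    ElementalFormula,
    IsotopeAbundanceTable,
    IsotopePattern,
    apply_derivative,
    convolve_patterns,
    natural_isotope_pattern,
    parse_formula,
)

__all__ = [
    "TracerSpec",
    "FragmentContext",
    "load_fragment_registry",
    "fragment_context",
    "MIDVector",
    "CorrectionMatrix",
    "build_correction_matrix",
    "forward_convolve",
    "correct_mid",
    "average_carbon_labeling",
    "enrichment_summary",
]

DEFAULT_PURITY = 0.99


@dataclass(frozen=True)
class TracerSpec:
    """One labeled element of a tracer: symbol, number of labelable
    backbone positions, and isotopic purity of the label."""

    element: str
    n_positions: int
    purity: float = DEFAULT_PURITY

    def __post_init__(self) -> None:
        if self.n_positions <= 0:
            raise ValueError("n_positions must be positive")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")


@dataclass(frozen=True)
class FragmentContext:
    """The measured fragment: analyte backbone, derivatizations applied,
    and the tracer(s) whose atoms must be excluded from natural spread.

    Dual-label tracers (e.g. one 15N plus five 13C) are represented as two
    TracerSpecs; at unit resolution their mass shifts share one axis, so
    the combined ladder has ``sum(n_positions)`` rungs. Ladder rungs are
    filled in list order (first tracer's positions first).
    """

    backbone: ElementalFormula
    derivatives: tuple[DerivativeSpec, ...] = ()
    tracers: tuple[TracerSpec, ...] = ()

    @classmethod
    def create(cls, backbone, derivatives=(), tracers=()) -> "FragmentContext":
        if isinstance(backbone, str):
            backbone = parse_formula(backbone)
        derivs = tuple(
            DERIVATIVES[d] if isinstance(d, str) else d for d in derivatives
        )
        tracers = tuple(tracers)
        for t in tracers:
            if t.n_positions > backbone[t.element]:
                raise ValueError(
                    f"tracer claims {t.n_positions} {t.element} positions but "
                    f"backbone has {backbone[t.element]}"
                )
        return cls(backbone, derivs, tracers)

    @property
    def full_formula(self) -> ElementalFormula:
        out = self.backbone
        for d in self.derivatives:
            out = apply_derivative(out, d)
        return out

    @property
    def n_tracer_positions(self) -> int:
        return sum(t.n_positions for t in self.tracers)

    def _ladder(self, j: int) -> list[tuple[TracerSpec, int]]:
        """How j heavy atoms distribute over the tracers (fill in order)."""
        out = []
        remaining = j
        for t in self.tracers:
            take = min(remaining, t.n_positions)
            if take:
                out.append((t, take))
            remaining -= take
        if remaining:
            raise ValueError(f"ladder rung {j} exceeds tracer positions")
        return out


@dataclass
class MIDVector:
    """Mol fractions m0..mN over integer mass shifts.

    ``state`` records whether the vector is as measured (still carrying
    natural-abundance background, N >= n) or corrected (tracer-only,
    N == n). Fractions are normalized to sum 1.
    """

    fractions: np.ndarray
    state: str
    n: int

    def __post_init__(self) -> None:
        vec = np.asarray(self.fractions, dtype=float)
        if vec.ndim != 1 or vec.size == 0:
            raise ValueError("MID must be a non-empty 1-D vector")
        if np.any(vec < -1e-9):
            raise ValueError("MID has negative fractions")
        total = vec.sum()
        if total <= 0:
            raise ValueError("MID is all zero")
        self.fractions = np.clip(vec, 0.0, None) / np.clip(vec, 0.0, None).sum()
        if self.state not in ("measured", "corrected"):
            raise ValueError(f"unknown state {self.state!r}")
        if self.state == "corrected" and len(self.fractions) != self.n + 1:
            raise ValueError("corrected MID must have exactly n+1 entries")
        if self.state == "measured" and len(self.fractions) < self.n + 1:
            raise ValueError("measured MID shorter than tracer ladder")

    def __len__(self) -> int:
        return len(self.fractions)


@dataclass
class CorrectionMatrix:
    """(K+1) x (n+1) matrix; column j is the expected measured pattern of
    the j-labeled species (truncated natural pattern x tracer purity)."""

    matrix: np.ndarray
    condition_number: float = field(default=np.nan)

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.ndim != 2:
            raise ValueError("correction matrix must be 2-D")
        if np.any(M < -1e-12) or np.any(M > 1 + 1e-12):
            raise ValueError("matrix entries must lie in [0, 1]")
        self.matrix = np.clip(M, 0.0, 1.0)
        if math.isnan(self.condition_number):
            self.condition_number = float(np.linalg.cond(self.matrix))

    @property
    def n(self) -> int:
        return self.matrix.shape[1] - 1


def _purity_binomial(ladder: list[tuple[TracerSpec, int]]) -> np.ndarray:
    """Shift distribution of j nominally-heavy tracer atoms allowing for
    isotopic impurity: each atom is heavy with probability = purity."""
    out = np.array([1.0])
    for tracer, count in ladder:
        p = tracer.purity
        single = np.array([1.0 - p, p])
        for _ in range(count):
            out = np.convolve(out, single)
    return out


def build_correction_matrix(
    ctx: FragmentContext,
    K: int | None = None,
    table: IsotopeAbundanceTable | None = None,
) -> CorrectionMatrix:
    """Correction matrix for a derivatized fragment.

    Column j is the natural pattern of the full fragment formula minus j
    atoms of the labeled element(s), shifted by j, convolved with the
    tracer-purity binomial over the j nominally labeled positions, and
    truncated to K+1 rows (default K = n_tracer_positions + 4).

    With an all-principal-isotope table and purity 1 this is the identity.
    """
    if table is None:
        table = IsotopeAbundanceTable.default()
    n = ctx.n_tracer_positions
    if n == 0:
        raise ValueError("fragment context has no tracer positions")
    if K is None:
        K = n + 4
    if K < n:
        raise ValueError("K must cover the tracer ladder (K >= n)")
    full = ctx.full_formula
    for t in ctx.tracers:
        if full[t.element] < t.n_positions:
            raise ValueError(
                f"tracer element {t.element!r} deficient in fragment formula"
            )
    M = np.zeros((K + 1, n + 1))
    for j in range(n + 1):
        ladder = ctx._ladder(j)
        reduced = full
        for tracer, count in ladder:
            reduced = reduced - ElementalFormula({tracer.element: count})
        nat = natural_isotope_pattern(reduced, table, K).fractions
        binom = _purity_binomial(ladder)
        col = np.convolve(nat, binom)[: K + 1]
        M[:, j] = col
    return CorrectionMatrix(M)


def forward_convolve(true_mid: MIDVector, M: CorrectionMatrix) -> MIDVector:
    """Simulate the measurement: measured = M @ true, renormalized.

    Inverse direction of :func:`correct_mid`; used by the synthetic-data
    generator to put natural-abundance background back onto true MIDs.
    """
    if true_mid.state != "corrected":
        raise ValueError("forward_convolve expects a corrected (true) MID")
    if len(true_mid) != M.matrix.shape[1]:
        raise ValueError("MID length does not match matrix columns")
    measured = M.matrix @ true_mid.fractions
    return MIDVector(measured, state="measured", n=true_mid.n)


def correct_mid(
    measured: MIDVector,
    M: CorrectionMatrix,
    method: str = "nnls",
) -> tuple[MIDVector, float]:
    """Deconvolve a measured MID to tracer-only fractions.

    Solves measured ~ M @ x with x >= 0 (non-negative least squares by
    default; ``method="lstsq"`` gives the unconstrained solution for
    oracle comparison), renormalizes x to sum 1, and returns the corrected
    MID together with the residual norm of the fit.
    """
    if measured.state != "measured":
        raise ValueError("correct_mid expects a measured MID")
    if len(measured) != M.matrix.shape[0]:
        raise ValueError("MID length does not match matrix rows")
    cond = M.condition_number
    if cond > 1e8:
        warnings.warn(
            f"correction matrix nearly rank-deficient (cond={cond:.3g}); "
            "solving anyway",
            RuntimeWarning,
            stacklevel=2,
        )
    if method == "nnls":
        x, resid = nnls(M.matrix, measured.fractions)
    elif method == "lstsq":
        x, *_ = np.linalg.lstsq(M.matrix, measured.fractions, rcond=None)
        resid = float(np.linalg.norm(M.matrix @ x - measured.fractions))
        x = np.clip(x, 0.0, None)
    else:
        raise ValueError(f"unknown method {method!r}")
    if x.sum() <= 0:
        raise ValueError("deconvolution produced an all-zero solution")
    return MIDVector(x, state="corrected", n=M.n), float(resid)


def load_fragment_registry(path=None):
    """Fragment registry CSV: metabolite, backbone formula, derivatization
    names (semicolon list), tracer positions (``El:count`` semicolon list).
    Loads the packaged default unless a path is given."""
    import pandas as pd
    from importlib import resources

    if path is None:
        ref = resources.files("patrace").joinpath("data/fragments.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, keep_default_na=False)
    else:
        df = pd.read_csv(path, keep_default_na=False)
    return df.set_index("metabolite", drop=False)


def fragment_context(
    metabolite: str,
    registry=None,
    purity: float = DEFAULT_PURITY,
) -> FragmentContext:
    """Build the :class:`FragmentContext` for a registry metabolite."""
    if registry is None:
        registry = load_fragment_registry()
    if metabolite not in registry.index:
        raise KeyError(f"metabolite {metabolite!r} not in fragment registry")
    row = registry.loc[metabolite]
    derivs = [d for d in str(row["derivatives"]).split(";") if d]
    tracers = []
    for tok in str(row["tracers"]).split(";"):
        if not tok:
            continue
        el, n = tok.split(":")
        tracers.append(TracerSpec(el, int(n), purity=purity))
    return FragmentContext.create(row["backbone_formula"], derivs, tracers)


def average_carbon_labeling(corrected: MIDVector) -> float:
    """Fraction of labelable positions carrying tracer:
    sum_i(m_i * i) / n, in [0, 1]; equals m1 when n = 1."""
    if corrected.state != "corrected":
        raise ValueError("average labeling requires a corrected MID")
    if corrected.n < 1:
        raise ValueError("n must be >= 1")
    idx = np.arange(len(corrected.fractions))
    return float((corrected.fractions * idx).sum() / corrected.n)


def enrichment_summary(corrected: MIDVector, which: int) -> float:
    """Mol fraction of a single isotopologue (e.g. M1 of glutamate to read
    out nitrogen transfer, M2 of glucose for the di-deuterated tracer)."""
    if corrected.state != "corrected":
        raise ValueError("enrichment requires a corrected MID")
    if not 0 <= which <= corrected.n:
        raise ValueError(f"isotopologue index {which} out of range 0..{corrected.n}")
    return float(corrected.fractions[which])
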