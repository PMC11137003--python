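"""Correction matrices, MID deconvolution, and labeling summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patrace import mid
from patrace.chem import natural_isotope_pattern, parse_formula
from patrace.mid import (
    FragmentContext,
    MIDVector,
    TracerSpec,
    average_carbon_labeling,
    build_correction_matrix,
    correct_mid,
    enrichment_summary,
    forward_convolve,
    fragment_context,
    load_fragment_registry,
)


def toy_context(purity=1.0):
    # 2-carbon backbone, fully 13C-labelable, no derivative
    return FragmentContext.create("C2H4O2", [], [TracerSpec("C", 2, purity)])


# -- matrix construction ---------------------------------------------------


def test_principal_table_purity_one_gives_identity(principal_table):
    M = build_correction_matrix(toy_context(), table=principal_table)
    assert np.allclose(M.matrix[:3, :], np.eye(3))
    assert np.allclose(M.matrix[3:, :], 0.0)


def test_fully_labeled_column_is_shifted_natural_pattern(nat_table):
    # column 2 of a C2 fragment = delta2 (x) natural pattern of H4O2
    ctx = toy_context()
    M = build_correction_matrix(ctx, K=6, table=nat_table)
    residue = natural_isotope_pattern(parse_formula("H4O2"), nat_table, 4).fractions
    expected = np.zeros(7)
    expected[2:7] = residue[:5]
    assert np.allclose(M.matrix[:, 2], expected, atol=1e-12)


def test_purity_leak_matches_binomial(principal_table):
    # with principal-isotope atoms, column 1 at purity p is [1-p, p]
    p = 0.9
    M = build_correction_matrix(toy_context(purity=p), table=principal_table)
    assert M.matrix[0, 1] == pytest.approx(1 - p)
    assert M.matrix[1, 1] == pytest.approx(p)
    # column 2 is the full binomial [(1-p)^2, 2p(1-p), p^2]
    assert M.matrix[:3, 2] == pytest.approx([(1 - p) ** 2, 2 * p * (1 - p), p**2])


def test_matrix_columns_are_subprobability(nat_table):
    ctx = fragment_context("propionylcarnitine")
    M = build_correction_matrix(ctx, table=nat_table)
    sums = M.matrix.sum(axis=0)
    assert np.all(sums <= 1 + 1e-12) and np.all(sums > 0.9)


def test_tracer_element_absent_raises(nat_table):
    ctx = FragmentContext(parse_formula("H2O"), (), (TracerSpec("C", 1),))
    with pytest.raises(ValueError):
        build_correction_matrix(ctx, table=nat_table)


# -- forward / inverse -----------------------------------------------------


def test_forward_of_delta0_is_column_zero(nat_table):
    M = build_correction_matrix(toy_context(), table=nat_table)
    true = MIDVector(np.array([1.0, 0.0, 0.0]), "corrected", 2)
    out = forward_convolve(true, M)
    col0 = M.matrix[:, 0]
    assert np.allclose(out.fractions, col0 / col0.sum())


def test_correcting_unlabeled_natural_pattern_gives_delta0(nat_table):
    ctx = fragment_context("propionylcarnitine")
    M = build_correction_matrix(ctx, table=nat_table)
    measured = MIDVector(M.matrix[:, 0], "measured", 3)
    corrected, resid = correct_mid(measured, M)
    assert corrected.fractions[0] == pytest.approx(1.0, abs=1e-6)
    assert resid < 1e-9


@pytest.mark.parametrize("metabolite", ["glucose", "valine", "propionylcarnitine", "citrate"])
def test_roundtrip_recovers_truth_noiseless(metabolite, rng):
    ctx = fragment_context(metabolite)
    n = ctx.n_tracer_positions
    M = build_correction_matrix(ctx)
    x = rng.dirichlet(np.ones(n + 1))
    measured = forward_convolve(MIDVector(x, "corrected", n), M)
    corrected, _ = correct_mid(measured, M)
    assert np.abs(corrected.fractions - x).max() < 1e-6


def test_nnls_and_lstsq_agree_noiseless(rng):
    ctx = fragment_context("valine")
    M = build_correction_matrix(ctx)
    x = rng.dirichlet(np.ones(ctx.n_tracer_positions + 1))
    measured = forward_convolve(MIDVector(x, "corrected", ctx.n_tracer_positions), M)
    a, _ = correct_mid(measured, M, method="nnls")
    b, _ = correct_mid(measured, M, method="lstsq")
    assert np.abs(a.fractions - b.fractions).max() < 1e-8


def test_corrected_vectors_nonnegative_normalized(rng):
    ctx = fragment_context("citrate")
    M = build_correction_matrix(ctx)
    for _ in range(20):
        x = rng.dirichlet(np.ones(7))
        measured = forward_convolve(MIDVector(x, "corrected", 6), M)
        noisy = measured.fractions * (1 + 0.05 * rng.standard_normal(len(measured)))
        corrected, _ = correct_mid(MIDVector(np.abs(noisy), "measured", 6), M)
        assert np.all(corrected.fractions >= 0)
        assert corrected.fractions.sum() == pytest.approx(1.0, abs=1e-6)


def test_dimension_mismatch_rejected(nat_table):
    M = build_correction_matrix(toy_context(), table=nat_table)
    with pytest.raises(ValueError):
        forward_convolve(MIDVector(np.array([0.5, 0.5]), "corrected", 1), M)
    with pytest.raises(ValueError):
        correct_mid(MIDVector(np.ones(4) / 4, "measured", 2), M)


def test_all_zero_measured_rejected():
    with pytest.raises(ValueError):
        MIDVector(np.zeros(4), "measured", 2)


# -- summaries -------------------------------------------------------------


@pytest.mark.parametrize(
    "fractions,n,expected",
    [
        ([1, 0, 0, 0], 3, 0.0),           # unlabeled
        ([0, 0, 0, 1], 3, 1.0),           # fully labeled
        ([0, 0.5, 0.5, 0], 3, 0.5),       # (0.5*1 + 0.5*2)/3
    ],
)
def test_average_carbon_labeling(fractions, n, expected):
    v = MIDVector(np.array(fractions, dtype=float), "corrected", n)
    assert average_carbon_labeling(v) == pytest.approx(expected)


@given(st.integers(min_value=1, max_value=8), st.integers(0, 2**32 - 1))
@settings(max_examples=50, deadline=None)
def test_average_labeling_bounds_and_linearity(n, seed):
    r = np.random.default_rng(seed)
    x = r.dirichlet(np.ones(n + 1))
    y = r.dirichlet(np.ones(n + 1))
    ax = average_carbon_labeling(MIDVector(x, "corrected", n))
    ay = average_carbon_labeling(MIDVector(y, "corrected", n))
    assert 0.0 <= ax <= 1.0
    lam = 0.3
    mix = average_carbon_labeling(MIDVector(lam * x + (1 - lam) * y, "corrected", n))
    assert mix == pytest.approx(lam * ax + (1 - lam) * ay, abs=1e-12)
    if n == 1:
        assert ax == pytest.approx(x[1] / x.sum())


def test_enrichment_summary_read_off():
    v = MIDVector(np.array([0.8, 0.15, 0.05]), "corrected", 2)
    assert enrichment_summary(v, 1) == pytest.approx(0.15)
    with pytest.raises(ValueError):
        enrichment_summary(v, 3)


def test_delta0_enrichments():
    v = MIDVector(np.array([1.0, 0.0]), "corrected", 1)
    assert enrichment_summary(v, 0) == 1.0
    assert enrichment_summary(v, 1) == 0.0


# -- registry --------------------------------------------------------------


def test_registry_contexts_build():
    reg = load_fragment_registry()
    for met in reg.index:
        ctx = fragment_context(met, reg)
        assert ctx.n_tracer_positions >= 1
        # dual-label valine carries 5 carbons + 1 nitrogen on one axis
        if met == "valine":
            assert ctx.n_tracer_positions == 6


def test_dual_label_matrix_shape():
    ctx = fragment_context("valine")
    M = build_correction_matrix(ctx)
    assert M.matrix.shape == (11, 7)  # K = n + 4 rows, n = 6


def test_tracer_positions_cannot_exceed_backbone():
    with pytest.raises(ValueError):
        FragmentContext.create("C2H4O2", [], [TracerSpec("C", 3)])
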