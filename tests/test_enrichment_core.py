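import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from mitonux.annotation_io import GeneRecord, AnnotationTable
from mitonux.enrichment_core import (
    ContingencyTable,
    EnrichmentError,
    EnrichmentResult,
    build_location_table,
    build_overlap_table,
    conditional_mle_odds_ratio,
    fisher_exact_two_sided,
    sample_odds_ratio,
)

from conftest import make_table


def exact_fisher_oracle(a, b, c, d):
    """Two-sided P by exhaustive enumeration in rational arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = math.comb(n, c1)
    pmf = {
        k: Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
        for k in range(lo, hi + 1)
    }
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs))


# --- table construction ---------------------------------------------------


def test_location_table_minimal_balanced(four_gene_table, gene_set):
    t = build_location_table(gene_set("f", ["x1", "a1"]), four_gene_table)
    assert t.counts() == (1, 1, 1, 1)


def test_location_table_focal_equals_background(four_gene_table, gene_set):
    t = build_location_table(
        gene_set("f", ["x1", "x2", "a1", "a2"]), four_gene_table
    )
    assert (t.c, t.d) == (0, 0) and t.counts() == (2, 2, 0, 0)


def test_location_table_disjoint_focal_is_error(four_gene_table, gene_set):
    with pytest.raises(EnrichmentError):
        build_location_table(gene_set("f", ["nope"]), four_gene_table)


def test_location_table_excludes_unknown_arms(gene_set):
    table = make_table(["X", "2L", "unknown", "unknown"])
    t = build_location_table(gene_set("f", ["g0", "g2"]), table)
    # g2 is unplaced: dropped from both margins
    assert t.counts() == (1, 0, 0, 1)


def test_overlap_table_set_arithmetic(gene_set):
    table = make_table(["2L"] * 1000)
    focal = gene_set("f", [f"g{i}" for i in range(100)])
    prop = gene_set("p", [f"g{i}" for i in range(80, 130)])
    t = build_overlap_table(focal, prop, table)
    assert t.counts() == (20, 80, 30, 870)


def test_overlap_table_degenerate_margins(gene_set):
    table = make_table(["2L"] * 10)
    focal = gene_set("f", ["g0", "g1"])
    t = build_overlap_table(focal, focal, table)
    assert t.counts() == (2, 0, 0, 8)
    t2 = build_overlap_table(focal, gene_set("p", ["g5"]), table)
    assert t2.a == 0


# --- odds ratios ----------------------------------------------------------


def test_sample_or_symmetry_and_reference_tables():
    assert sample_odds_ratio(ContingencyTable(1, 1, 1, 1)) == 1.0
    # reconstructed published tables print at two decimals
    assert round(sample_odds_ratio(ContingencyTable(166, 1045, 1778, 9161)), 2) == 0.82
    assert round(sample_odds_ratio(ContingencyTable(78, 341, 2323, 12751)), 2) == 1.26


def test_sample_or_zero_cell_requires_correction():
    t = ContingencyTable(5, 0, 3, 2)
    with pytest.raises(EnrichmentError):
        sample_odds_ratio(t)
    corrected = sample_odds_ratio(t, zero_cell_correction=True)
    assert corrected == (5.5 * 2.5) / (0.5 * 3.5)


def test_contingency_rejects_bad_cells():
    with pytest.raises(EnrichmentError):
        ContingencyTable(0, 0, 0, 0)
    with pytest.raises(EnrichmentError):
        ContingencyTable(-1, 2, 3, 4)


# --- exact test -----------------------------------------------------------


def test_fisher_modal_table_is_one():
    assert fisher_exact_two_sided(ContingencyTable(2, 2, 2, 2)) == 1.0


def test_fisher_perfect_separation_closed_form():
    # support {0..5}; the two extreme tables each have probability 1/C(10,5)
    p = fisher_exact_two_sided(ContingencyTable(5, 0, 0, 5))
    assert p == pytest.approx(2 / 252, rel=1e-12)


@pytest.mark.parametrize(
    "cells",
    [
        (1, 3, 2, 4), (0, 5, 7, 1), (3, 3, 3, 3), (6, 1, 0, 9),
        (2, 9, 8, 2), (1, 1, 10, 2), (4, 0, 0, 4), (5, 7, 2, 11),
    ],
)
def test_fisher_matches_enumeration_oracle(cells):
    p = fisher_exact_two_sided(ContingencyTable(*cells))
    assert p == pytest.approx(exact_fisher_oracle(*cells), abs=1e-12)


@pytest.mark.parametrize(
    "cells",
    [(166, 1045, 1778, 9161), (78, 341, 2323, 12751), (101, 1110, 616, 10323)],
)
def test_fisher_matches_scipy_at_survey_scale(cells):
    """Independent cross-check at realistic background sizes (~15k genes)."""
    ours = fisher_exact_two_sided(ContingencyTable(*cells))
    ref = scipy.stats.fisher_exact(np.array(cells).reshape(2, 2))[1]
    assert ours == pytest.approx(ref, rel=1e-9)


small_tables = st.tuples(
    st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)
).filter(lambda t: sum(t) > 0)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(cells=small_tables)
def test_fisher_and_or_transposition_and_reciprocity(cells):
    t = ContingencyTable(*cells)
    p = fisher_exact_two_sided(t)
    assert 0 < p <= 1
    assert fisher_exact_two_sided(t.transpose()) == pytest.approx(p, rel=1e-12)
    assert fisher_exact_two_sided(t.swap_rows()) == pytest.approx(p, rel=1e-12)
    if 0 not in cells:
        or_ = sample_odds_ratio(t)
        assert sample_odds_ratio(t.transpose()) == pytest.approx(or_, rel=1e-12)
        assert sample_odds_ratio(t.swap_rows()) == pytest.approx(1 / or_, rel=1e-12)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(cells=small_tables)
def test_hypergeometric_support_probabilities_sum_to_one(cells):
    from mitonux.enrichment_core import _support_log_pmf

    _, log_pmf = _support_log_pmf(ContingencyTable(*cells))
    assert np.exp(log_pmf).sum() == pytest.approx(1.0, abs=1e-12)


# --- conditional MLE ------------------------------------------------------


def test_conditional_mle_balanced_tables_are_one():
    assert conditional_mle_odds_ratio(ContingencyTable(1, 1, 1, 1)).value == 1.0
    for k in (2, 5, 20):
        est = conditional_mle_odds_ratio(ContingencyTable(k, k, k, k))
        assert est.value == pytest.approx(1.0, abs=1e-7)


@pytest.mark.parametrize(
    "cells", [(166, 1045, 1778, 9161), (7, 3, 2, 8), (20, 5, 10, 32)]
)
def test_conditional_mle_matches_scipy(cells):
    ours = conditional_mle_odds_ratio(ContingencyTable(*cells))
    ref = scipy.stats.contingency.odds_ratio(
        np.array(cells).reshape(2, 2), kind="conditional"
    ).statistic
    assert ours.value == pytest.approx(ref, rel=1e-5)
    assert not ours.at_boundary


def test_conditional_mle_close_to_sample_or_at_survey_scale():
    t = ContingencyTable(166, 1045, 1778, 9161)
    mle = conditional_mle_odds_ratio(t).value
    assert abs(mle - sample_odds_ratio(t)) / sample_odds_ratio(t) < 0.01


def test_conditional_mle_boundary_sentinels():
    lo = conditional_mle_odds_ratio(ContingencyTable(0, 5, 5, 5))
    assert lo.value == 0.0 and lo.at_boundary
    hi = conditional_mle_odds_ratio(ContingencyTable(5, 0, 2, 8))
    assert hi.value == math.inf and hi.at_boundary


# --- result assembly ------------------------------------------------------


def test_enrichment_result_percentages_and_serialization():
    r = EnrichmentResult.from_table(ContingencyTable(166, 1045, 1778, 9161))
    assert r.focal_pct == pytest.approx(13.7, abs=0.05)
    assert r.background_pct == pytest.approx(16.0, abs=0.05)
    assert not r.correction_applied
    d = r.to_dict()
    assert d["a"] == 166 and 0 < d["p_two_sided"] <= 1
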