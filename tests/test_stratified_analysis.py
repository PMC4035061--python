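import importlib.resources

import pytest
import yaml

from mitonux.annotation_io import GeneSet, restrict_to_background
from mitonux.stratified_analysis import (
    AnalysisError,
    AnalysisPlan,
    BootstrapSpec,
    ComparisonSpec,
    CountsSpec,
    PlanError,
    apply_exclusion,
    reconstruct_counts,
    report_frame,
    run_plan,
)

from conftest import make_table


def flagged_table():
    # 100 genes, 16 testis-biased, 10 duplicates, 20 on X
    arms = ["X"] * 20 + ["2L"] * 80
    return make_table(arms, testis=range(16), dup=range(40, 50))


# --- exclusions -----------------------------------------------------------


def test_flag_exclusion_shrinks_table_and_is_idempotent():
    table = flagged_table()
    once = apply_exclusion(table, "testis_biased")
    assert len(once) == 84
    twice = apply_exclusion(once, "testis_biased")
    assert twice.gene_ids == once.gene_ids


def test_set_exclusion_on_gene_set_and_flag_needs_table():
    table = flagged_table()
    s = GeneSet("s", frozenset(f"g{i}" for i in range(30)))
    out = apply_exclusion(s, GeneSet("drop", frozenset(["g0", "g1", "zz"])))
    assert len(out) == 28
    with pytest.raises(PlanError):
        apply_exclusion(s, "testis_biased")  # no table to resolve the flag
    flagged = apply_exclusion(s, "testis_biased", table=table)
    assert len(flagged) == 14


def test_exclusion_removing_everything_is_error():
    table = flagged_table()
    s = GeneSet("s", frozenset(["g0", "g1"]))
    with pytest.raises(AnalysisError):
        apply_exclusion(s, GeneSet("all", s.gene_ids))


def test_exclusion_commutes_with_background_restriction():
    table = flagged_table()
    s = GeneSet("s", frozenset(f"g{i}" for i in range(0, 60, 2)) | {"off1"})
    excluded_table = apply_exclusion(table, "testis_biased")
    a = apply_exclusion(
        restrict_to_background(s, excluded_table), "testis_biased", table=table
    )
    b = restrict_to_background(
        apply_exclusion(s, "testis_biased", table=table), excluded_table
    )
    assert a.gene_ids == b.gene_ids


# --- counts reconstruction ------------------------------------------------


@pytest.mark.parametrize(
    "args, expected",
    [
        ((1211, 13.7, 12150, 16), (166, 1045, 1778, 9161)),
        ((419, 18.7, 15493, 15.5), (78, 341, 2323, 12751)),
        ((10, 100, 10, 100), (10, 0, 0, 0)),
    ],
)
def test_reconstruct_counts_rounding_rule(args, expected):
    assert reconstruct_counts(*args).counts() == expected


def test_reconstruct_counts_rejects_inconsistent_numbers():
    with pytest.raises(AnalysisError):
        reconstruct_counts(100, 90, 120, 5)  # a+c < a
    with pytest.raises(AnalysisError):
        reconstruct_counts(100, 200, 120, 5)
    with pytest.raises(AnalysisError):
        reconstruct_counts(200, 10, 100, 10)


@pytest.mark.parametrize(
    "args",
    [(1211, 13.7, 12150, 16.0), (419, 18.7, 15493, 15.5), (1211, 8.3, 12150, 5.9)],
)
def test_reconstructed_percentages_round_back_near_printed(args):
    """Reconstructed percentages return the printed inputs to ~0.1 pp.

    Exact 1-dp round-tripping is impossible for some printed values (no
    integer count out of 419 genes yields 18.7%), so the bound is half a
    reporting unit on either side of the rounding grid.
    """
    from mitonux.enrichment_core import EnrichmentResult

    n_focal, pct_focal, n_bg, pct_bg = args
    r = EnrichmentResult.from_table(reconstruct_counts(*args))
    assert r.focal_pct == pytest.approx(pct_focal, abs=0.1)
    assert r.background_pct == pytest.approx(pct_bg, abs=0.1)


# --- plan driver ----------------------------------------------------------


def list_mode_plan():
    table = flagged_table()
    focal = GeneSet("focal", frozenset(f"g{i}" for i in range(0, 40)))
    prop = GeneSet("prop", frozenset(f"g{i}" for i in range(30, 70)))
    return AnalysisPlan(
        annotation=table,
        gene_sets={"focal": focal, "prop": prop},
        comparisons=(
            ComparisonSpec(name="loc", focal="focal",
                           exclusions=("none", "testis_biased", "duplicate")),
            ComparisonSpec(name="ovl", focal="focal", test="overlap",
                           property_set="prop"),
        ),
        bootstrap=BootstrapSpec(R=200, seed=3),
    )


def test_run_plan_row_count_is_combinatorial():
    rows = run_plan(list_mode_plan())
    assert len(rows) == 3 + 1
    assert [r.exclusion for r in rows[:3]] == ["none", "testis_biased", "duplicate"]


def test_run_plan_single_location_comparison():
    table = flagged_table()
    plan = AnalysisPlan(
        annotation=table,
        gene_sets={"f": GeneSet("f", frozenset(["g0", "g21"]))},
        comparisons=(ComparisonSpec(name="only", focal="f", bootstrap=False),),
        bootstrap=None,
    )
    rows = run_plan(plan)
    assert len(rows) == 1
    assert rows[0].result.table.counts() == (1, 1, 19, 79)


def test_plan_validation_collects_unresolved_names_before_compute():
    plan = AnalysisPlan(
        annotation=flagged_table(),
        gene_sets={},
        comparisons=(
            ComparisonSpec(name="bad", focal="missing", background="nowhere",
                           exclusions=("none", "mystery")),
        ),
    )
    with pytest.raises(PlanError) as err:
        run_plan(plan)
    msg = str(err.value)
    assert "missing" in msg and "nowhere" in msg and "mystery" in msg


def test_exclusion_shrinks_background_denominator():
    """Removing testis-biased genes must shrink a+c+b+d, not just a+b."""
    rows = run_plan(list_mode_plan())
    inclusive, excluded = rows[0], rows[1]
    assert excluded.result.table.n == 84
    assert inclusive.result.table.n == 100


def test_bundled_counts_plan_reproduces_published_ors():
    ref = importlib.resources.files("mitonux") / "configs" / "reference_counts.yaml"
    config = yaml.safe_load(ref.read_text())
    plan = AnalysisPlan.from_config(config)
    rows = {r.comparison: r for r in run_plan(plan)}
    assert round(rows["mito_sensitive_x"].result.odds_ratio, 2) == 0.82
    assert round(rows["core_proteome_x"].result.odds_ratio, 2) == 1.26
    assert round(rows["mito_sensitive_male_fitness"].result.odds_ratio, 2) == 1.52
    # rounding-fragile reconstructions are flagged, not failed
    assert rows["mito_annotated_x"].warning is not None
    assert rows["mito_sensitive_x"].warning is None


def test_report_frame_columns_and_bh_column():
    frame = report_frame(run_plan(list_mode_plan()))
    assert list(frame["comparison"][:3]) == ["loc"] * 3
    assert frame["p_bh"].notna().all()
    assert frame["boot_median"].notna().all()
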