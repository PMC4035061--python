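"""Analysis plans: exclusions, count reconstruction, and the report driver.

Two sensitivity procedures recur in chromosomal-representation analyses of
mito-interacting gene lists: excluding known mito-annotated gene
*duplicates* (which relocate off the X with testis-specific expression and
could drive a spurious under-representation signal), and excluding all
*testis-biased* genes (spermatogenesis X-inactivation already pushes those
off the X). An exclusion removes genes from the focal list *and* from the
background, so every subsequent denominator shrinks — this is what makes the
post-exclusion baseline percentages move.

``reconstruct_counts`` rebuilds a 2×2 table from published summary numbers
(list size, percentage with the property, background size, background
percentage), enabling verification against printed odds ratios when the
original gene lists are not at hand. ``run_plan`` drives any number of
list-mode and counts-mode comparisons into one deterministic report.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .annotation_io import (
    AnnotationTable,
    GeneSet,
    read_annotation,
    read_gene_set,
    restrict_to_background,
)
from .enrichment_core import (
    ContingencyTable,
    EnrichmentResult,
    build_location_table,
    build_overlap_table,
)
from .resampling import BootstrapResult, bootstrap_table_or

log = logging.getLogger(__name__)

#: Exclusion tokens resolved against annotation flags rather than sets.
FLAG_EXCLUSIONS = ("duplicate", "testis_biased")

#: Warn when a reconstructed OR differs from the printed one by more than
#: this — percentage rounding propagates, so it is a warning, not an error.
OR_DISCREPANCY_WARN = 0.02


class PlanError(ValueError):
    """Invalid analysis plan (unresolvable names, bad schema)."""


class AnalysisError(ValueError):
    """Data-level failure while executing a valid plan."""


def apply_exclusion(
    obj: AnnotationTable | GeneSet,
    criterion: GeneSet | str,
    table: AnnotationTable | None = None,
):
    """Remove genes matching ``criterion`` from a table or a gene set.

    ``criterion`` is either a :class:`GeneSet` or a flag name
    (``"duplicate"`` / ``"testis_biased"``); flag criteria are resolved
    against ``obj`` itself when it is a table, else against ``table``.
    Removing everything is a hard error. Idempotent.
    """
    if isinstance(criterion, GeneSet):
        drop = criterion.gene_ids
    elif criterion in FLAG_EXCLUSIONS:
        source = obj if isinstance(obj, AnnotationTable) else table
        if source is None:
            raise PlanError(
                f"flag exclusion {criterion!r} on a gene set needs an annotation table"
            )
        drop = source.flagged_ids(criterion)
    else:
        raise PlanError(f"unknown exclusion criterion {criterion!r}")

    if isinstance(obj, AnnotationTable):
        keep = obj.gene_ids - drop
        if not keep:
            raise AnalysisError("exclusion removed every background gene")
        removed = len(obj) - len(keep)
        if removed:
            log.info("exclusion removed %d background genes", removed)
        return obj.subset(keep)
    keep_ids = obj.gene_ids - drop
    if not keep_ids:
        raise AnalysisError(f"exclusion removed every gene of set {obj.name!r}")
    removed = len(obj) - len(keep_ids)
    if removed:
        log.info("exclusion removed %d genes from set %r", removed, obj.name)
    return GeneSet(name=obj.name, gene_ids=keep_ids, provenance=obj.provenance)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def reconstruct_counts(
    n_focal: int,
    pct_focal: float,
    n_background: int,
    pct_background: float,
    focal_label: str = "focal",
    property_label: str = "property",
) -> ContingencyTable:
    """Rebuild a 2×2 table from published sizes and percentages.

    ``a`` = round(n_focal·pct_focal/100); ``a+c`` =
    round(n_background·pct_background/100); rounding is to the nearest
    integer, half away from zero. Inconsistent printed numbers (a negative
    derived cell) are a hard error.
    """
    for pct in (pct_focal, pct_background):
        if not 0.0 <= pct <= 100.0:
            raise AnalysisError(f"percentage {pct} outside [0, 100]")
    if n_focal > n_background:
        raise AnalysisError("focal size exceeds background size")
    a = _round_half_away(n_focal * pct_focal / 100.0)
    a_plus_c = _round_half_away(n_background * pct_background / 100.0)
    b = n_focal - a
    c = a_plus_c - a
    d = n_background - n_focal - c
    if min(a, b, c, d) < 0:
        raise AnalysisError(
            f"inconsistent printed numbers: derived cells ({a},{b},{c},{d})"
        )
    return ContingencyTable(
        a, b, c, d, focal_label=focal_label, property_label=property_label,
        provenance="reconstructed",
    )


@dataclass(frozen=True)
class BootstrapSpec:
    R: int = 10_000
    level: float = 0.95
    seed: int = 0


@dataclass(frozen=True)
class ComparisonSpec:
    """One list-mode comparison: a focal set against a location or a property set."""

    name: str
    focal: str
    test: str = "location"  # "location" | "overlap"
    property_set: str | None = None
    background: str = "all"
    exclusions: tuple[str, ...] = ("none",)
    bootstrap: bool = True


@dataclass(frozen=True)
class CountsSpec:
    """One counts-mode comparison rebuilt from published summary numbers."""

    name: str
    n_focal: int
    pct_focal: float
    n_background: int
    pct_background: float
    focal_label: str = "focal"
    property_label: str = "property"
    printed_or: float | None = None
    bootstrap: bool = True


@dataclass
class AnalysisPlan:
    """Everything :func:`run_plan` needs, fully resolved in memory.

    ``backgrounds`` maps a background name to ``None`` (the whole
    annotation) or to a :class:`GeneSet` restricting it (e.g. the
    expression-chip gene universe).
    """

    annotation: AnnotationTable | None = None
    gene_sets: Mapping[str, GeneSet] = field(default_factory=dict)
    backgrounds: Mapping[str, GeneSet | None] = field(
        default_factory=lambda: {"all": None}
    )
    comparisons: Sequence[ComparisonSpec] = ()
    counts_comparisons: Sequence[CountsSpec] = ()
    bootstrap: BootstrapSpec | None = field(default_factory=BootstrapSpec)

    def validate(self) -> None:
        """Collect every resolution problem before any computation runs."""
        problems: list[str] = []
        if self.comparisons and self.annotation is None:
            problems.append("list-mode comparisons require an annotation table")
        for comp in self.comparisons:
            if comp.test not in ("location", "overlap"):
                problems.append(f"{comp.name}: unknown test {comp.test!r}")
            if comp.focal not in self.gene_sets:
                problems.append(f"{comp.name}: unknown focal set {comp.focal!r}")
            if comp.test == "overlap":
                if comp.property_set is None:
                    problems.append(f"{comp.name}: overlap test needs property_set")
                elif comp.property_set not in self.gene_sets:
                    problems.append(
                        f"{comp.name}: unknown property set {comp.property_set!r}"
                    )
            if comp.background not in self.backgrounds:
                problems.append(
                    f"{comp.name}: unknown background {comp.background!r}"
                )
            for token in comp.exclusions:
                if token not in ("none",) + FLAG_EXCLUSIONS and token not in self.gene_sets:
                    problems.append(f"{comp.name}: unknown exclusion {token!r}")
        if not self.comparisons and not self.counts_comparisons:
            problems.append("plan contains no comparisons")
        if problems:
            raise PlanError("; ".join(problems))

    @classmethod
    def from_config(cls, config: Mapping, base_dir: str | Path = ".") -> "AnalysisPlan":
        """Build a plan from a parsed YAML/JSON mapping, loading referenced files."""
        base = Path(base_dir)
        annotation = None
        if config.get("annotation"):
            annotation = read_annotation(
                base / config["annotation"],
                format=config.get("annotation_format", "tsv"),
                x_arms=tuple(config.get("x_arms", ("X",))),
            )
        gene_sets = {
            name: read_gene_set(base / path, name)
            for name, path in (config.get("gene_sets") or {}).items()
        }
        backgrounds: dict[str, GeneSet | None] = {"all": None}
        for name, ref in (config.get("backgrounds") or {}).items():
            if ref is None:
                backgrounds[name] = None
            elif ref in gene_sets:
                backgrounds[name] = gene_sets[ref]
            else:
                backgrounds[name] = read_gene_set(base / ref, name)
        comparisons = tuple(
            ComparisonSpec(
                name=c["name"],
                focal=c["focal"],
                test=c.get("test", "location"),
                property_set=c.get("property"),
                background=c.get("background", "all"),
                exclusions=tuple(c.get("exclusions", ["none"])),
                bootstrap=bool(c.get("bootstrap", True)),
            )
            for c in config.get("comparisons") or []
        )
        counts = tuple(
            CountsSpec(
                name=c["name"],
                n_focal=int(c["n_focal"]),
                pct_focal=float(c["pct_focal"]),
                n_background=int(c["n_background"]),
                pct_background=float(c["pct_background"]),
                focal_label=c.get("focal_label", c["name"]),
                property_label=c.get("property_label", "property"),
                printed_or=c.get("printed_or"),
                bootstrap=bool(c.get("bootstrap", True)),
            )
            for c in config.get("counts_comparisons") or []
        )
        boot_cfg = config.get("bootstrap")
        bootstrap = (
            BootstrapSpec(
                R=int(boot_cfg.get("R", 10_000)),
                level=float(boot_cfg.get("level", 0.95)),
                seed=int(boot_cfg.get("seed", 0)),
            )
            if boot_cfg
            else None
        )
        return cls(
            annotation=annotation,
            gene_sets=gene_sets,
            backgrounds=backgrounds,
            comparisons=comparisons,
            counts_comparisons=counts,
            bootstrap=bootstrap,
        )


@dataclass(frozen=True)
class ReportRow:
    """One comparison under one exclusion state."""

    comparison: str
    mode: str  # "lists" | "reconstructed"
    test: str
    exclusion: str
    background: str
    result: EnrichmentResult
    bootstrap: BootstrapResult | None = None
    p_bh: float | None = None
    warning: str | None = None

    def to_dict(self, include_replicates: bool = False) -> dict:
        out = {
            "comparison": self.comparison,
            "mode": self.mode,
            "test": self.test,
            "exclusion": self.exclusion,
            "background": self.background,
            **self.result.to_dict(),
            "p_bh": self.p_bh,
            "warning": self.warning,
        }
        if self.bootstrap is not None:
            out["bootstrap"] = self.bootstrap.to_dict(include_replicates)
        return out


def _background_table(
    plan: AnalysisPlan, name: str
) -> AnnotationTable:
    restriction = plan.backgrounds[name]
    assert plan.annotation is not None
    if restriction is None:
        return plan.annotation
    return plan.annotation.subset(
        restriction.gene_ids & plan.annotation.gene_ids
    )


def _run_list_comparison(
    plan: AnalysisPlan, comp: ComparisonSpec, row_seed: int
) -> list[ReportRow]:
    rows = []
    base_bg = _background_table(plan, comp.background)
    for token in comp.exclusions:
        bg = base_bg
        focal = plan.gene_sets[comp.focal]
        prop = plan.gene_sets[comp.property_set] if comp.test == "overlap" else None
        if token != "none":
            criterion: GeneSet | str = (
                plan.gene_sets[token] if token in plan.gene_sets else token
            )
            bg = apply_exclusion(base_bg, criterion)
            focal = apply_exclusion(focal, criterion, table=base_bg)
            if prop is not None:
                prop = apply_exclusion(prop, criterion, table=base_bg)
        focal = restrict_to_background(focal, bg)
        if comp.test == "location":
            table = build_location_table(focal, bg)
        else:
            prop = restrict_to_background(prop, bg)
            table = build_overlap_table(focal, prop, bg)
        result = EnrichmentResult.from_table(table)
        boot = None
        if plan.bootstrap is not None and comp.bootstrap:
            boot = bootstrap_table_or(
                table.a, table.b, table.c, table.d,
                R=plan.bootstrap.R, level=plan.bootstrap.level,
                seed=plan.bootstrap.seed + row_seed,
            )
        rows.append(
            ReportRow(
                comparison=comp.name, mode="lists", test=comp.test,
                exclusion=token, background=comp.background,
                result=result, bootstrap=boot,
            )
        )
        row_seed += 1
    return rows


def run_plan(plan: AnalysisPlan) -> list[ReportRow]:
    """Execute every comparison of a validated plan, deterministically.

    Emits one row per (comparison, exclusion-state) in declaration order,
    then one row per counts-mode comparison. A Benjamini–Hochberg adjusted
    P column is attached across all rows for transparency; nothing is gated
    on it (published analyses of this kind report raw exact P-values).
    """
    plan.validate()
    rows: list[ReportRow] = []
    row_seed = 0
    for comp in plan.comparisons:
        new_rows = _run_list_comparison(plan, comp, row_seed)
        rows.extend(new_rows)
        row_seed += len(new_rows)
    for spec in plan.counts_comparisons:
        table = reconstruct_counts(
            spec.n_focal, spec.pct_focal, spec.n_background, spec.pct_background,
            focal_label=spec.focal_label, property_label=spec.property_label,
        )
        result = EnrichmentResult.from_table(table)
        warning = None
        if (
            spec.printed_or is not None
            and abs(result.odds_ratio - spec.printed_or) > OR_DISCREPANCY_WARN
        ):
            warning = (
                f"reconstructed OR {result.odds_ratio:.3f} differs from printed "
                f"{spec.printed_or} by more than {OR_DISCREPANCY_WARN} "
                "(percentage-rounding propagation)"
            )
            log.warning("%s: %s", spec.name, warning)
        boot = None
        if plan.bootstrap is not None and spec.bootstrap:
            boot = bootstrap_table_or(
                table.a, table.b, table.c, table.d,
                R=plan.bootstrap.R, level=plan.bootstrap.level,
                seed=plan.bootstrap.seed + row_seed,
            )
        rows.append(
            ReportRow(
                comparison=spec.name, mode="reconstructed", test="counts",
                exclusion="none", background=f"n={spec.n_background}",
                result=result, bootstrap=boot, warning=warning,
            )
        )
        row_seed += 1

    pvals = [row.result.p_two_sided for row in rows]
    if pvals:
        _, p_bh, _, _ = multipletests(pvals, method="fdr_bh")
        rows = [
            ReportRow(
                comparison=r.comparison, mode=r.mode, test=r.test,
                exclusion=r.exclusion, background=r.background,
                result=r.result, bootstrap=r.bootstrap,
                p_bh=float(adj), warning=r.warning,
            )
            for r, adj in zip(rows, p_bh)
        ]
    return rows


_REPORT_COLUMNS = [
    "comparison", "mode", "test", "exclusion", "background",
    "focal", "property", "a", "b", "c", "d",
    "focal_pct", "background_pct", "odds_ratio", "p_two_sided", "p_bh",
    "correction_applied", "boot_median", "boot_ci_low", "boot_ci_high",
    "warning",
]


def report_frame(rows: Sequence[ReportRow]) -> pd.DataFrame:
    """Flatten report rows into a DataFrame with a stable column order."""
    flat = []
    for row in rows:
        d = row.to_dict()
        boot = d.pop("bootstrap", None)
        d["boot_median"] = boot["median"] if boot else None
        d["boot_ci_low"] = boot["ci_low"] if boot else None
        d["boot_ci_high"] = boot["ci_high"] if boot else None
        d.pop("provenance", None)
        flat.append(d)
    return pd.DataFrame(flat, columns=_REPORT_COLUMNS)
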