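"""Exact 2×2 enrichment statistics.

Every representation claim in the analysis reduces to a 2×2
cross-classification of a background gene universe: focal-set membership
(rows) against a binary property (columns) — X-linkage, membership of a
second gene list, or testis-biased expression. This module builds those
tables and computes:

* the sample (cross-product) odds ratio ``a·d / (b·c)``, optionally with the
  Haldane–Anscombe +0.5 correction when a cell is zero;
* the two-sided Fisher exact P-value, by enumerating the hypergeometric
  distribution of cell ``a`` with all margins fixed and summing the point
  probabilities not exceeding that of the observed table (the
  point-probability two-sided rule). All probability arithmetic is done in
  log-space via log-gamma so backgrounds of ~15 000 genes pose no stability
  problem;
* the conditional maximum-likelihood odds ratio under Fisher's noncentral
  hypergeometric model, as a diagnostic for sensitivity to the estimator
  convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .annotation_io import AnnotationTable, GeneSet

log = logging.getLogger(__name__)

# Relative tie tolerance for the point-probability rule: tables whose point
# probability exceeds the observed one by less than this factor count as
# ties. Exact rational ties computed via gammaln differ by ~1e-14, far
# below this; genuinely distinct probabilities at small n differ by far
# more (>= 1/C(n, c1) in absolute numerator terms).
_TIE_EPS = 1e-9


class EnrichmentError(ValueError):
    """Invalid contingency input or undefined statistic."""


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 integer counts.

    ``a`` focal ∧ property, ``b`` focal ∧ ¬property, ``c`` non-focal ∧
    property, ``d`` non-focal ∧ ¬property. Rows partition the background
    into focal vs non-focal genes; the background percentage nevertheless
    refers to the whole background (a+c over n), matching the convention of
    published baselines that include the focal genes.
    """

    a: int
    b: int
    c: int
    d: int
    focal_label: str = "focal"
    property_label: str = "property"
    provenance: str = ""

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise EnrichmentError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise EnrichmentError("contingency table must have a positive total")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.a, self.c, self.b, self.d,
                                self.property_label, self.focal_label)

    def swap_rows(self) -> "ContingencyTable":
        return ContingencyTable(self.c, self.d, self.a, self.b,
                                f"non-{self.focal_label}", self.property_label)

    def counts(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class EnrichmentResult:
    """Odds ratio, exact two-sided P, and the percentage pair.

    ``focal_pct`` is 100·a/(a+b) (the property rate inside the focal set);
    ``background_pct`` is 100·(a+c)/n (the property rate over the whole
    background, focal genes included).
    """

    table: ContingencyTable
    odds_ratio: float
    p_two_sided: float
    focal_pct: float
    background_pct: float
    correction_applied: bool

    @classmethod
    def from_table(
        cls, table: ContingencyTable, zero_cell_correction: bool = True
    ) -> "EnrichmentResult":
        has_zero = 0 in table.counts()
        correction = zero_cell_correction and has_zero
        return cls(
            table=table,
            odds_ratio=sample_odds_ratio(table, zero_cell_correction=correction),
            p_two_sided=fisher_exact_two_sided(table),
            focal_pct=100.0 * table.a / (table.a + table.b),
            background_pct=100.0 * (table.a + table.c) / table.n,
            correction_applied=correction,
        )

    def to_dict(self) -> dict:
        t = self.table
        return {
            "focal": t.focal_label,
            "property": t.property_label,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "odds_ratio": self.odds_ratio,
            "p_two_sided": self.p_two_sided,
            "focal_pct": self.focal_pct,
            "background_pct": self.background_pct,
            "correction_applied": self.correction_applied,
            "provenance": t.provenance,
        }


def build_location_table(
    gene_set: GeneSet, table: AnnotationTable, property_label: str = "X-linked"
) -> ContingencyTable:
    """Cross-classify background genes by focal membership × X-linkage.

    Genes with an ``unknown`` chromosome arm are excluded from both rows
    (count logged). The focal set should already be restricted to the
    background; off-background members are ignored here.
    """
    known = table.known_ids()
    dropped_unknown = len(table) - len(known)
    if dropped_unknown:
        log.info("build_location_table: excluded %d genes with unknown arm",
                 dropped_unknown)
    x_ids = table.x_ids() & known
    focal = gene_set.gene_ids & known
    if not focal:
        raise EnrichmentError(
            f"focal set {gene_set.name!r} shares no placed genes with the background"
        )
    a = len(focal & x_ids)
    b = len(focal) - a
    c = len(x_ids) - a
    d = len(known) - len(focal) - c
    return ContingencyTable(a, b, c, d, focal_label=gene_set.name,
                            property_label=property_label)


def build_overlap_table(
    focal: GeneSet, property_set: GeneSet, table: AnnotationTable
) -> ContingencyTable:
    """Cross-classify background genes by focal membership × property-set membership."""
    universe = table.gene_ids
    f = focal.gene_ids & universe
    p = property_set.gene_ids & universe
    if not f:
        raise EnrichmentError(
            f"focal set {focal.name!r} is disjoint from the background"
        )
    a = len(f & p)
    b = len(f) - a
    c = len(p) - a
    d = len(universe) - len(f) - c
    return ContingencyTable(a, b, c, d, focal_label=focal.name,
                            property_label=property_set.name)


def sample_odds_ratio(
    t: ContingencyTable, zero_cell_correction: bool = False
) -> float:
    """Cross-product ratio a·d/(b·c).

    With ``zero_cell_correction`` the Haldane–Anscombe +0.5 is added to all
    four cells first; without it a zero cell raises (the OR is undefined).
    """
    a, b, c, d = t.counts()
    if zero_cell_correction:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    if 0 in (a, b, c, d):
        raise EnrichmentError(
            "sample odds ratio undefined for a zero cell; enable the "
            "Haldane–Anscombe correction"
        )
    return (a * d) / (b * c)


def _support_log_pmf(t: ContingencyTable) -> tuple[np.ndarray, np.ndarray]:
    """Support of cell ``a`` given all margins, with log point probabilities."""
    r1, r2 = t.row_margins
    c1, _ = t.col_margins
    n = t.n
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    k = np.arange(lo, hi + 1)
    log_pmf = (
        gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
        + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - (c1 - k) + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    return k, log_pmf


def fisher_exact_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher exact P by the point-probability rule.

    With all margins fixed, cell ``a`` follows a (central) hypergeometric
    distribution; the P-value sums the point probabilities of all tables at
    least as extreme — i.e. no more probable — than the observed one.
    Computed in log-space; the result is clipped to (0, 1].
    """
    k, log_pmf = _support_log_pmf(t)
    if len(k) == 1:  # degenerate margin: only one table possible
        return 1.0
    log_p_obs = log_pmf[k == t.a][0]
    mask = log_pmf <= log_p_obs + _TIE_EPS
    if mask.all():  # observed table is modal: every table is at least as extreme
        return 1.0
    # log-sum-exp over the selected tables
    m = log_pmf[mask].max()
    p = math.exp(m) * np.exp(log_pmf[mask] - m).sum()
    return min(max(p, math.ulp(0.0)), 1.0)


class ConditionalMLE(NamedTuple):
    """Conditional MLE of the odds ratio; ``at_boundary`` flags the 0/inf sentinels."""

    value: float
    at_boundary: bool


def conditional_mle_odds_ratio(t: ContingencyTable, tol: float = 1e-8) -> ConditionalMLE:
    """Odds ratio maximizing the Fisher noncentral hypergeometric likelihood.

    Solves the score equation E_ψ[a] = a by monotone root search on the
    log-odds (the conditional expectation is strictly increasing in log ψ).
    When the observed ``a`` sits at the boundary of its support the MLE is
    0 or +inf; those sentinels are returned with ``at_boundary=True``.
    """
    k, log_pmf0 = _support_log_pmf(t)
    if len(k) == 1:
        return ConditionalMLE(1.0, False)
    if t.a == k[0]:
        return ConditionalMLE(0.0, True)
    if t.a == k[-1]:
        return ConditionalMLE(math.inf, True)

    def score(log_psi: float) -> float:
        logw = log_pmf0 + k * log_psi
        logw -= logw.max()
        w = np.exp(logw)
        return float((k * w).sum() / w.sum()) - t.a

    at_one = score(0.0)
    if at_one == 0.0:  # observed count equals the central expectation exactly
        return ConditionalMLE(1.0, False)
    lo, hi = -1.0, 1.0
    while score(lo) > 0:
        lo *= 2
    while score(hi) < 0:
        hi *= 2
    root = brentq(score, lo, hi, xtol=tol)
    return ConditionalMLE(math.exp(root), False)
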