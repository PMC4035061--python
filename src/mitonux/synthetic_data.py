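"""Synthetic genomes and gene lists with controlled enrichment structure.

The generator emulates the statistical shape of the real inputs — a genome
of N genes spread over chromosome arms with a known X fraction, a
testis-biased flag at a fixed base rate, and named focal gene lists whose
X-membership and testis-membership follow specified (log-)odds ratios, with
optional pairwise overlap structure between lists. It simulates the *lists*,
not the upstream transcriptomics: no expression values, array noise, or
differential-expression calling.

Sets of exactly the requested size are drawn by weighted sampling without
replacement using exponential keys (one Exp(1)/weight key per candidate
gene; the smallest keys win), which is reproducible and equivalent to
successive sampling proportional to weights. A gene's log-weight for a set
is ``x_log_odds·1[on X] + testis_log_odds·1[testis-biased]`` plus latent
pairwise tilts: each tilted set pair shares a latent Bernoulli "pathway"
indicator whose rate matches the smaller set's genome fraction, and both
members upweight (for negative association, one upweights and one
downweights) pathway genes by a tilt solved so the induced membership odds
ratio approximates the requested ``exp(pairwise_overlap_log_odds)`` under a
rare-set mixture approximation. Calibration degrades for targets near the
feasibility bound 1/rate and for sets that exhaust the latent pool.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .annotation_io import AnnotationTable, GeneRecord, GeneSet

log = logging.getLogger(__name__)

#: Arm fractions shaped like the D. melanogaster gene complement: the X
#: carries ~15.5% of annotated genes; the dot fourth chromosome is tiny.
DEFAULT_ARM_FRACTIONS: dict[str, float] = {
    "X": 0.155, "2L": 0.200, "2R": 0.210, "3L": 0.205, "3R": 0.222, "4": 0.008,
}

#: Genome-wide testis-biased base rate (fraction of annotated genes
#: significantly over-expressed in testes).
DEFAULT_TESTIS_BASE_RATE = 0.161


class SyntheticDataError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class SetSpec:
    """Size and sampling tilts for one named gene set.

    ``within`` restricts the candidate pool to a previously declared set
    (e.g. lists derived from an expression array are drawn within the
    array's gene universe).
    """

    size: int
    x_log_odds: float = 0.0
    testis_log_odds: float = 0.0
    within: str | None = None


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one synthetic world."""

    n_genes: int
    set_specs: Mapping[str, SetSpec] = field(default_factory=dict)
    arm_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARM_FRACTIONS)
    )
    testis_base_rate: float = DEFAULT_TESTIS_BASE_RATE
    pairwise_overlap_log_odds: Mapping[tuple[str, str], float] = field(
        default_factory=dict
    )
    duplicate_set: str | None = None
    x_arms: tuple[str, ...] = ("X",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise SyntheticDataError("n_genes must be positive")
        total = math.fsum(self.arm_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise SyntheticDataError(f"arm_fractions sum to {total}, not 1")
        if not (0.0 < self.testis_base_rate < 1.0):
            raise SyntheticDataError("testis_base_rate must be in (0,1)")
        declared = list(self.set_specs)
        for name, spec in self.set_specs.items():
            if spec.size < 1:
                raise SyntheticDataError(f"set {name!r}: size must be positive")
            if spec.within is None:
                if spec.size > self.n_genes:
                    raise SyntheticDataError(
                        f"set {name!r}: size {spec.size} exceeds n_genes"
                    )
            else:
                if spec.within not in declared[: declared.index(name)]:
                    raise SyntheticDataError(
                        f"set {name!r}: 'within' target {spec.within!r} must be "
                        "declared earlier"
                    )
                if spec.size > self.set_specs[spec.within].size:
                    raise SyntheticDataError(
                        f"set {name!r}: size exceeds its 'within' pool"
                    )
        for pair in self.pairwise_overlap_log_odds:
            for name in pair:
                if name not in self.set_specs:
                    raise SyntheticDataError(f"overlap pair names unknown set {name!r}")
        if self.duplicate_set is not None and self.duplicate_set not in self.set_specs:
            raise SyntheticDataError(
                f"duplicate_set {self.duplicate_set!r} is not a declared set"
            )


def _pair_tilt(rho: float, lam: float) -> float:
    """Member log-tilt whose induced membership OR approximates exp(lam).

    For two rare sets sharing a Bernoulli(rho) latent indicator, upweighting
    pathway genes by ``exp(a)`` in each member induces a membership odds
    ratio of roughly ``(rho·e^{2a}+1)/(rho·e^a+1)^2``, which is capped above
    by 1/rho; targets beyond ~90% of the cap get the maximal tilt.
    """
    from scipy.optimize import brentq

    target = math.exp(abs(lam))
    if target <= 1.0:
        return 0.0
    if target >= 0.9 / rho:
        return 8.0

    def f(a: float) -> float:
        u = math.exp(a)
        return (rho * u * u + 1.0) / (rho * u + 1.0) ** 2 - target

    return brentq(f, 0.0, 40.0)


def generate_world(
    cfg: SyntheticConfig,
) -> tuple[AnnotationTable, dict[str, GeneSet], dict]:
    """Draw one world: annotation table, named gene sets, and a truth record.

    Identical configs (including seed) produce identical worlds. The truth
    record echoes every generative parameter plus realized marginal
    fractions, so estimator-recovery harnesses can compare against it.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    arms_vocab = list(cfg.arm_fractions)
    arm_idx = rng.choice(len(arms_vocab), size=n, p=list(cfg.arm_fractions.values()))
    arms = np.array(arms_vocab, dtype=object)[arm_idx]
    on_x = np.isin(arms, cfg.x_arms)
    testis = rng.random(n) < cfg.testis_base_rate

    # Latent binary pathway indicators, one per tilted set pair, with the
    # pool rate tied to the smaller member so high overlaps stay feasible.
    # Pools are composition-neutral (uniform in X and testis status): as
    # long as the member tilt stays below the saturation cap, a member's
    # own x/testis log-odds act identically inside and outside the pool,
    # leaving marginal enrichments uncontaminated by overlap structure.
    pair_latents: dict[tuple[str, str], np.ndarray] = {}
    pair_tilts: dict[tuple[str, str], float] = {}
    for pair, lam in cfg.pairwise_overlap_log_odds.items():
        if lam != 0.0:
            rho = min(cfg.set_specs[s].size for s in pair) / n
            rho = min(max(rho, 1.0 / n), 0.5)
            pair_latents[pair] = rng.random(n) < rho
            pair_tilts[pair] = _pair_tilt(rho, lam)

    gene_ids = np.array([f"G{i:06d}" for i in range(n)], dtype=object)
    member_idx: dict[str, np.ndarray] = {}
    sets: dict[str, GeneSet] = {}
    for name, spec in cfg.set_specs.items():
        logw = np.zeros(n)
        logw += spec.x_log_odds * on_x
        logw += spec.testis_log_odds * testis
        for pair, lam in cfg.pairwise_overlap_log_odds.items():
            if name in pair and lam != 0.0:
                # negative association: the second member downweights
                sign = -1.0 if (lam < 0.0 and name == pair[1]) else 1.0
                logw += sign * pair_tilts[pair] * pair_latents[pair]
        candidates = (
            np.arange(n) if spec.within is None else member_idx[spec.within]
        )
        # exponential-keys weighted sampling without replacement
        keys = rng.exponential(size=len(candidates)) * np.exp(-logw[candidates])
        chosen = candidates[np.argpartition(keys, spec.size - 1)[: spec.size]]
        member_idx[name] = np.sort(chosen)
        sets[name] = GeneSet(
            name=name,
            gene_ids=frozenset(gene_ids[member_idx[name]]),
            provenance=f"synthetic (seed={cfg.seed})",
        )

    duplicate = np.zeros(n, dtype=bool)
    if cfg.duplicate_set is not None:
        duplicate[member_idx[cfg.duplicate_set]] = True

    records = [
        GeneRecord(
            gene_id=gene_ids[i],
            chromosome=arms[i],
            testis_biased=bool(testis[i]),
            duplicate=bool(duplicate[i]),
        )
        for i in range(n)
    ]
    vocab = tuple(arms_vocab) + tuple(
        a for a in ("other", "unknown") if a not in arms_vocab
    )
    table = AnnotationTable(records, arm_vocabulary=vocab, x_arms=cfg.x_arms)

    truth = {
        "seed": cfg.seed,
        "n_genes": n,
        "arm_fractions": dict(cfg.arm_fractions),
        "testis_base_rate": cfg.testis_base_rate,
        "realized_x_fraction": float(on_x.mean()),
        "realized_testis_fraction": float(testis.mean()),
        "set_specs": {
            name: {
                "size": spec.size,
                "x_log_odds": spec.x_log_odds,
                "x_odds_ratio": math.exp(spec.x_log_odds),
                "testis_log_odds": spec.testis_log_odds,
                "within": spec.within,
            }
            for name, spec in cfg.set_specs.items()
        },
        "pairwise_overlap_log_odds": {
            "|".join(pair): lam
            for pair, lam in cfg.pairwise_overlap_log_odds.items()
        },
        "duplicate_set": cfg.duplicate_set,
    }
    return table, sets, truth


def survey_shaped_world(
    seed: int,
) -> tuple[AnnotationTable, dict[str, GeneSet], dict]:
    """A world with the dimensions of the published D. melanogaster survey.

    15 493 annotated genes with a 12 150-gene expression-chip subset;
    focal lists of 524 mito-annotated, 419 core mito-proteome, 1211
    mito-sensitive, and 123 mito-annotated duplicate genes, plus Y-sensitive
    and male-fitness lists at their chip base rates. Generative X odds
    ratios and testis odds ratios are set to the published point estimates,
    so the pipeline's estimates can be checked for recovery of known truth.
    """
    cfg = SyntheticConfig(
        n_genes=15_493,
        seed=seed,
        set_specs={
            "chip": SetSpec(size=12_150),
            "mito_annotated": SetSpec(
                size=524, x_log_odds=math.log(1.01), testis_log_odds=math.log(1.27)
            ),
            "core_proteome": SetSpec(
                size=419, x_log_odds=math.log(1.26), testis_log_odds=math.log(0.39)
            ),
            "mito_sensitive": SetSpec(
                size=1211, x_log_odds=math.log(0.82),
                testis_log_odds=math.log(3.3), within="chip",
            ),
            "y_sensitive": SetSpec(
                size=705, testis_log_odds=math.log(1.8), within="chip"
            ),
            "male_fitness": SetSpec(size=717, within="chip"),
            "duplicates": SetSpec(
                size=123, x_log_odds=math.log(0.4), testis_log_odds=math.log(3.0)
            ),
        },
        pairwise_overlap_log_odds={
            ("mito_annotated", "core_proteome"): 2.0,
            ("mito_sensitive", "y_sensitive"): math.log(1.38),
            ("mito_sensitive", "male_fitness"): math.log(1.52),
            ("mito_annotated", "duplicates"): 2.0,
        },
        duplicate_set="duplicates",
    )
    return generate_world(cfg)
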