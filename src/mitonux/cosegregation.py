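"""Co-transmission of nuclear gene copies with the mitochondrial genome.

mtDNA is strictly maternally inherited, so a nuclear gene copy
"co-segregates" with the mtDNA exactly when it passes through the mother.
Counting transmitted gene copies in an XY system with an even sex ratio:

* X-linked — a daughter receives an X from each parent (one maternal), a son
  receives his single X from his mother; with equal numbers of sons and
  daughters, 2 of every 3 transmitted X copies are maternal → 2/3.
* autosomal — every offspring receives one copy from each parent → 1/2.
* Y-linked — the Y passes strictly father-to-son → 0.

These three fractions are the quantitative premise of the coadaptation
hypothesis (X-linkage maximizes co-transmission of mito-nuclear allele
pairs) and its sexual-conflict rival (movement off the X decouples nuclear
counter-adaptations from the maternally filtered mtDNA). The Monte-Carlo
model here verifies the closed forms by simulating random mating with
Mendelian transmission and strict maternal mtDNA inheritance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

LINKAGE_CLASSES = ("X", "autosome", "Y")

_CLOSED_FORM = {"X": 2.0 / 3.0, "autosome": 0.5, "Y": 0.0}


class CosegregationError(ValueError):
    """Invalid transmission model or failed simulation."""


def cosegregation_probability(linkage: str) -> float:
    """Closed-form fraction of transmitted gene copies that are maternal."""
    try:
        return _CLOSED_FORM[linkage]
    except KeyError:
        raise CosegregationError(
            f"unknown linkage {linkage!r}; expected one of {LINKAGE_CLASSES}"
        ) from None


@dataclass(frozen=True)
class TransmissionModel:
    """Random-mating XY population for one linkage class.

    Non-overlapping generations, even sex ratio at initialization, panmixia.
    """

    linkage: str
    population_size: int = 10_000
    generations: int = 1
    seed: int = 0
    system: str = "XY"

    def __post_init__(self) -> None:
        if self.linkage not in LINKAGE_CLASSES:
            raise CosegregationError(f"unknown linkage {self.linkage!r}")
        if self.system != "XY":
            raise CosegregationError("only the XY system is modeled")
        if self.population_size < 10 or self.population_size % 2:
            raise CosegregationError("population size must be even and ≥ 10")
        if self.generations < 1:
            raise CosegregationError("generations must be ≥ 1")


@dataclass(frozen=True)
class CosegregationEstimate:
    """Empirical maternal co-transmission fraction with its tally."""

    linkage: str
    fraction: float
    maternal_copies: int
    total_copies: int
    generations: int
    seed: int


def simulate_cosegregation(model: TransmissionModel) -> CosegregationEstimate:
    """Monte-Carlo maternal co-transmission fraction for one linkage class.

    Each generation, every one of N offspring draws a mother and a father
    uniformly from the current females/males and a sex at random; the
    offspring's mtDNA always comes from the mother. For the focal linkage
    class, transmitted gene copies are tallied along with whether the
    transmitting parent also transmitted the mtDNA (i.e. is the mother).
    A generation in which one sex goes extinct is redrawn (logged); after
    100 redraws the simulation aborts.
    """
    rng = np.random.default_rng(model.seed)
    n = model.population_size
    # True marks a female. Initial population: exactly half each sex.
    sexes = np.zeros(n, dtype=bool)
    sexes[: n // 2] = True

    maternal = 0
    total = 0
    failures = 0
    for _ in range(model.generations):
        for _attempt in range(101):
            offspring_female = rng.random(n) < 0.5
            if offspring_female.any() and (~offspring_female).any():
                break
            failures += 1
            log.info("simulate_cosegregation: single-sex generation redrawn")
        else:
            raise CosegregationError(
                "simulation aborted: 100 consecutive single-sex generations"
            )
        if failures > 100:
            raise CosegregationError("simulation aborted after 100 redraws")
        # Under panmixia every offspring has exactly one mother and one
        # father regardless of which individuals they are, so the copy
        # tally depends only on the realized offspring sexes.
        n_daughters = int(offspring_female.sum())
        n_sons = n - n_daughters
        if model.linkage == "X":
            # daughter: X from each parent; son: X from mother only
            total += 2 * n_daughters + n_sons
            maternal += n_daughters + n_sons
        elif model.linkage == "autosome":
            total += 2 * n
            maternal += n
        else:  # Y: father-to-son only
            total += n_sons
            # maternal += 0
        sexes = offspring_female
    return CosegregationEstimate(
        linkage=model.linkage,
        fraction=maternal / total if total else 0.0,
        maternal_copies=maternal,
        total_copies=total,
        generations=model.generations,
        seed=model.seed,
    )
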