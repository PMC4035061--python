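"""Genome annotations and gene lists: reading, validation, normalization.

Every downstream module consumes the three types defined here. A
:class:`GeneRecord` is the unit of analysis — one nuclear gene with a
chromosome-arm assignment and two boolean covariates (testis-biased
expression, duplicate status). An :class:`AnnotationTable` is the gene
universe ("background") against which enrichment is measured, and a
:class:`GeneSet` is a named list of gene identifiers (e.g. the
mito-annotated genes, the core mito-proteome, the mito-sensitive genes).

Gene identifiers are case-sensitive, whitespace-stripped tokens; no fuzzy
matching or probe-to-gene mapping is attempted.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

log = logging.getLogger(__name__)

#: Chromosome-arm vocabulary for the D. melanogaster genome. ``other``
#: absorbs arms outside the declared vocabulary; ``unknown`` marks genes on
#: unplaced scaffolds, which stay in the table but are excluded from
#: X-vs-rest denominators.
DEFAULT_ARM_VOCABULARY: tuple[str, ...] = (
    "X", "2L", "2R", "3L", "3R", "4", "Y", "other", "unknown",
)

DEFAULT_X_ARMS: tuple[str, ...] = ("X",)


class AnnotationError(ValueError):
    """Invalid annotation input (duplicate IDs, empty files, bad formats)."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene: identifier, chromosome arm, and boolean covariates."""

    gene_id: str
    chromosome: str
    testis_biased: bool = False
    duplicate: bool = False

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise AnnotationError("gene_id must be non-empty")


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers with a provenance note."""

    name: str
    gene_ids: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise AnnotationError("GeneSet name must be non-empty")
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids

    def intersection(self, other: "GeneSet | Iterable[str]") -> frozenset[str]:
        other_ids = other.gene_ids if isinstance(other, GeneSet) else frozenset(other)
        return self.gene_ids & other_ids


class AnnotationTable:
    """Collection of :class:`GeneRecord` keyed by gene_id.

    Parameters
    ----------
    records:
        Gene records; gene_ids must be unique.
    arm_vocabulary:
        Ordered list of valid chromosome labels.
    x_arms:
        Subset of arms counted as X-linked (default ``("X",)``).
    """

    def __init__(
        self,
        records: Iterable[GeneRecord],
        arm_vocabulary: Sequence[str] = DEFAULT_ARM_VOCABULARY,
        x_arms: Sequence[str] = DEFAULT_X_ARMS,
    ) -> None:
        self.arm_vocabulary = tuple(arm_vocabulary)
        self.x_arms = tuple(x_arms)
        if not set(self.x_arms) <= set(self.arm_vocabulary):
            raise AnnotationError(
                f"x_arms {self.x_arms} not a subset of the arm vocabulary"
            )
        self._records: dict[str, GeneRecord] = {}
        for rec in records:
            if rec.gene_id in self._records:
                raise AnnotationError(f"duplicate gene_id: {rec.gene_id!r}")
            if rec.chromosome not in self.arm_vocabulary:
                raise AnnotationError(
                    f"chromosome {rec.chromosome!r} of {rec.gene_id!r} not in vocabulary"
                )
            self._records[rec.gene_id] = rec
        if not self._records:
            raise AnnotationError("AnnotationTable must contain at least one gene")

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._records.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._records

    def record(self, gene_id: str) -> GeneRecord:
        return self._records[gene_id]

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(self._records)

    def arm_counts(self) -> dict[str, int]:
        counts = Counter(rec.chromosome for rec in self)
        return {arm: counts.get(arm, 0) for arm in self.arm_vocabulary}

    def known_ids(self) -> frozenset[str]:
        """Gene ids with a placed chromosome (arm != 'unknown')."""
        return frozenset(
            rec.gene_id for rec in self if rec.chromosome != "unknown"
        )

    def x_ids(self) -> frozenset[str]:
        """Gene ids on the arms counted as X-linked."""
        return frozenset(
            rec.gene_id for rec in self if rec.chromosome in self.x_arms
        )

    def flagged_ids(self, flag: str) -> frozenset[str]:
        """Gene ids with a boolean flag (``testis_biased`` or ``duplicate``) set."""
        if flag not in ("testis_biased", "duplicate"):
            raise AnnotationError(f"unknown flag {flag!r}")
        return frozenset(
            rec.gene_id for rec in self if getattr(rec, flag)
        )

    def subset(self, gene_ids: Iterable[str]) -> "AnnotationTable":
        """New table restricted to ``gene_ids`` (input order preserved)."""
        keep = set(gene_ids)
        return AnnotationTable(
            (rec for rec in self if rec.gene_id in keep),
            arm_vocabulary=self.arm_vocabulary,
            x_arms=self.x_arms,
        )


def _parse_flag(token: str, path: Path, column: str) -> bool:
    token = token.strip()
    if token in ("0", ""):
        return False
    if token == "1":
        return True
    raise AnnotationError(f"{path}: flag column {column!r} must be 0/1, got {token!r}")


def _read_annotation_tsv(
    path: Path, arm_vocabulary: Sequence[str]
) -> list[GeneRecord]:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise AnnotationError(f"{path}: empty annotation file")
    header = lines[0].split("\t")
    required = {"gene_id", "chromosome"}
    if not required <= set(header):
        raise AnnotationError(
            f"{path}: header must contain gene_id and chromosome, got {header}"
        )
    idx = {col: header.index(col) for col in header}
    records = []
    vocab = set(arm_vocabulary)
    for ln in lines[1:]:
        fields = ln.split("\t")
        gene_id = fields[idx["gene_id"]].strip()
        arm = fields[idx["chromosome"]].strip()
        if arm not in vocab:
            arm = "other"
        kwargs = {}
        for flag in ("testis_biased", "duplicate"):
            if flag in idx and len(fields) > idx[flag]:
                kwargs[flag] = _parse_flag(fields[idx[flag]], path, flag)
        records.append(GeneRecord(gene_id, arm, **kwargs))
    return records


def _read_annotation_gff3(
    path: Path, arm_vocabulary: Sequence[str]
) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    vocab = set(arm_vocabulary)
    records = []
    for feat in db.features_of_type("gene"):
        arm = feat.seqid if feat.seqid in vocab else "other"
        records.append(GeneRecord(feat.id, arm))
    if not records:
        raise AnnotationError(f"{path}: no gene features found")
    return records


def read_annotation(
    path: str | Path,
    format: str = "tsv",
    x_arms: Sequence[str] = DEFAULT_X_ARMS,
    arm_vocabulary: Sequence[str] = DEFAULT_ARM_VOCABULARY,
) -> AnnotationTable:
    """Read a genome annotation into an :class:`AnnotationTable`.

    ``format`` is ``"tsv"`` (columns gene_id, chromosome[, testis_biased,
    duplicate]) or ``"gff3"`` (rows of type ``gene``; seqid used as arm).
    Arms outside the vocabulary map to ``"other"``. Duplicate gene_ids are a
    hard error naming the offending ID.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"annotation file not found: {path}")
    if format == "tsv":
        records = _read_annotation_tsv(path, arm_vocabulary)
    elif format == "gff3":
        records = _read_annotation_gff3(path, arm_vocabulary)
    else:
        raise AnnotationError(f"unknown annotation format {format!r}")
    table = AnnotationTable(records, arm_vocabulary=arm_vocabulary, x_arms=x_arms)
    log.info("read %d genes from %s; arm counts: %s", len(table), path,
             table.arm_counts())
    return table


def write_annotation(table: AnnotationTable, path: str | Path) -> None:
    """Write the TSV dialect of :func:`read_annotation` (flags as 0/1)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tchromosome\ttestis_biased\tduplicate\n")
        for rec in table:
            fh.write(
                f"{rec.gene_id}\t{rec.chromosome}\t"
                f"{int(rec.testis_biased)}\t{int(rec.duplicate)}\n"
            )


def read_gene_set(path: str | Path, name: str) -> GeneSet:
    """Read a plain-text gene list (one ID per line, ``#`` comments).

    Duplicate IDs are collapsed (count logged); an empty list after
    filtering is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"gene list not found: {path}")
    ids: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            ids.append(token)
    unique = frozenset(ids)
    if not unique:
        raise AnnotationError(f"{path}: gene list empty after filtering")
    if len(unique) < len(ids):
        log.info("%s: collapsed %d duplicate ids", path, len(ids) - len(unique))
    return GeneSet(name=name, gene_ids=unique, provenance=str(path))


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    """Write a gene list in the plain-text dialect (sorted, one ID per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        for gene_id in sorted(gene_set.gene_ids):
            fh.write(gene_id + "\n")


def restrict_to_background(
    gene_set: GeneSet, table: AnnotationTable
) -> GeneSet:
    """Intersect a gene set with the background table's gene universe.

    Enrichment statistics are only meaningful for genes present in the
    background (e.g. genes with probe-sets on the expression array), so
    off-background members are dropped; the count dropped is logged.
    """
    kept = gene_set.gene_ids & table.gene_ids
    dropped = len(gene_set) - len(kept)
    if not kept:
        raise AnnotationError(
            f"gene set {gene_set.name!r} is disjoint from the background"
        )
    if dropped:
        log.info("restrict_to_background: dropped %d/%d ids of %r",
                 dropped, len(gene_set), gene_set.name)
    return GeneSet(
        name=gene_set.name,
        gene_ids=kept,
        provenance=f"{gene_set.provenance} ∩ background" if gene_set.provenance
        else "∩ background",
    )


def overlap_fraction(a: GeneSet, b: GeneSet) -> float:
    """Directional overlap |a∩b| / |a|.

    Directional because published overlap statements are asymmetric
    (a fraction *of* one list found in another); compute both directions
    explicitly when a symmetric picture is wanted.
    """
    if len(a) == 0:
        raise AnnotationError(f"overlap_fraction: set {a.name!r} is empty")
    return len(a.gene_ids & b.gene_ids) / len(a)
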