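"""CNVR annotation against gene and QTL intervals.

A feature is "positive" for a CNVR when strictly more than half of the
feature's length is overlapped by the CNVR — the denominator is the feature
length, not the CNVR length, and the 50% boundary is exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from intervaltree import IntervalTree

from .core import Cnvr, FeatureInterval, overlap_bp

DEFAULT_MIN_FRACTION = 0.5


@dataclass(frozen=True)
class AnnotationHit:
    """One CNVR/feature overlap with its base-pair extent and feature fraction."""

    cnvr_id: str
    feature_id: str
    kind: str
    overlap_bp: int
    fraction: float  # of the feature length
    positive: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("overlap fraction must be within [0, 1]")


@dataclass
class AnnotationSummary:
    """CNVR-level gene/QTL content over one CNVR set."""

    n_cnvrs: int
    n_cnvrs_with_gene: int
    n_cnvrs_with_qtl: int
    n_positive_genes: int
    n_positive_qtls: int
    qtl_class_counts: dict[str, int] = field(default_factory=dict)

    @property
    def percent_with_gene(self) -> float:
        return 100.0 * self.n_cnvrs_with_gene / self.n_cnvrs if self.n_cnvrs else 0.0

    @property
    def percent_with_qtl(self) -> float:
        return 100.0 * self.n_cnvrs_with_qtl / self.n_cnvrs if self.n_cnvrs else 0.0


def overlap_features(
    cnvrs: Sequence[Cnvr],
    features: Sequence[FeatureInterval],
    min_fraction: float = DEFAULT_MIN_FRACTION,
    chromosomes: Sequence[str] | None = None,
) -> tuple[list[AnnotationHit], AnnotationSummary]:
    """Intersect CNVRs with features and score positives by feature fraction.

    ``fraction = overlap bp / feature length``; positive iff fraction is
    strictly greater than ``min_fraction``.  When ``chromosomes`` is given,
    any CNVR or feature on a name outside that set is rejected with a listing
    of the unmatched names (guards against mixed naming conventions).
    """
    if not (0.0 <= min_fraction < 1.0):
        raise ValueError("min_fraction must be in [0, 1)")
    if chromosomes is not None:
        known = set(chromosomes)
        bad = sorted(
            {r.chrom for r in cnvrs if r.chrom not in known}
            | {f.chrom for f in features if f.chrom not in known}
        )
        if bad:
            raise ValueError(f"unmatched chromosome names: {bad}")

    trees: dict[str, IntervalTree] = {}
    for k, r in enumerate(cnvrs):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, k)

    hits: list[AnnotationHit] = []
    cnvr_pos_gene: set[str] = set()
    cnvr_pos_qtl: set[str] = set()
    pos_genes: set[str] = set()
    pos_qtls: set[str] = set()
    class_counts: dict[str, int] = {}
    for f in features:
        tree = trees.get(f.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(f.start, f.end)):
            r = cnvrs[iv.data]
            bp = overlap_bp(r.start, r.end, f.start, f.end)
            if bp <= 0:
                continue
            frac = bp / f.length
            positive = frac > min_fraction
            hits.append(AnnotationHit(r.id, f.id, f.kind, bp, frac, positive))
            if positive:
                if f.kind == "gene":
                    cnvr_pos_gene.add(r.id)
                    pos_genes.add(f.id)
                else:
                    cnvr_pos_qtl.add(r.id)
                    if f.id not in pos_qtls and f.trait_class:
                        class_counts[f.trait_class] = class_counts.get(f.trait_class, 0) + 1
                    pos_qtls.add(f.id)
    summary = AnnotationSummary(
        n_cnvrs=len(cnvrs),
        n_cnvrs_with_gene=len(cnvr_pos_gene),
        n_cnvrs_with_qtl=len(cnvr_pos_qtl),
        n_positive_genes=len(pos_genes),
        n_positive_qtls=len(pos_qtls),
        qtl_class_counts=dict(sorted(class_counts.items())),
    )
    return hits, summary
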