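"""Genomic interval algebra and peak classification.

All coordinates are 0-based, half-open ``[start, end)`` (BED convention).
Peak collections travel as :class:`pandas.DataFrame` objects with BED6
columns ``chrom, start, end, name, score, strand``; single intervals are
:class:`GenomicInterval` instances. Strand is ignored by every overlap
computation (counting and intersection are unstranded throughout).

The classification rules implemented here mirror common ChIP-seq practice:
a binding site is *reproducible* when its peak overlaps a peak from the
second biological replicate by at least 1 bp, and *intergenic* when it
overlaps no gene feature (promoter, exon, UTR, intron) and its center lies
more than 1 kb from every annotated TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

#: precedence used when a peak overlaps several feature types
FEATURE_PRECEDENCE = ("promoter", "exon", "UTR", "intron")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open coordinate span with optional strand/name/score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GeneModel:
    """A gene with its TSS positions and typed feature intervals.

    ``span`` is the full genomic footprint (promoter included); every
    feature interval nests inside it.  ``expressed`` marks genes that pass
    the expression filter of the accompanying RNA-seq experiment and is
    what nearest-gene annotation conditions on.
    """

    gene_id: str
    span: GenomicInterval
    tss: list[int]
    features: list[tuple[str, GenomicInterval]] = field(default_factory=list)
    expressed: bool = True

    def __post_init__(self) -> None:
        for pos in self.tss:
            if not (self.span.start <= pos < self.span.end):
                raise ValueError(f"TSS {pos} outside span of {self.gene_id}")
        for kind, iv in self.features:
            if iv.chrom != self.span.chrom or iv.start < self.span.start or iv.end > self.span.end:
                raise ValueError(f"feature {kind} escapes span of {self.gene_id}")

    @property
    def strand(self) -> str:
        return self.span.strand


@dataclass
class PeakAnnotation:
    """Nearest-expressed-gene annotation of one peak."""

    peak: GenomicInterval
    nearest_gene: str | None
    distance_to_tss: int | None
    location_class: str


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base pairs shared by two intervals; 0 if disjoint or on different chroms.

    Half-open convention: intervals that merely touch share 0 bp.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _check_bed(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("chrom", "start", "end") if c not in df.columns]
    if missing:
        raise ValueError(f"peak frame lacks columns {missing}")
    return df


def build_trees(df: pd.DataFrame) -> dict[str, IntervalTree]:
    """Index a BED-like frame as one interval tree per chromosome."""
    _check_bed(df)
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        trees[str(chrom)] = IntervalTree.from_tuples(
            (int(s), int(e), i) for i, s, e in zip(sub.index, sub["start"], sub["end"])
        )
    return trees


def _overlap_lengths(df: pd.DataFrame, trees: dict[str, IntervalTree]) -> np.ndarray:
    """Maximum single-partner overlap (bp) of each row of ``df`` against ``trees``."""
    out = np.zeros(len(df), dtype=int)
    for k, (chrom, s, e) in enumerate(zip(df["chrom"], df["start"], df["end"])):
        tree = trees.get(str(chrom))
        if tree is None:
            continue
        best = 0
        for hit in tree.overlap(int(s), int(e)):
            best = max(best, min(int(e), hit.end) - max(int(s), hit.begin))
        out[k] = best
    return out


def sort_peaks(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def reproducible_peaks(rep1: pd.DataFrame, rep2: pd.DataFrame) -> pd.DataFrame:
    """Peaks of the anchor replicate overlapping the second replicate by >= 1 bp.

    The anchor convention keeps replicate-1 coordinates for every
    reproducible site.  Output is sorted by (chrom, start, end).
    """
    _check_bed(rep1)
    if len(rep1) == 0:
        return rep1.copy()
    keep = _overlap_lengths(rep1, build_trees(rep2)) >= 1
    return sort_peaks(rep1.loc[keep])


def remove_blacklisted(peaks: pd.DataFrame, blacklist: pd.DataFrame) -> pd.DataFrame:
    """Drop peaks overlapping any blacklist interval by >= 1 bp."""
    _check_bed(peaks)
    if len(peaks) == 0 or len(blacklist) == 0:
        return peaks.copy()
    hit = _overlap_lengths(peaks, build_trees(blacklist)) >= 1
    return peaks.loc[~hit].reset_index(drop=True)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping *and bookended* intervals into a flat set."""
    _check_bed(df)
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    rows = []
    for chrom, sub in df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            s, e = int(s), int(e)
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:  # bookended (s == cur_e) joins too
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def window_around(
    peak: GenomicInterval, width: int, chrom_length: int | None = None
) -> GenomicInterval:
    """Fixed-width window centered on the peak center, clipped at chromosome bounds.

    The center is ``floor((start + end) / 2)``; the window spans
    ``[center - width//2, center - width//2 + width)`` so its length is
    exactly ``width`` unless clipping shortens it.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    start = peak.center - width // 2
    end = start + width
    if start < 0:
        start = 0
    if chrom_length is not None and end > chrom_length:
        end = chrom_length
    return GenomicInterval(peak.chrom, start, end, peak.strand, peak.name, peak.score)


def trim_to_center(peak: GenomicInterval, width: int = 100,
                   chrom_length: int | None = None) -> GenomicInterval:
    """Trim a peak to ``width`` bp around its center (motif-analysis convention)."""
    return window_around(peak, width, chrom_length)


def windows_around(
    peaks: pd.DataFrame, width: int, chrom_sizes: dict[str, int] | None = None
) -> pd.DataFrame:
    """Vectorised :func:`window_around` over a peak frame; keeps other columns."""
    if width <= 0:
        raise ValueError("width must be positive")
    out = peaks.copy().reset_index(drop=True)
    center = (out["start"].to_numpy(int) + out["end"].to_numpy(int)) // 2
    start = center - width // 2
    end = start + width
    start = np.maximum(start, 0)
    if chrom_sizes:
        limits = out["chrom"].map(chrom_sizes).to_numpy(float)
        has = ~np.isnan(limits)
        end = np.where(has, np.minimum(end, np.where(has, limits, np.inf)), end).astype(int)
    out["start"], out["end"] = start, end
    return out


@dataclass
class IntersectReport:
    """Two-sided peak-set intersection counts at a fixed bp threshold."""

    a_only: int
    b_only: int
    shared_a: int
    shared_b: int
    shared_a_index: list = field(default_factory=list)
    shared_b_index: list = field(default_factory=list)


def intersect_sets(set_a: pd.DataFrame, set_b: pd.DataFrame, min_bp: int = 1) -> IntersectReport:
    """Classify each element of A (and of B) as shared or side-specific.

    An element of A is shared when it overlaps at least one element of B by
    ``min_bp`` or more (single-partner overlap, not summed across partners),
    and symmetrically for B.  Counts are reported per side: sharing need
    not be numerically symmetric.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    shared_a = _overlap_lengths(set_a, build_trees(set_b)) >= min_bp if len(set_a) else np.array([], bool)
    shared_b = _overlap_lengths(set_b, build_trees(set_a)) >= min_bp if len(set_b) else np.array([], bool)
    return IntersectReport(
        a_only=int((~shared_a).sum()),
        b_only=int((~shared_b).sum()),
        shared_a=int(shared_a.sum()),
        shared_b=int(shared_b.sum()),
        shared_a_index=list(set_a.index[shared_a]) if len(set_a) else [],
        shared_b_index=list(set_b.index[shared_b]) if len(set_b) else [],
    )


def _promoters(gene: GeneModel, promoter_halfwidth: int) -> list[GenomicInterval]:
    out = []
    for pos in gene.tss:
        s = max(0, pos - promoter_halfwidth)
        out.append(GenomicInterval(gene.span.chrom, s, pos + promoter_halfwidth))
    return out


def classify_location(
    peak: GenomicInterval,
    genes: list[GeneModel],
    tss_distance: int = 1000,
    promoter_halfwidth: int = 1000,
) -> str:
    """Locate a peak relative to gene features.

    Returns ``intergenic`` iff the peak overlaps no feature of any gene
    (expressed or not) *and* its center lies more than ``tss_distance`` bp
    from every TSS.  Otherwise the class of the overlapped feature with
    precedence promoter > exon > UTR > intron; a peak near a TSS without
    direct feature overlap is classed ``promoter``.
    """
    hit_kinds: set[str] = set()
    near_tss = False
    for gene in genes:
        if gene.span.chrom != peak.chrom:
            continue
        for pos in gene.tss:
            if abs(peak.center - pos) <= tss_distance:
                near_tss = True
        for prom in _promoters(gene, promoter_halfwidth):
            if overlap_bp(peak, prom) > 0:
                hit_kinds.add("promoter")
        for kind, iv in gene.features:
            if overlap_bp(peak, iv) > 0:
                hit_kinds.add("UTR" if kind in ("five_prime_utr", "three_prime_utr") else kind)
    if not hit_kinds and not near_tss:
        return "intergenic"
    for kind in FEATURE_PRECEDENCE:
        if kind in hit_kinds:
            return kind
    return "promoter"  # near a TSS but outside every stored feature


def annotate_nearest_expressed_gene(
    peaks: pd.DataFrame,
    genes: list[GeneModel],
    tss_distance: int = 1000,
    promoter_halfwidth: int = 1000,
) -> pd.DataFrame:
    """Annotate each peak with its closest expressed gene and location class.

    Distance runs from the peak center to the nearest TSS of the winning
    gene, signed by gene strand (negative when the peak lies upstream of
    the TSS).  Ties on |distance| break to the lexicographically smaller
    gene_id; chromosomes without an expressed gene annotate to ``None``.
    """
    _check_bed(peaks)
    expressed = [g for g in genes if g.expressed]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in expressed:
        by_chrom.setdefault(g.span.chrom, []).append(g)

    rows = []
    for idx, chrom, s, e in zip(peaks.index, peaks["chrom"], peaks["start"], peaks["end"]):
        peak = GenomicInterval(str(chrom), int(s), int(e))
        best: tuple[int, str, int] | None = None  # (|dist|, gene_id, signed dist)
        for g in by_chrom.get(peak.chrom, []):
            for pos in g.tss:
                signed = peak.center - pos
                if g.strand == "-":
                    signed = -signed
                key = (abs(signed), g.gene_id, signed)
                if best is None or key[:2] < best[:2]:
                    best = key
        loc = classify_location(peak, genes, tss_distance, promoter_halfwidth)
        rows.append(
            {
                "peak_index": idx,
                "chrom": peak.chrom,
                "start": peak.start,
                "end": peak.end,
                "nearest_gene": None if best is None else best[1],
                "distance_to_tss": None if best is None else best[2],
                "location_class": loc,
            }
        )
    return pd.DataFrame(rows)
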