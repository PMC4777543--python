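"""Genomic-interval algebra for peak-set integration.

All coordinates are 0-based half-open (BED convention).  Two intervals
overlap iff they lie on the same chromosome and share at least one
nucleotide, i.e. ``max(starts) < min(ends)``; abutting intervals do not
overlap.

The module provides the primitives every downstream stage builds on:

* replicate intersection with per-replicate concordance,
* overlap fractions of a peak set against a reference region set,
* nearest-TSS annotation within a distance cutoff, with strand-aware
  signed distances,
* positional classification (proximal / distal upstream / distal
  downstream), and
* Pearson correlation of paired peak heights.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

MAX_TSS_DISTANCE = 100_000
PROXIMAL_BOUND = 1_000

PROXIMAL = "proximal"
DISTAL_UPSTREAM = "distal_upstream"
DISTAL_DOWNSTREAM = "distal_downstream"
UNASSIGNED = "unassigned"

POSITION_CLASSES = (PROXIMAL, DISTAL_UPSTREAM, DISTAL_DOWNSTREAM)


class EmptyQueryError(ValueError):
    """Raised when an overlap fraction is requested for an empty peak set.

    Distinguishes "no peaks were supplied" from the legitimate result
    "no peak overlapped the reference".
    """


class ZeroVarianceError(ValueError):
    """Raised when a correlation is undefined because one coordinate is constant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"interval start must precede end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor midpoint, used as the default peak reference point."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and max(self.start, other.start) < min(
            self.end, other.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff ``a`` and ``b`` share >= 1 nucleotide."""
    return a.overlaps(b)


@dataclass(frozen=True)
class Peak:
    """A called binding site: an interval plus a height (cumulative tag count
    surrogate) and an optional summit."""

    interval: GenomicInterval
    height: float = 0.0
    summit: Optional[int] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError("peak height must be nonnegative")
        if self.summit is not None and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValueError("summit must lie within the peak interval")

    @property
    def reference_point(self) -> int:
        """Summit if present, else the interval midpoint."""
        return self.summit if self.summit is not None else self.interval.midpoint


class PeakSet:
    """An ordered collection of peaks with a lazy per-chromosome interval index."""

    def __init__(self, peaks: Iterable[Peak] = ()):  # noqa: D401
        self.peaks: list[Peak] = list(peaks)
        self._trees: Optional[dict[str, IntervalTree]] = None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def add(self, peak: Peak) -> None:
        self.peaks.append(peak)
        self._trees = None

    @property
    def trees(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
            for i, p in enumerate(self.peaks):
                trees[p.interval.chrom].addi(p.interval.start, p.interval.end, i)
            self._trees = dict(trees)
        return self._trees

    def overlapping(self, interval: GenomicInterval) -> list[int]:
        """Indices of member peaks sharing >= 1 bp with ``interval``."""
        tree = self.trees.get(interval.chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.overlap(interval.start, interval.end))


class RegionSet:
    """A reference interval set (DHS regions, cofactor occupancy, ...)."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):  # noqa: D401
        self.intervals: list[GenomicInterval] = list(intervals)
        self._trees: Optional[dict[str, IntervalTree]] = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    @property
    def trees(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
            for iv in self.intervals:
                trees[iv.chrom].addi(iv.start, iv.end)
            self._trees = dict(trees)
        return self._trees

    def overlaps_interval(self, interval: GenomicInterval) -> bool:
        tree = self.trees.get(interval.chrom)
        return tree is not None and bool(tree.overlap(interval.start, interval.end))


@dataclass
class Gene:
    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


class GeneAnnotation:
    """TSS + strand per gene; the coordinate frame for all peak distances."""

    def __init__(self, genes: Iterable[Gene] = ()):  # noqa: D401
        self.genes: list[Gene] = list(genes)
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene identifiers must be unique")
        self._by_chrom: Optional[dict[str, tuple[list[int], list[Gene]]]] = None

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def subset(self, gene_ids: Iterable[str]) -> "GeneAnnotation":
        wanted = set(gene_ids)
        return GeneAnnotation(g for g in self.genes if g.gene_id in wanted)

    def _index(self) -> dict[str, tuple[list[int], list[Gene]]]:
        if self._by_chrom is None:
            grouped: dict[str, list[Gene]] = defaultdict(list)
            for g in self.genes:
                grouped[g.chrom].append(g)
            out: dict[str, tuple[list[int], list[Gene]]] = {}
            for chrom, gs in grouped.items():
                gs.sort(key=lambda g: (g.tss, g.gene_id))
                out[chrom] = ([g.tss for g in gs], gs)
            self._by_chrom = out
        return self._by_chrom

    def nearest(self, chrom: str, point: int) -> Optional[tuple[Gene, int]]:
        """Nearest gene on ``chrom`` by absolute TSS distance.

        Equidistant candidates resolve to the lexicographically smallest
        gene identifier.  Returns ``(gene, unsigned genomic distance)`` or
        None when the chromosome carries no genes.
        """
        idx = self._index().get(chrom)
        if idx is None:
            return None
        tss_list, genes = idx
        pos = bisect.bisect_left(tss_list, point)
        best: Optional[Gene] = None
        best_d = None
        # Scan outward from the insertion point; equal-TSS duplicates are
        # adjacent after the (tss, id) sort, so walk while distance ties.
        for j in range(pos - 1, -1, -1):
            d = abs(point - tss_list[j])
            if best_d is not None and d > best_d:
                break
            if best_d is None or d < best_d or genes[j].gene_id < best.gene_id:
                best, best_d = genes[j], d
        for j in range(pos, len(tss_list)):
            d = abs(point - tss_list[j])
            if best_d is not None and d > best_d:
                break
            if best_d is None or d < best_d or genes[j].gene_id < best.gene_id:
                best, best_d = genes[j], d
        assert best is not None and best_d is not None
        return best, best_d


@dataclass
class ConcordanceReport:
    """Replicate-intersection summary.

    ``concordance1`` / ``concordance2`` are the shared count divided by each
    replicate's size (the two candidate readings of a single "concordance"
    figure whose denominator is ambiguous); ``mean_concordance`` is their
    arithmetic mean.
    """

    shared: int
    n1: int
    n2: int
    concordance1: float
    concordance2: float
    mean_concordance: float
    empty_input: bool = False
    pairs: list[tuple[int, int]] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "shared": self.shared,
            "n_replicate1": self.n1,
            "n_replicate2": self.n2,
            "concordance_replicate1": self.concordance1,
            "concordance_replicate2": self.concordance2,
            "mean_concordance": self.mean_concordance,
            "empty_input": self.empty_input,
        }


def intersect_peaksets(r1: PeakSet, r2: PeakSet) -> tuple[PeakSet, ConcordanceReport]:
    """High-confidence peaks: replicate-1 peaks with >= 1 bp overlap in replicate 2.

    Each replicate-1 peak is counted once and paired with its
    largest-overlap replicate-2 mate (ties -> leftmost mate).  The
    replicate-1 interval is retained as the high-confidence peak, which
    preserves peak widths for window extraction.
    """
    if len(r1) == 0 or len(r2) == 0:
        report = ConcordanceReport(0, len(r1), len(r2), 0.0, 0.0, 0.0, empty_input=True)
        return PeakSet(), report
    hc: list[Peak] = []
    pairs: list[tuple[int, int]] = []
    for i, p in enumerate(r1):
        hits = r2.overlapping(p.interval)
        if not hits:
            continue
        # largest overlap wins; ties broken by leftmost (then first-listed) mate
        best = max(
            hits,
            key=lambda j: (
                p.interval.overlap_length(r2[j].interval),
                -r2[j].interval.start,
                -j,
            ),
        )
        hc.append(p)
        pairs.append((i, best))
    shared = len(hc)
    c1 = shared / len(r1)
    c2 = shared / len(r2)
    report = ConcordanceReport(shared, len(r1), len(r2), c1, c2, (c1 + c2) / 2.0, pairs=pairs)
    return PeakSet(hc), report


def overlap_fraction(query: PeakSet, reference: RegionSet) -> tuple[float, np.ndarray]:
    """Fraction of query peaks with >= 1 bp overlap with any reference region.

    Returns ``(fraction, flags)`` where ``flags[i]`` marks query peak *i*.
    An empty query raises :class:`EmptyQueryError` rather than reporting 0.
    """
    if len(query) == 0:
        raise EmptyQueryError(
            "overlap fraction is undefined for an empty query peak set "
            "(zero overlap would be indistinguishable from missing input)"
        )
    flags = np.fromiter(
        (reference.overlaps_interval(p.interval) for p in query),
        dtype=bool,
        count=len(query),
    )
    return float(flags.mean()), flags


@dataclass
class PeakAnnotation:
    """Assignment of one peak to its nearest TSS within the distance cutoff.

    ``signed_distance`` is strand-aware: negative values lie upstream of the
    TSS in the gene's reading orientation.
    """

    peak_name: str
    gene_id: Optional[str]
    signed_distance: Optional[int]
    position_class: str

    @property
    def assigned(self) -> bool:
        return self.gene_id is not None


def classify_position(signed_distance: int) -> str:
    """Positional class of an assigned peak-to-TSS distance.

    proximal: |d| <= 1 kb (boundaries inclusive); distal upstream:
    -100 kb <= d < -1 kb; distal downstream: +1 kb < d <= +100 kb.  The
    three classes partition [-100 kb, +100 kb]; anything beyond is
    unassigned.
    """
    d = int(signed_distance)
    if abs(d) <= PROXIMAL_BOUND:
        return PROXIMAL
    if -MAX_TSS_DISTANCE <= d < -PROXIMAL_BOUND:
        return DISTAL_UPSTREAM
    if PROXIMAL_BOUND < d <= MAX_TSS_DISTANCE:
        return DISTAL_DOWNSTREAM
    return UNASSIGNED


def annotate_nearest_tss(
    peaks: PeakSet,
    genes: GeneAnnotation,
    max_dist: int = MAX_TSS_DISTANCE,
) -> list[PeakAnnotation]:
    """Assign each peak to the nearest TSS within ``max_dist``.

    The peak reference point is the summit if present, else the interval
    midpoint.  Nearest is by absolute genomic distance; equidistant genes
    resolve to the lexicographically smaller identifier.  Peaks with no
    gene within the cutoff are unassigned.
    """
    if len(genes) == 0:
        raise ValueError("gene annotation is empty")
    out: list[PeakAnnotation] = []
    for i, p in enumerate(peaks):
        name = p.name or f"peak_{i}"
        point = p.reference_point
        hit = genes.nearest(p.interval.chrom, point)
        if hit is None or hit[1] > max_dist:
            out.append(PeakAnnotation(name, None, None, UNASSIGNED))
            continue
        gene, _ = hit
        delta = point - gene.tss
        signed = delta if gene.strand == "+" else -delta
        out.append(PeakAnnotation(name, gene.gene_id, signed, classify_position(signed)))
    return out


def height_correlation(
    heights1: Sequence[float], heights2: Sequence[float]
) -> tuple[float, float]:
    """Pearson product-moment correlation of paired peak heights (raw scale).

    Returns ``(r, round(r, 2))`` — full precision alongside the 2-decimal
    headline value.
    """
    x = np.asarray(heights1, dtype=float)
    y = np.asarray(heights2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("height vectors must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 height pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined: a height vector is constant")
    r = float(stats.pearsonr(x, y).statistic)
    return r, round(r, 2)
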