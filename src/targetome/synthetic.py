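"""Synthetic input generators with exactly planted structure.

Every generator realizes its planted quantity *exactly*: replicate peak
sets share exactly ``k`` pairs, quota-based region sets overlap exactly
``round(fraction * n / 100)`` target peaks, planted peak-to-TSS distances
survive jitter without changing positional class, and expression matrices
carry their truth labels.  This is what makes every downstream counting
operation testable against integers rather than approximations.

Genes are laid out with a large minimum TSS spacing (default 300 kb, i.e.
more than twice the 100 kb annotation cutoff plus peak widths) so that the
nearest-gene assignment of every planted peak is unambiguous and recovers
the planted gene map with zero mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    Gene,
    GeneAnnotation,
    GenomicInterval,
    MAX_TSS_DISTANCE,
    Peak,
    PeakSet,
    PROXIMAL_BOUND,
    RegionSet,
    overlap_fraction,
)
from .motifs import IUPAC, Motif, reverse_complement, scan_consensus
from .utils import largest_remainder_counts, round_half_away

DEFAULT_SEED = 42
DEFAULT_SPACING = 300_000
UNIQUE_PEAK_CHROM = "chrU"

CATEGORY_ORDER = ("proximal", "distal_upstream", "distal_downstream")


class GenomeTooSmallError(ValueError):
    """The genome model cannot host the requested number of genes."""


class NestingError(ValueError):
    """A nested region quota exceeds the eligible (parent-overlapped) peak count."""


@dataclass
class GenomeModel:
    """Chromosome names/lengths plus the minimum inter-gene TSS spacing."""

    chromosomes: dict[str, int]
    spacing: int = DEFAULT_SPACING
    max_peak_width: int = 1_000

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome needs at least one chromosome")
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has nonpositive length")
        floor = 2 * MAX_TSS_DISTANCE + 2 * self.max_peak_width
        if self.spacing < floor:
            raise ValueError(
                f"spacing {self.spacing} too small: need >= {floor} so nearest-gene "
                "assignment within 100 kb is unambiguous"
            )

    @property
    def total_length(self) -> int:
        return sum(self.chromosomes.values())


@dataclass
class FixtureSpec:
    """Planted counts, quotas and effects that the generators realize exactly.

    Positional quotas are integer-percentage triples (proximal, distal
    upstream, distal downstream) summing to 100; DHS and cofactor quotas
    are overlap percentages of the per-direction peak sets, with the
    cofactor quota required to nest inside the DHS quota (cofactor-occupied
    sites lie in accessible chromatin).
    """

    n1: int
    n2: int
    k: int
    n_genes: int  # unique genes the shared peaks map onto
    n_up: int = 0
    n_down: int = 0
    bound_up: int = 0
    bound_down: int = 0
    positional_quota_up: tuple[float, float, float] = (14, 23, 63)
    positional_quota_down: tuple[float, float, float] = (9, 27, 64)
    dhs_quota_up: float = 42.0
    dhs_quota_down: float = 69.0
    cofactor_quota_up: float = 32.0
    cofactor_quota_down: float = 53.0
    rho: float = 0.91
    peak_width: int = 200
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.k > min(self.n1, self.n2):
            raise ValueError("shared count k cannot exceed either replicate size")
        if self.k and not (0 < self.n_genes <= self.k):
            raise ValueError("unique-gene target must be in (0, k]")
        for name in ("positional_quota_up", "positional_quota_down"):
            q = getattr(self, name)
            if len(q) != 3 or abs(sum(q) - 100) > 1e-9 or any(v < 0 for v in q):
                raise ValueError(f"{name} must be three nonnegative values summing to 100")
        for name in ("dhs_quota_up", "dhs_quota_down", "cofactor_quota_up",
                     "cofactor_quota_down"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percentage in [0, 100]")
        if self.cofactor_quota_up > self.dhs_quota_up:
            raise ValueError("cofactor quota (up) must nest within the DHS quota")
        if self.cofactor_quota_down > self.dhs_quota_down:
            raise ValueError("cofactor quota (down) must nest within the DHS quota")
        if not -1 <= self.rho <= 1:
            raise ValueError("height correlation rho must lie in [-1, 1]")
        if self.bound_up > self.n_up or self.bound_down > self.n_down:
            raise ValueError("bound-regulated allocation cannot exceed regulated counts")
        if self.peak_width < 8:
            raise ValueError("peak width too small to carry jittered overlaps")

    @property
    def targetome_size(self) -> int:
        return self.bound_up + self.bound_down


def genome_for(spec: FixtureSpec, n_genes: Optional[int] = None,
               spacing: int = DEFAULT_SPACING) -> GenomeModel:
    """A genome model large enough for ``n_genes`` plus a peak-only chromosome.

    Gene-bearing chromosomes mimic a multi-chromosome layout; a dedicated
    chromosome hosts the replicate-unique peaks so they can never collide
    with gene neighborhoods.
    """
    n = spec.n_genes if n_genes is None else n_genes
    per_chrom = 1000
    n_chroms = max(1, -(-max(n, 1) // per_chrom))
    chrom_len = int((per_chrom + 2) * spacing * 1.3)
    chroms = {f"chr{i + 1}": chrom_len for i in range(n_chroms)}
    n_unique = (spec.n1 - spec.k) + (spec.n2 - spec.k)
    chroms[UNIQUE_PEAK_CHROM] = max(1_000, (n_unique + 2) * 3 * spec.peak_width)
    return GenomeModel(chroms, spacing=spacing)


def generate_gene_annotation(
    genome: GenomeModel, n_genes: int, seed: Optional[int] = None
) -> GeneAnnotation:
    """Place ``n_genes`` TSSs with pairwise spacing >= ``genome.spacing``.

    Genes fill chromosomes in order (the dedicated peak-only chromosome is
    skipped); positions advance by spacing plus a random slack, strands are
    random.  Deterministic for a fixed seed.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be nonnegative")
    rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)
    spacing = genome.spacing
    genes: list[Gene] = []
    width = len(str(max(n_genes, 1)))
    gi = 0
    for chrom, length in genome.chromosomes.items():
        if chrom == UNIQUE_PEAK_CHROM:
            continue
        pos = spacing  # leave headroom at the chromosome start
        while gi < n_genes and pos + spacing < length:
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(f"G{gi:0{width}d}", chrom, int(pos), strand))
            gi += 1
            pos += spacing + int(rng.integers(0, spacing // 4))
        if gi >= n_genes:
            break
    if gi < n_genes:
        deficit = n_genes - gi
        raise GenomeTooSmallError(
            f"genome too small: placed {gi} of {n_genes} genes at spacing "
            f"{spacing} bp; {deficit} more would not fit"
        )
    return GeneAnnotation(genes)


@dataclass
class PlantedPeak:
    """Truth record for one shared peak: its gene, category and distance."""

    index: int
    gene_id: str
    direction: str  # up / down / none
    category: str
    signed_distance: int


def _draw_distance(category: str, margin: int, rng: np.random.Generator) -> int:
    """A signed TSS distance inside ``category`` with a jitter-proof margin."""
    if category == "proximal":
        return int(rng.integers(-(PROXIMAL_BOUND - margin), PROXIMAL_BOUND - margin + 1))
    if category == "distal_upstream":
        return int(rng.integers(-(MAX_TSS_DISTANCE - margin),
                                -(PROXIMAL_BOUND + margin) + 1))
    if category == "distal_downstream":
        return int(rng.integers(PROXIMAL_BOUND + margin,
                                MAX_TSS_DISTANCE - margin + 1))
    raise ValueError(f"unknown positional category {category!r}")


def generate_paired_heights(
    n: int,
    rho: float,
    seed: Optional[int] = None,
    mean: float = 200.0,
    sd: float = 40.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired peak heights with population Pearson correlation ``rho``.

    Drawn from a bivariate normal on the raw height scale (the scale the
    pipeline correlates), then floored at zero; with the default mean/sd
    the floor is ~5 sd away and effectively never binds.  ``rho = 1``
    yields exactly collinear pairs (sample r = 1.0).
    """
    if n < 3:
        raise ValueError("need at least 3 pairs for a meaningful correlation")
    if not -1 <= rho <= 1:
        raise ValueError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    y = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * z2
    h1 = np.maximum(0.0, mean + sd * z1)
    h2 = np.maximum(0.0, mean + sd * y)
    return h1, h2


def generate_replicate_peaksets(
    spec: FixtureSpec,
    annotation: GeneAnnotation,
    seed: Optional[int] = None,
    gene_directions: Optional[dict[str, str]] = None,
) -> tuple[PeakSet, PeakSet, list[PlantedPeak]]:
    """Two replicate peak sets sharing exactly ``spec.k`` overlapping pairs.

    The first ``spec.n_genes`` shared peaks map onto distinct genes (one
    each); remaining shared peaks revisit random genes, so the shared set
    covers exactly ``spec.n_genes`` unique genes.  Each shared peak's
    anchor sits at a planted signed distance from its gene's TSS, drawn by
    per-direction positional quota (peaks of unregulated genes follow the
    up-direction quota), with a margin so replicate jitter cannot move the
    midpoint across a class boundary or past the 100 kb cutoff.  Replicate
    pairs are jittered copies of the anchor guaranteed to share >= 1 bp;
    replicate-unique peaks live on a dedicated chromosome in disjoint
    slots, so no cross-replicate overlap exists outside the planted pairs.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if spec.n_genes > len(annotation):
        raise ValueError("annotation has fewer genes than the unique-gene target")
    gene_directions = gene_directions or {}
    w = spec.peak_width
    margin = w  # > max midpoint shift (w/4) with generous slack
    genes = annotation.genes[: spec.n_genes]

    # gene assignment: surjective onto the first n_genes genes
    gene_idx = list(range(spec.n_genes))
    if spec.k > spec.n_genes:
        gene_idx += list(rng.integers(0, spec.n_genes, spec.k - spec.n_genes))

    # direction per peak, then per-direction positional categories by
    # largest remainder at each direction's peak count
    directions = [gene_directions.get(genes[g].gene_id, "none") for g in gene_idx]
    categories: list[str] = [""] * spec.k
    for direction in ("up", "down", "none"):
        members = [i for i, d in enumerate(directions) if d == direction]
        if not members:
            continue
        quota = (spec.positional_quota_down if direction == "down"
                 else spec.positional_quota_up)
        counts = largest_remainder_counts(quota, len(members), warn=False)
        order = list(rng.permutation(len(members)))
        pos = 0
        for cat, c in zip(CATEGORY_ORDER, counts):
            for j in order[pos : pos + c]:
                categories[members[j]] = cat
            pos += c

    # distances, separated per gene so same-gene peak pairs stay disjoint
    # even after jitter (centers >= peak width + max jitter span apart)
    separation = w + w // 2 + 10
    used: dict[int, list[int]] = {}
    distances: list[int] = []
    for i in range(spec.k):
        g = gene_idx[i]
        taken = used.setdefault(g, [])
        placed = False
        # fall back to the roomier distal categories if a narrow one is full
        # at this gene; the realized category is recorded in the truth map
        for cat in (categories[i], "distal_downstream", "distal_upstream", "proximal"):
            for _ in range(500):
                d = _draw_distance(cat, margin, rng)
                if all(abs(d - u) >= separation for u in taken):
                    taken.append(d)
                    categories[i] = cat
                    placed = True
                    break
            if placed:
                break
        if not placed:  # pragma: no cover - combined quota space >> peaks per gene
            raise RuntimeError("could not place a collision-free distance")
        distances.append(d)

    h1, h2 = generate_paired_heights(
        max(spec.k, 3), spec.rho, seed=int(rng.integers(0, 2**31 - 1))
    )
    r1: list[Peak] = []
    r2: list[Peak] = []
    planted: list[PlantedPeak] = []
    for i in range(spec.k):
        gene = genes[gene_idx[i]]
        d = distances[i]
        center = gene.tss + (d if gene.strand == "+" else -d)
        j1 = int(rng.integers(-(w // 4), w // 4 + 1))
        j2 = int(rng.integers(-(w // 4), w // 4 + 1))
        iv1 = GenomicInterval(gene.chrom, center - w // 2 + j1, center + w // 2 + j1)
        iv2 = GenomicInterval(gene.chrom, center - w // 2 + j2, center + w // 2 + j2)
        r1.append(Peak(iv1, float(h1[i]), name=f"r1_{i:05d}"))
        r2.append(Peak(iv2, float(h2[i]), name=f"r2_{i:05d}"))
        planted.append(PlantedPeak(i, gene.gene_id, directions[i], categories[i], d))

    # replicate-unique peaks: disjoint slots on the dedicated chromosome
    slot = 0
    step = 3 * w
    for i in range(spec.n1 - spec.k):
        start = (slot + 1) * step
        r1.append(
            Peak(GenomicInterval(UNIQUE_PEAK_CHROM, start, start + w),
                 float(abs(rng.normal(200.0, 40.0))), name=f"r1_u{i:05d}")
        )
        slot += 1
    for i in range(spec.n2 - spec.k):
        start = (slot + 1) * step
        r2.append(
            Peak(GenomicInterval(UNIQUE_PEAK_CHROM, start, start + w),
                 float(abs(rng.normal(200.0, 40.0))), name=f"r2_u{i:05d}")
        )
        slot += 1
    return PeakSet(r1), PeakSet(r2), planted


def generate_region_set_with_quota(
    targets: PeakSet,
    fraction: float,
    seed: Optional[int] = None,
    nested_within: Optional[RegionSet] = None,
) -> RegionSet:
    """A region set overlapping exactly ``round(fraction * n / 100)`` target peaks.

    Regions are placed strictly inside their chosen target peaks, so no
    other peak is touched (target peaks must be pairwise disjoint; this is
    verified).  With ``nested_within``, chosen peaks are drawn only from
    peaks already overlapped by the parent set, enforcing e.g. that
    cofactor-occupied sites lie inside accessible (DHS) chromatin.
    """
    if not 0 <= fraction <= 100:
        raise ValueError("fraction must be a percentage in [0, 100]")
    n = len(targets)
    if n == 0:
        return RegionSet()
    rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)
    m = round_half_away(fraction * n / 100.0)
    if nested_within is not None:
        _, flags = overlap_fraction(targets, nested_within)
        eligible = np.flatnonzero(flags)
        if m > eligible.size:
            raise NestingError(
                f"quota of {m} peaks cannot nest within the {eligible.size} peaks "
                "overlapped by the parent region set"
            )
    else:
        eligible = np.arange(n)
    chosen = rng.choice(eligible, size=m, replace=False) if m else np.array([], dtype=int)
    regions: list[GenomicInterval] = []
    for i in sorted(int(c) for c in chosen):
        iv = targets[i].interval
        pad = max(1, iv.length // 3)
        a, b = iv.start + pad, iv.end - pad
        if a >= b:
            a, b = iv.start, iv.end
        regions.append(GenomicInterval(iv.chrom, a, b))
    out = RegionSet(regions)
    _, flags = overlap_fraction(targets, out) if n else (0.0, np.zeros(0, bool))
    if int(flags.sum()) != m or set(np.flatnonzero(flags)) != {int(c) for c in chosen}:
        raise ValueError(
            "quota infeasible: target peaks overlap each other, so an emitted "
            "region cannot avoid touching a non-chosen peak"
        )
    return out


@dataclass
class ExpressionTruth:
    """Planted per-probe effects with truth labels for a two-group design."""

    probe_ids: list[str]
    effects: np.ndarray  # signed planted log2 effect per probe
    labels: list[str]  # up / down / null
    sigma: float
    n_control: int = 3
    n_treated: int = 3
    baseline: float = 8.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("noise standard deviation sigma must be > 0")
        if self.n_control < 2 or self.n_treated < 2:
            raise ValueError("need >= 2 replicates per group")
        if not (len(self.probe_ids) == len(self.effects) == len(self.labels)):
            raise ValueError("probe_ids, effects and labels must align")
        for e, lab in zip(self.effects, self.labels):
            if lab == "up" and e <= 0:
                raise ValueError("up-labelled probes need positive effects")
            if lab == "down" and e >= 0:
                raise ValueError("down-labelled probes need negative effects")
            if lab == "null" and e != 0:
                raise ValueError("null-labelled probes need zero effect")

    @classmethod
    def planted(
        cls,
        n_probes: int,
        n_up: int,
        n_down: int,
        effect: float = 2.0,
        sigma: float = 0.5,
        n_control: int = 3,
        n_treated: int = 3,
        probe_ids: Optional[Sequence[str]] = None,
    ) -> "ExpressionTruth":
        if n_up + n_down > n_probes:
            raise ValueError("planted up+down counts exceed the probe count")
        if probe_ids is None:
            width = len(str(max(n_probes, 1)))
            probe_ids = [f"P{i:0{width}d}" for i in range(n_probes)]
        effects = np.zeros(n_probes)
        effects[:n_up] = abs(effect)
        effects[n_up : n_up + n_down] = -abs(effect)
        labels = ["up"] * n_up + ["down"] * n_down + ["null"] * (n_probes - n_up - n_down)
        return cls(list(probe_ids), effects, labels, sigma, n_control, n_treated)

    @property
    def up_probes(self) -> set[str]:
        return {p for p, l in zip(self.probe_ids, self.labels) if l == "up"}

    @property
    def down_probes(self) -> set[str]:
        return {p for p, l in zip(self.probe_ids, self.labels) if l == "down"}


def generate_expression_matrix(
    truth: ExpressionTruth, seed: Optional[int] = None
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Normalized-scale expression values: baseline + effect x treated + noise.

    Returns ``(matrix, groups)`` with probes as rows, samples as columns and
    a sample -> {control, treated} group map.
    """
    rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)
    n = len(truth.probe_ids)
    cols = [f"ctrl_{i + 1}" for i in range(truth.n_control)] + [
        f"trt_{i + 1}" for i in range(truth.n_treated)
    ]
    values = truth.baseline + rng.normal(0.0, truth.sigma, (n, len(cols)))
    values[:, truth.n_control :] += truth.effects[:, None]
    matrix = pd.DataFrame(values, index=list(truth.probe_ids), columns=cols)
    groups = {c: ("control" if c.startswith("ctrl") else "treated") for c in cols}
    return matrix, groups


def generate_sequences(
    window_names: Sequence[str],
    plantings: Sequence[int],
    motif: Motif,
    seed: Optional[int] = None,
    width: int = 300,
) -> list[tuple[str, str]]:
    """Background windows with an exact number of planted motif occurrences.

    Backgrounds are i.i.d. uniform nucleotides, rejection-resampled until
    they carry no accidental motif hit; planted occurrences (degenerate
    consensus positions concretized at random) are inserted at random
    non-overlapping offsets on a random strand.  A window is redrawn if
    insertion junctions create extra hits, so the scan count equals the
    planted count exactly.
    """
    if len(window_names) != len(plantings):
        raise ValueError("one planting count per window is required")
    mlen = len(motif)
    rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)
    bases = np.array(list("ACGT"))
    records: list[tuple[str, str]] = []
    for name, count in zip(window_names, plantings):
        if count < 0:
            raise ValueError("planting counts must be nonnegative")
        if count * mlen > width:
            raise ValueError(
                f"cannot plant {count} x {mlen} bp occurrences in a {width} bp window"
            )
        for _ in range(500):
            seq = rng.choice(bases, width)
            if scan_consensus("".join(seq), motif) != 0:
                continue
            offsets: list[int] = []
            ok = True
            for _ in range(count):
                for _ in range(200):
                    o = int(rng.integers(0, width - mlen + 1))
                    if all(abs(o - p) >= mlen for p in offsets):
                        offsets.append(o)
                        break
                else:
                    ok = False
                    break
            if not ok:
                continue
            for o in offsets:
                instance = "".join(
                    IUPAC[b][rng.integers(0, len(IUPAC[b]))] for b in motif.pattern
                )
                if rng.random() < 0.5:
                    instance = reverse_complement(instance)
                seq[o : o + mlen] = list(instance)
            final = "".join(seq)
            if scan_consensus(final, motif) == count:
                records.append((name, final))
                break
        else:  # pragma: no cover - acceptance probability is near 1
            raise RuntimeError(f"failed to realize planting quota in window {name!r}")
    return records
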