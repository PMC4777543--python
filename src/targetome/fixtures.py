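"""Canonical fixture bundles realizing the study's planted set structure.

Each builder wires the low-level generators in :mod:`targetome.synthetic`
into one reproducible scenario:

* :func:`replicate_fixture` — two replicate cistromes of 19,266 and 21,536
  peaks sharing exactly 14,712 pairs over 6,984 unique genes, with 547
  up- and 551 down-regulated genes of which 432 / 253 are bound (a 685-gene
  direct-target set);
* :func:`positional_fixture` — 1,000 peaks per direction whose planted
  TSS-distance categories follow the per-direction quotas 14/23/63 and
  9/27/64 exactly;
* :func:`chromatin_fixture` — 1,000 peaks per direction with DHS overlap
  quotas 42% (induced) / 69% (repressed) and cofactor occupancy 32% / 53%
  nested inside the DHS subset;
* :func:`paired_height_fixture` — 14,712 height pairs at correlation 0.91;
* :func:`expression_fixture` — 547 + 551 planted effects among 20,000
  probes (|log2 effect| 2, noise sd 0.5, 3 vs 3).

All planted integer counts are invariant to the seed; only coordinates,
noise and random choices move.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .intervals import GeneAnnotation, PeakSet, RegionSet, intersect_peaksets
from .synthetic import (
    ExpressionTruth,
    FixtureSpec,
    GenomeModel,
    PlantedPeak,
    generate_expression_matrix,
    generate_gene_annotation,
    generate_paired_heights,
    generate_region_set_with_quota,
    generate_replicate_peaksets,
    genome_for,
)

DEFAULT_SEED = 42

REPLICATE_SPEC = dict(
    n1=19_266, n2=21_536, k=14_712, n_genes=6_984,
    n_up=547, n_down=551, bound_up=432, bound_down=253,
)


@dataclass
class ReplicateFixture:
    """The full-scale two-replicate scenario plus its regulated gene sets."""

    spec: FixtureSpec
    genome: GenomeModel
    annotation: GeneAnnotation
    replicate1: PeakSet
    replicate2: PeakSet
    planted: list[PlantedPeak] = field(repr=False)
    up_genes: set[str] = field(default_factory=set)
    down_genes: set[str] = field(default_factory=set)

    @property
    def gene_directions(self) -> dict[str, str]:
        d = {g: "up" for g in self.up_genes}
        d.update({g: "down" for g in self.down_genes})
        return d


def replicate_fixture(
    seed: int = DEFAULT_SEED, scale: float = 1.0
) -> ReplicateFixture:
    """Replicate peak lists with the planted intersection and Venn structure.

    ``scale`` < 1 shrinks every planted count proportionally (keeping the
    invariants k <= min(n1, n2), bound <= regulated) for fast unit tests;
    the default is the full-scale scenario.
    """
    base = REPLICATE_SPEC
    if scale != 1.0:
        counts = {k: max(3, int(round(v * scale))) for k, v in base.items()}
        counts["k"] = min(counts["k"], counts["n1"], counts["n2"])
        counts["n_genes"] = min(counts["n_genes"], counts["k"])
        counts["bound_up"] = min(counts["bound_up"], counts["n_up"])
        counts["bound_down"] = min(counts["bound_down"], counts["n_down"])
    else:
        counts = dict(base)
    spec = FixtureSpec(seed=seed, **counts)
    rng = np.random.default_rng(seed)

    n_extra_up = spec.n_up - spec.bound_up
    n_extra_down = spec.n_down - spec.bound_down
    n_total_genes = spec.n_genes + n_extra_up + n_extra_down
    genome = genome_for(spec, n_genes=n_total_genes)
    annotation = generate_gene_annotation(
        genome, n_total_genes, seed=int(rng.integers(0, 2**31 - 1))
    )
    ids = annotation.gene_ids
    bound_ids = ids[: spec.n_genes]
    extra_ids = ids[spec.n_genes :]

    chosen = rng.choice(spec.n_genes, size=spec.bound_up + spec.bound_down, replace=False)
    up = {bound_ids[i] for i in chosen[: spec.bound_up]}
    down = {bound_ids[i] for i in chosen[spec.bound_up :]}
    up |= set(extra_ids[:n_extra_up])
    down |= set(extra_ids[n_extra_up : n_extra_up + n_extra_down])

    directions = {g: "up" for g in up}
    directions.update({g: "down" for g in down})
    r1, r2, planted = generate_replicate_peaksets(
        spec, annotation, seed=int(rng.integers(0, 2**31 - 1)),
        gene_directions=directions,
    )
    return ReplicateFixture(spec, genome, annotation, r1, r2, planted, up, down)


@dataclass
class DirectionalPeakFixture:
    """Per-direction peak sets near regulated genes, with planted truth."""

    spec: FixtureSpec
    annotation: GeneAnnotation
    peaks: PeakSet  # high-confidence set, index-aligned with ``planted``
    planted: list[PlantedPeak] = field(repr=False)
    up_genes: set[str] = field(default_factory=set)
    down_genes: set[str] = field(default_factory=set)
    dhs: Optional[RegionSet] = None
    cofactor: Optional[RegionSet] = None


def _directional_peaks(
    n_per_direction: int, seed: int, spec_overrides: Optional[dict] = None
) -> DirectionalPeakFixture:
    n = n_per_direction
    spec = FixtureSpec(
        n1=2 * n, n2=2 * n, k=2 * n, n_genes=2 * n,
        n_up=n, n_down=n, bound_up=n, bound_down=n,
        seed=seed, **(spec_overrides or {}),
    )
    rng = np.random.default_rng(seed)
    genome = genome_for(spec)
    annotation = generate_gene_annotation(genome, 2 * n, seed=int(rng.integers(0, 2**31 - 1)))
    ids = annotation.gene_ids
    up, down = set(ids[:n]), set(ids[n:])
    directions = {g: "up" for g in up}
    directions.update({g: "down" for g in down})
    r1, r2, planted = generate_replicate_peaksets(
        spec, annotation, seed=int(rng.integers(0, 2**31 - 1)),
        gene_directions=directions,
    )
    hc, _ = intersect_peaksets(r1, r2)
    assert len(hc) == 2 * n
    return DirectionalPeakFixture(spec, annotation, hc, planted, up, down)


def positional_fixture(
    n_per_direction: int = 1_000, seed: int = DEFAULT_SEED
) -> DirectionalPeakFixture:
    """Peaks whose TSS-distance categories realize 14/23/63 (up) and 9/27/64 (down)."""
    return _directional_peaks(n_per_direction, seed)


def chromatin_fixture(
    n_per_direction: int = 1_000, seed: int = DEFAULT_SEED
) -> DirectionalPeakFixture:
    """Peaks plus DHS / cofactor region sets realizing the chromatin quotas.

    DHS overlap: 42% of induced-gene peaks, 69% of repressed-gene peaks.
    Cofactor overlap (nested inside the DHS subset): 32% and 53%.
    """
    fx = _directional_peaks(n_per_direction, seed)
    spec = fx.spec
    rng = np.random.default_rng(seed + 1)
    up_idx = [p.index for p in fx.planted if p.direction == "up"]
    down_idx = [p.index for p in fx.planted if p.direction == "down"]
    up_peaks = PeakSet(fx.peaks[i] for i in up_idx)
    down_peaks = PeakSet(fx.peaks[i] for i in down_idx)

    dhs_up = generate_region_set_with_quota(
        up_peaks, spec.dhs_quota_up, seed=int(rng.integers(0, 2**31 - 1))
    )
    dhs_down = generate_region_set_with_quota(
        down_peaks, spec.dhs_quota_down, seed=int(rng.integers(0, 2**31 - 1))
    )
    cf_up = generate_region_set_with_quota(
        up_peaks, spec.cofactor_quota_up, seed=int(rng.integers(0, 2**31 - 1)),
        nested_within=dhs_up,
    )
    cf_down = generate_region_set_with_quota(
        down_peaks, spec.cofactor_quota_down, seed=int(rng.integers(0, 2**31 - 1)),
        nested_within=dhs_down,
    )
    fx.dhs = RegionSet(list(dhs_up) + list(dhs_down))
    fx.cofactor = RegionSet(list(cf_up) + list(cf_down))
    return fx


def paired_height_fixture(
    n: int = 14_712, rho: float = 0.91, seed: int = DEFAULT_SEED
) -> tuple[np.ndarray, np.ndarray]:
    """Planted height pairs for the shared peaks at the study correlation."""
    return generate_paired_heights(n, rho, seed=seed)


def expression_fixture(
    n_probes: int = 20_000,
    n_up: int = 547,
    n_down: int = 551,
    effect: float = 2.0,
    sigma: float = 0.5,
    seed: int = DEFAULT_SEED,
) -> tuple[ExpressionTruth, pd.DataFrame, dict[str, str]]:
    """Planted expression truth plus its generated matrix and group map."""
    truth = ExpressionTruth.planted(n_probes, n_up, n_down, effect=effect, sigma=sigma)
    matrix, groups = generate_expression_matrix(truth, seed=seed)
    return truth, matrix, groups
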