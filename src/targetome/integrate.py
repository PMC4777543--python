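"""Join binding and regulation into the direct-target table ("targetome").

Two annotation passes are made deliberately and kept separate:

* pass (i) annotates high-confidence peaks to the nearest gene among ALL
  genes — this defines the bound-gene universe for the gene-level Venn;
* pass (ii) annotates the same peaks to the nearest REGULATED gene only —
  this drives the peak-level per-direction summaries (positional
  distribution, chromatin context), where a binding site is attributed to
  the regulated gene it most plausibly acts on.

A direct target is a regulated gene with at least one pass-(i) peak within
the distance cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .intervals import (
    GeneAnnotation,
    MAX_TSS_DISTANCE,
    PeakSet,
    POSITION_CLASSES,
    RegionSet,
    annotate_nearest_tss,
    overlap_fraction,
)
from .utils import counts_to_percent_triple, round_half_away

UNDEFINED = None  # marker for percentages with an empty denominator


class ReconciliationError(ValueError):
    """Regulated genes absent from the annotation (orphans are listed)."""


@dataclass
class Targetome:
    """Gene-level and peak-level join of binding and regulation."""

    gene_table: pd.DataFrame  # gene, direction, bound, peak_count
    peak_table: pd.DataFrame  # peak, gene, direction, position_class, signed_distance
    peaks: PeakSet = field(repr=False)
    bound_genes: set[str] = field(default_factory=set)
    up_genes: set[str] = field(default_factory=set)
    down_genes: set[str] = field(default_factory=set)

    @property
    def regulated_genes(self) -> set[str]:
        return self.up_genes | self.down_genes

    @property
    def direct_targets(self) -> set[str]:
        return self.regulated_genes & self.bound_genes


def build_targetome(
    hc_peaks: PeakSet,
    up_genes: set[str],
    down_genes: set[str],
    annotation: GeneAnnotation,
    max_dist: int = MAX_TSS_DISTANCE,
) -> Targetome:
    """Assemble the targetome from high-confidence peaks and DE gene sets."""
    known = set(annotation.gene_ids)
    orphans = sorted((up_genes | down_genes) - known)
    if orphans:
        raise ReconciliationError(
            f"{len(orphans)} regulated gene(s) missing from the annotation, "
            f"e.g. {orphans[:5]}"
        )
    direction_of = {g: "up" for g in up_genes}
    direction_of.update({g: "down" for g in down_genes})

    ann_all = annotate_nearest_tss(hc_peaks, annotation, max_dist=max_dist)
    regulated = up_genes | down_genes
    if regulated:
        ann_reg = annotate_nearest_tss(
            hc_peaks, annotation.subset(regulated), max_dist=max_dist
        )
    else:
        ann_reg = [None] * len(hc_peaks)

    bound_genes: set[str] = set()
    peak_counts: dict[str, int] = {}
    peak_rows = []
    for idx, (peak, a_all) in enumerate(zip(hc_peaks, ann_all)):
        if a_all.assigned:
            bound_genes.add(a_all.gene_id)
            peak_counts[a_all.gene_id] = peak_counts.get(a_all.gene_id, 0) + 1
        a_reg = ann_reg[idx]
        if a_reg is not None and a_reg.assigned:
            peak_rows.append(
                {
                    "peak": a_reg.peak_name,
                    "peak_index": idx,
                    "gene": a_reg.gene_id,
                    "direction": direction_of[a_reg.gene_id],
                    "signed_distance": a_reg.signed_distance,
                    "position_class": a_reg.position_class,
                }
            )
    peak_table = pd.DataFrame(
        peak_rows,
        columns=["peak", "peak_index", "gene", "direction", "signed_distance",
                 "position_class"],
    )

    gene_rows = []
    for g in sorted(bound_genes | regulated):
        gene_rows.append(
            {
                "gene": g,
                "direction": direction_of.get(g, "none"),
                "bound": g in bound_genes,
                "peak_count": peak_counts.get(g, 0),
            }
        )
    gene_table = pd.DataFrame(gene_rows, columns=["gene", "direction", "bound", "peak_count"])
    return Targetome(gene_table, peak_table, hc_peaks, bound_genes, set(up_genes), set(down_genes))


def _pct(numerator: int, denominator: int):
    if denominator == 0:
        return UNDEFINED
    return round_half_away(100.0 * numerator / denominator)


def summarize_binding_venn(t: Targetome) -> dict:
    """Gene-level Venn counts and headline percentages (Fig-1C-style).

    Percentages are integer-rounded half-away-from-zero; empty denominators
    yield an explicit undefined marker, never 0.
    """
    bound, regulated = t.bound_genes, t.regulated_genes
    both = bound & regulated
    both_up = bound & t.up_genes
    both_down = bound & t.down_genes
    return {
        "bound_genes": len(bound),
        "regulated_genes": len(regulated),
        "up_genes": len(t.up_genes),
        "down_genes": len(t.down_genes),
        "bound_only": len(bound - regulated),
        "regulated_only": len(regulated - bound),
        "both": len(both),
        "both_up": len(both_up),
        "both_down": len(both_down),
        "pct_regulated_among_bound": _pct(len(both), len(bound)),
        "pct_bound_among_regulated": _pct(len(both), len(regulated)),
        "pct_up_bound": _pct(len(both_up), len(t.up_genes)),
        "pct_down_bound": _pct(len(both_down), len(t.down_genes)),
    }


def summarize_distribution(t: Targetome) -> dict:
    """Per-direction positional percentage triples (proximal, distal up, distal down).

    Triples are largest-remainder reconciled so each sums to 100; a
    direction with zero peaks reports an undefined marker.
    """
    out: dict = {}
    for direction in ("up", "down"):
        sub = t.peak_table[t.peak_table["direction"] == direction]
        counts = [int((sub["position_class"] == c).sum()) for c in POSITION_CLASSES]
        n = sum(counts)
        out[direction] = {
            "n_peaks": n,
            "counts": dict(zip(POSITION_CLASSES, counts)),
            "percent": (
                dict(zip(POSITION_CLASSES, counts_to_percent_triple(counts)))
                if n > 0
                else UNDEFINED
            ),
        }
    return out


def summarize_chromatin_context(
    t: Targetome, dhs: RegionSet, cofactor: Optional[RegionSet] = None
) -> dict:
    """Per-direction DHS / cofactor overlap percentages and the 2x2 cross-tab.

    The cross-tab cell (non-DHS and cofactor) is the direct check of the
    nesting claim that cofactor-occupied binding sites lie inside
    accessible chromatin.
    """
    out: dict = {}
    for direction in ("up", "down"):
        sub = t.peak_table[t.peak_table["direction"] == direction]
        n = len(sub)
        if n == 0:
            out[direction] = {"n_peaks": 0, "pct_dhs": UNDEFINED,
                              "pct_non_dhs": UNDEFINED, "pct_cofactor": UNDEFINED,
                              "crosstab": UNDEFINED}
            continue
        subset = PeakSet(t.peaks[i] for i in sub["peak_index"])
        _, dhs_flags = overlap_fraction(subset, dhs)
        n_dhs = int(dhs_flags.sum())
        entry = {
            "n_peaks": n,
            "n_dhs": n_dhs,
            "pct_dhs": _pct(n_dhs, n),
            "pct_non_dhs": _pct(n - n_dhs, n),
        }
        if cofactor is not None:
            _, cf_flags = overlap_fraction(subset, cofactor)
            n_cf = int(cf_flags.sum())
            entry["n_cofactor"] = n_cf
            entry["pct_cofactor"] = _pct(n_cf, n)
            entry["crosstab"] = {
                "dhs_and_cofactor": int((dhs_flags & cf_flags).sum()),
                "dhs_only": int((dhs_flags & ~cf_flags).sum()),
                "cofactor_only": int((~dhs_flags & cf_flags).sum()),
                "neither": int((~dhs_flags & ~cf_flags).sum()),
            }
        out[direction] = entry
    return out
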