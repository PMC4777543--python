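# targetome

Cistrome–transcriptome integration for transcription-factor studies: turn
two replicate ChIP-seq peak lists plus a two-group expression experiment
into the factor's **direct-target gene set** ("targetome"), with positional
classification of binding sites, chromatin-context overlap summaries and
consensus-motif enrichment. A synthetic fixture generator plants every
set-overlap quantity exactly, so the whole pipeline is testable end to end
without any external download.

It is written for computational biologists who have peak calls (BED), a
TSS annotation, and a normalized expression matrix, and who want the
standard integration arithmetic done reproducibly:

* **Replicate concordance** — shared binding sites are peak intervals that
  overlap by ≥ 1 nucleotide; each replicate-1 peak with a mate becomes a
  *high-confidence* peak, and concordance is reported per replicate
  (shared / replicate size) together with the arithmetic mean, plus the
  Pearson *r* of paired peak heights.
* **Nearest-TSS annotation** — each peak (summit, else midpoint) is
  assigned to the nearest TSS within 100 kb; signed distances are
  strand-aware (negative = upstream) and classified as proximal (±1 kb),
  distal upstream (−100 kb to −1 kb) or distal downstream (+1 kb to
  +100 kb).
* **Rank-product differential expression** — for K = n_t × n_c pairwise
  treated/control comparisons, RP(g) = (∏ₖ rankₖ(g))^(1/K) with rank 1 the
  most changed probe in the requested direction; significance is a
  permutation-based proportion-of-false-positives (q-value), called at
  q ≤ 0.05.
* **Targetome join** — a *direct target* is a regulated gene with ≥ 1
  high-confidence peak within 100 kb of its TSS. Two annotation passes are
  kept separate: nearest gene among **all** genes (the bound-gene universe
  for the Venn summary) and nearest **regulated** gene (peak-level
  per-direction summaries).
* **Chromatin context** — overlap fractions of per-direction binding sites
  against a DNase-hypersensitivity (DHS) region set and a cofactor
  (ETS-factor) occupancy set, with the 2×2 DHS × cofactor cross-tab.
* **Motif enrichment** — exact IUPAC consensus scanning (both strands,
  overlapping hits counted) of 300 bp peak-center windows; enrichment z
  against per-window mononucleotide-shuffled backgrounds. The built-in
  library carries the NBRE (`AAAGGTCA`), the dimeric NurRE
  (`TGATATTT·N6·AAAGTCCA`) and generic ETS/RUNX cores.

## Worked example

Simulate a fixture bundle at 5 % of the default study scale and run the
full pipeline on it:

```bash
targetome all --outdir demo --seed 42 --scale 0.05
# shared peaks: 736; direct targets: 39
```

`demo/results/report.json` then contains (abridged):

```json
"concordance": {
  "shared": 736, "n_replicate1": 963, "n_replicate2": 1077,
  "concordance_replicate1": 0.7643, "concordance_replicate2": 0.6834,
  "mean_concordance": 0.7238, "height_r_2dp": 0.91
},
"differential_expression": {"n_up": 27, "n_down": 32, "q_threshold": 0.05},
"targetome": {
  "venn": {"bound_genes": 349, "regulated_genes": 59, "both": 39,
           "pct_regulated_among_bound": 11, "pct_bound_among_regulated": 66}
}
```

Reading: of 963 and 1,077 replicate peaks, 736 replicate-concordant
binding sites survive (76 % / 68 % of each replicate; planted height
correlation 0.91 is recovered). Rank product calls 27 induced and 32
repressed genes at q ≤ 0.05; 39 regulated genes carry a binding site
within 100 kb and form the direct-target set — 11 % of all bound genes,
66 % of regulated ones. The motif section ranks the NBRE first in the
categories where it was planted (z ≈ 31) and near z ≈ 0 elsewhere.

The same stages are available individually (`targetome simulate`,
`intersect`, `de`, `targetome`, `motifs`, `report`) on your own BED/TSV
inputs; `report --config run.txt` accepts a key–value config file whose
entries mirror the flags.

## Library use

```python
from targetome import intersect_peaksets, annotate_nearest_tss, build_targetome
from targetome.fixtures import replicate_fixture

fx = replicate_fixture(seed=42)                     # full-scale planted scenario
hc, conc = intersect_peaksets(fx.replicate1, fx.replicate2)
t = build_targetome(hc, fx.up_genes, fx.down_genes, fx.annotation)
print(conc.shared, len(t.direct_targets))           # 14712 685
```

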