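# Methods

This note documents the models, conventions and design choices behind the
package; nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate and overlap conventions

All intervals are 0-based half-open (BED). Two regions *overlap* iff they
lie on the same chromosome and share at least one nucleotide
(`max(starts) < min(ends)`); abutting intervals do not overlap. Replicate
intersection keeps the **replicate-1 interval** as the high-confidence
peak (not the intersection or union), which preserves native peak widths
for window extraction; each replicate-1 peak is counted once and paired
with its largest-overlap replicate-2 mate (ties → leftmost mate).

Because "concordance" has an ambiguous denominator, the report carries
both per-replicate fractions (shared / replicate size) *and* their
arithmetic mean, rather than picking one silently.

## Nearest-TSS annotation and positional classes

The peak reference point is the summit if present, else the floor
midpoint. The nearest gene is chosen by absolute genomic distance to the
TSS; equidistant candidates resolve to the lexicographically smaller gene
identifier (a deterministic, documented tie-break). Peaks farther than
100 kb (configurable `max_tss_distance`) are unassigned. Signed distances
are strand-aware: negative means upstream in the gene's reading
orientation. Positional classes partition [−100 kb, +100 kb]: proximal
|d| ≤ 1 kb with both boundaries inclusive, distal upstream
−100 kb ≤ d < −1 kb, distal downstream +1 kb < d ≤ +100 kb.

The targetome join makes two annotation passes on purpose: pass (i)
against **all** genes defines the bound-gene universe for the gene-level
Venn summary; pass (ii) against **regulated genes only** drives the
peak-level per-direction summaries, where each binding site is attributed
to the regulated gene it most plausibly acts on. Conflating the two would
distort either the universe or the attribution; both are computed and
labelled. A *direct target* is a regulated gene with ≥ 1 pass-(i) peak
within the cutoff.

Headline percentages are integer-rounded half-away-from-zero; positional
triples are reconciled by largest remainder so each triple sums to 100.
Empty denominators report an explicit undefined marker (JSON `null`),
never 0.

Peak heights are correlated on the raw height scale (Pearson product-
moment); the synthetic generator plants its correlation on the same
scale, so the convention is self-consistent.

## Rank-product differential expression

For n_c control and n_t treated samples, every treated/control pair gives
a per-probe log fold change; within each of the K = n_t·n_c comparisons
probes are ranked (rank 1 = most changed in the requested direction, ties
averaged), and RP = (∏ ranks)^(1/K). RP is invariant to adding a constant
to a probe's samples and to permuting sample order within a group.

**q-values (proportion of false positives).** The null models an
exchangeable no-effect probe *inserted into the observed experiment*:

1. within-group residuals are computed and rescaled by
   √(n_g / (n_g − 1)) to undo the variance shrinkage of group centering;
2. each sample column of the residual matrix is permuted independently
   across probes, giving synthetic noise probes whose K pairwise
   comparisons share replicate values — and are therefore correlated —
   exactly like real probes;
3. each synthetic probe's fold changes are ranked against the **observed**
   fold-change columns, and its RP recorded; this repeats `permutations`
   times (default 100, minimum 20).

For the probe at ascending-RP position *i*, q = E[null RP ≤ RPᵢ] / i,
monotonized by a running maximum so threshold sets are nested, and clipped
to [0, 1] for reporting. Calls are made at q ≤ 0.05, with the probe→gene
collapse keeping each gene's best q.

Two simpler nulls were considered and rejected, for measurable reasons.
Permuting fold-change columns independently ignores the shared-replicate
correlation among the K comparisons and is anti-conservative (correlated
noise probes reach low RP far more often than independent columns
suggest). Ranking permuted noise rows *within a signal-free permuted
matrix* is badly conservative whenever a sizeable fraction of probes
carries real signal: in the permuted matrix a noise row can reach rank 1,
while in the real data the signal block occupies the top ranks and
shields them from null probes. The insertion null keeps both the
correlation and the competition, and on null-only data its false-call
fraction stays at or below the nominal level (checked in the test suite).

## Synthetic fixtures

The generators plant every quantity **exactly**, so downstream counting
operations are testable against integers:

* **Genes** are laid out with ≥ 300 kb TSS spacing — more than twice the
  100 kb cutoff plus peak widths — so every planted peak has a unique,
  provably recoverable nearest gene. Replicate-unique peaks live on a
  dedicated peak-only chromosome and can never collide with gene
  neighborhoods.
* **Replicate peak sets** share exactly *k* anchor pairs: both replicate
  peaks are jittered copies of an anchor with jitter ≤ ¼ peak width, which
  guarantees ≥ 1 bp overlap while keeping the intervals distinct (the
  intersection logic is exercised non-trivially). The first *g* shared
  peaks map onto distinct genes, the remainder revisit random genes, so
  the shared set covers exactly *g* unique genes. Planted TSS distances
  are drawn inside their positional category with a jitter-proof margin,
  so the realized class always equals the planted one; same-gene peaks
  keep their centers far enough apart to stay disjoint. If a narrow
  category is exhausted at one gene (many peaks on one gene), the
  generator falls back to a roomier category and records the realized
  class in the truth map.
* **Quota region sets** overlap exactly round(fraction·n/100) target
  peaks: regions are placed strictly inside chosen peaks (targets must be
  pairwise disjoint; verified by a post-check) so no other peak is
  touched. Nesting draws the chosen subset only from peaks overlapped by
  the parent set — the construction that makes cofactor-occupied sites a
  subset of accessible (DHS) sites, and the (non-DHS ∧ cofactor) cross-tab
  cell identically zero.
* **Paired heights** come from a bivariate normal (mean 200, sd 40) with
  the requested correlation on the raw scale, floored at zero (the floor
  is ~5 sd away and effectively never binds); ρ = 1 yields exactly
  collinear pairs.
* **Expression matrices** are baseline 8 + effect·(treated indicator) +
  N(0, σ²) — already-normalized log-scale values; the default study
  conditions plant 547 up and 551 down probes among 20,000 with |effect|
  = 2, σ = 0.5 and 3 vs 3 replicates.
* **Motif windows** are 300 bp i.i.d. uniform backgrounds
  rejection-resampled until they carry no accidental motif hit; planted
  consensus occurrences (degenerate positions concretized at random) are
  inserted at non-overlapping offsets on a random strand, and a window is
  redrawn if insertion junctions create extra hits — the scan count equals
  the planted count exactly.

Quota percentages that are not integral at the requested n are resolved by
largest remainder with a warning. All generators are deterministic per
seed (default 42) and byte-identical across re-runs.

**Default planted scenario.** The full-scale replicate fixture uses
19,266 and 21,536 replicate peaks sharing 14,712 over 6,984 unique genes;
547 up- and 551 down-regulated genes of which 432 and 253 are bound,
giving a 685-gene direct-target set (62 % of regulated genes, ~10 % of
bound genes, 79 % of up-regulated genes). The per-direction split was
chosen to satisfy the total (685), the overall bound-among-regulated
fraction (62 %) and the up-direction fraction (79 %) simultaneously; no
allocation can also realize a 54 % down-direction fraction
(0.79·547 + 0.54·551 ≈ 730 ≠ 685), so the implied down fraction here is
46 %. Positional quotas are 14/23/63 (induced) and 9/27/64 (repressed);
DHS quotas 42 % (induced; i.e. 58 % non-DHS) and 69 % (repressed);
cofactor quotas 32 % and 53 %, nested in DHS. The height correlation is
ρ = 0.91 over the shared peaks.

**What the fixtures do and do not emulate.** They reproduce set-overlap
structure, planted effect sizes and planted correlations — which is what
the integration arithmetic consumes. They do not emulate read-level
artifacts, peak-shape or width variation, clustered regulatory regions,
probe–gene multiplicity, heteroscedastic array noise, or correlated genes;
passing tests therefore validate the *pipeline arithmetic and statistics*,
not robustness to those real-data properties.

## Motif scanning and enrichment

Motifs are IUPAC consensus strings; dimeric elements carry an explicit
N-run spacer. Scanning is exact matching via overlapping-window regex on
both strands (the reverse-complement pattern is scanned on the forward
strand); a locus matching both strands counts once. There is no PWM or
energy model — exactness keeps fixtures deterministic, at the cost of
ignoring near-matches.

Enrichment z compares a category's total occurrence count with
per-window mononucleotide-shuffled backgrounds (each shuffle is an exact
permutation of the window, preserving base composition); a dinucleotide
shuffle (random Eulerian-walk with rejection) is available as an option.
With `shuffles` background replicates (default 100 in the library API,
minimum 20), z = (observed − mean)/sd; a degenerate background (sd = 0)
reports a signed-infinity sentinel, or 0 when observed equals the
constant background. Motif ranking sorts by descending z, ties by
observed count then name. The z-scores are descriptive enrichment
statistics, not calibrated p-values.

The built-in library: NBRE `AAAGGTCA` (monomeric element), NurRE
`TGATATTT` + N6 + `AAAGTCCA` (dimeric element), ETS core `GGAW`, RUNX
core `TGYGGT`. The ETS and RUNX entries are generic family cores, chosen
as standard consensus forms rather than dataset-specific matrices.

## Problem sizes and determinism

The default test suite and the acceptance script run the full planted
scale — 19,266 + 21,536 peaks, 20,000 probes × 6 samples with 100
permutations, 1,000 peaks per direction, 500 motif windows — in well
under a minute on one CPU; smaller scales (`scale` parameters throughout)
exist for interactive use. Every stochastic component takes an explicit
seed; the pipeline report embeds the config digest, seed and package
version for provenance.

## Known limitations

* The q-value is a permutation pfp estimate; with few permutations its
  granularity is 1/permutations, hence the enforced minimum of 20.
* `intersect_peaksets` is asymmetric by design (replicate 1 is the
  reference); swapping inputs changes which intervals are reported,
  though the shared count is symmetric for typical (non-chained) peak
  geometries.
* Probe→gene mapping is identity unless a mapping is supplied; many-to-one
  collapse keeps the best q and ignores probe-level disagreement.
* The motif arm treats windows as unrelated sequences; genomic context
  (GC isochores, repeats) is not modelled beyond the shuffle background.
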