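"""Consensus-motif scanning of peak-center windows and shuffle-based enrichment.

Motifs are IUPAC consensus strings (a dimeric response element is written
with an explicit N-run spacer, e.g. ``TGATATTTNNNNNNAAAGTCCA``).  Scanning
is exact IUPAC matching on both strands; enrichment is a z-score of the
observed occurrence total against per-window mononucleotide-shuffled
backgrounds, which preserve each window's base composition exactly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

WINDOW_WIDTH = 300

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass(frozen=True)
class Motif:
    """A named IUPAC consensus."""

    name: str
    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("consensus must be non-empty")
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC letters in consensus: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.consensus)

    @property
    def pattern(self) -> str:
        return self.consensus.upper()


def default_motif_library() -> list[Motif]:
    """Built-in consensus library.

    NBRE is the monomeric NGFI-B response element; NurRE is the dimeric
    element written as two half-sites around a 6-base unspecified spacer.
    The ETS (GGAW) and RUNX (TGYGGT) entries are standard family core
    consensuses, not sequences specific to any one dataset.
    """
    return [
        Motif("NBRE", "AAAGGTCA"),
        Motif("NurRE", "TGATATTT" + "N" * 6 + "AAAGTCCA"),
        Motif("ETS", "GGAW"),
        Motif("RUNX", "TGYGGT"),
    ]


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for b in pattern:
        opts = IUPAC[b]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    # lookahead so overlapping occurrences are all counted
    return re.compile(r"(?=" + "".join(parts) + r")")


def _match_positions(seq: str, pattern: str) -> set[int]:
    return {m.start() for m in _iupac_regex(pattern).finditer(seq)}


def scan_consensus(window: str, motif: Motif) -> int:
    """Count exact IUPAC matches of ``motif`` in ``window`` on both strands.

    Overlapping matches count separately; a locus matching on both strands
    (a self-reverse-complementary hit) counts once.  Window letters are
    taken literally, so an ambiguous window base (N) matches only a
    consensus position that itself allows N.
    """
    seq = window.upper()
    fwd = motif.pattern
    rev = reverse_complement(fwd)
    hits = _match_positions(seq, fwd)
    if rev != fwd:
        hits |= _match_positions(seq, rev)
    return len(hits)


@dataclass
class Window:
    """One peak-centered sequence window with its (direction, position) category."""

    name: str
    sequence: str
    category: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"window alphabet must be ACGTN, found {sorted(bad)}")


class WindowSet:
    """A collection of fixed-width windows grouped by category label."""

    def __init__(self, windows: Iterable[Window] = (), width: int = WINDOW_WIDTH):
        self.windows: list[Window] = list(windows)
        self.width = width
        for w in self.windows:
            if len(w.sequence) != width:
                raise ValueError(
                    f"window {w.name!r} has length {len(w.sequence)}, expected {width}"
                )

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def categories(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.windows:
            seen.setdefault(w.category, None)
        return list(seen)

    def by_category(self, category: str) -> list[Window]:
        return [w for w in self.windows if w.category == category]


def extract_windows(
    peaks,
    genome: Mapping[str, str],
    width: int = WINDOW_WIDTH,
    categories: Optional[Sequence[str]] = None,
) -> WindowSet:
    """Cut ``width``-bp windows centered on each peak's reference point.

    ``genome`` maps chromosome name to sequence (a dict or a pyfaidx.Fasta
    both work).  Windows that would run off a chromosome end are dropped
    with a logged warning.  A peak on a chromosome absent from ``genome``
    is an error naming the chromosome.
    """
    half = width // 2
    out: list[Window] = []
    dropped = 0
    for i, p in enumerate(peaks):
        chrom = p.interval.chrom
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} missing from genome sequence source")
        seq = genome[chrom]
        chrom_len = len(seq)
        center = p.reference_point
        lo, hi = center - half, center + half
        if lo < 0 or hi > chrom_len:
            dropped += 1
            continue
        cat = categories[i] if categories is not None else ""
        out.append(Window(p.name or f"peak_{i}", str(seq[lo:hi]).upper(), cat))
    if dropped:
        logger.warning("dropped %d window(s) clipped at chromosome edges", dropped)
    return WindowSet(out, width=width)


@dataclass
class EnrichmentResult:
    motif: str
    category: str
    observed: int
    background_mean: float
    background_sd: float
    z: float
    n_windows: int


def shuffle_window(seq: str, rng: np.random.Generator) -> str:
    """Mononucleotide shuffle: a uniformly random permutation of the window."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    return b"".join(rng.permutation(arr)).decode()


def _dinucleotide_shuffle(
    seq: str, rng: np.random.Generator, max_tries: int = 1000
) -> str:
    """Shuffle preserving dinucleotide composition (random Eulerian walk).

    Exposed as an alternative background; the default is the mononucleotide
    shuffle.  Successor lists of the dinucleotide multigraph are permuted
    and the walk replayed; orderings that strand the walk before consuming
    every edge are rejected and redrawn.
    """
    from collections import defaultdict

    s = seq.upper()
    if len(s) < 3:
        return s
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    n_edges = len(s) - 1
    for _ in range(max_tries):
        succ = {k: [v[i] for i in rng.permutation(len(v))] for k, v in edges.items()}
        counts = {k: 0 for k in succ}
        out = [s[0]]
        cur = s[0]
        ok = True
        for _ in range(n_edges):
            lst = succ.get(cur, ())
            if counts.get(cur, 0) >= len(lst):
                ok = False
                break
            out.append(lst[counts[cur]])
            counts[cur] += 1
            cur = out[-1]
        if ok:
            return "".join(out)
    raise RuntimeError("dinucleotide shuffle failed to find a complete Eulerian walk")


def enrichment_z(
    windows: WindowSet,
    motif: Motif,
    shuffles: int = 100,
    seed: Optional[int] = None,
    background: str = "mono",
) -> dict[str, EnrichmentResult]:
    """Per-category enrichment z of observed occurrence totals vs shuffled windows.

    For each category: observed = total motif occurrences over its windows;
    the background replicates shuffle every window independently and rescan,
    ``shuffles`` times; z = (observed - mean_bg) / sd_bg.  A degenerate
    background (sd 0) reports a signed-infinity sentinel (or 0 when the
    observed count equals the constant background).
    """
    if shuffles < 20:
        raise ValueError("at least 20 shuffles are required for a usable background")
    if background not in ("mono", "di"):
        raise ValueError("background must be 'mono' or 'di'")
    rng = np.random.default_rng(seed)
    shuffler = shuffle_window if background == "mono" else _dinucleotide_shuffle
    results: dict[str, EnrichmentResult] = {}
    for cat in windows.categories():
        group = windows.by_category(cat)
        if not group:
            continue
        observed = sum(scan_consensus(w.sequence, motif) for w in group)
        bg = np.empty(shuffles)
        for s in range(shuffles):
            bg[s] = sum(scan_consensus(shuffler(w.sequence, rng), motif) for w in group)
        mean, sd = float(bg.mean()), float(bg.std(ddof=1))
        if sd == 0.0:
            if observed == mean:
                z = 0.0
            else:
                z = float("inf") if observed > mean else float("-inf")
        else:
            z = (observed - mean) / sd
        results[cat] = EnrichmentResult(
            motif.name, cat, observed, mean, sd, z, len(group)
        )
    return results


def rank_motifs(
    windows: WindowSet,
    library: Sequence[Motif],
    shuffles: int = 100,
    seed: Optional[int] = None,
) -> dict[str, list[EnrichmentResult]]:
    """Rank a motif library by enrichment within each window category.

    Sorting is by descending z, ties by observed count then motif name.
    Categories with no windows are omitted with a logged notice.
    """
    if not library:
        raise ValueError("motif library must be non-empty")
    per_cat: dict[str, list[EnrichmentResult]] = {}
    rng = np.random.default_rng(seed)
    for motif in library:
        sub = int(rng.integers(0, 2**31 - 1))
        for cat, res in enrichment_z(windows, motif, shuffles=shuffles, seed=sub).items():
            per_cat.setdefault(cat, []).append(res)
    for cat in windows.categories():
        if cat not in per_cat:
            logger.info("category %r has no windows; omitted from motif ranking", cat)
    for cat, rows in per_cat.items():
        rows.sort(key=lambda r: (-r.z, -r.observed, r.motif))
    return per_cat
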