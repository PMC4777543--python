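"""Readers and writers for the pipeline's plain-text exchange formats.

Peaks travel as BED6 (0-based half-open; the score column carries the peak
height), gene annotations as a 4-column TSV (gene, chrom, tss, strand),
expression as a TSV matrix with a 2-column sample->group sidecar, motif
windows as FASTA, and reports/truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .intervals import Gene, GeneAnnotation, GenomicInterval, Peak, PeakSet, RegionSet
from .motifs import Motif, Window, WindowSet

PathLike = Union[str, Path]


def write_bed(peaks: PeakSet, path: PathLike) -> None:
    rows = []
    for i, p in enumerate(peaks):
        rows.append(
            (p.interval.chrom, p.interval.start, p.interval.end,
             p.name or f"peak_{i}", p.height, ".")
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: PathLike) -> PeakSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    peaks = []
    for i, row in enumerate(df.itertuples(index=False)):
        name = str(row[3]) if len(row) > 3 else f"peak_{i}"
        height = float(row[4]) if len(row) > 4 else 0.0
        peaks.append(Peak(GenomicInterval(str(row[0]), int(row[1]), int(row[2])),
                          height, name=name))
    return PeakSet(peaks)


def write_regions_bed(regions: RegionSet, path: PathLike) -> None:
    rows = [(iv.chrom, iv.start, iv.end) for iv in regions]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_regions_bed(path: PathLike) -> RegionSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return RegionSet(
        GenomicInterval(str(r[0]), int(r[1]), int(r[2]))
        for r in df.itertuples(index=False)
    )


def write_annotation(annotation: GeneAnnotation, path: PathLike) -> None:
    rows = [(g.gene_id, g.chrom, g.tss, g.strand) for g in annotation]
    pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotation(path: PathLike) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t")
    return GeneAnnotation(
        Gene(str(r.gene), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples(index=False)
    )


def write_expression(matrix: pd.DataFrame, groups: Mapping[str, str],
                     matrix_path: PathLike, groups_path: PathLike) -> None:
    matrix.to_csv(matrix_path, sep="\t", index_label="probe")
    pd.DataFrame(sorted(groups.items()), columns=["sample", "group"]).to_csv(
        groups_path, sep="\t", index=False
    )


def read_expression(matrix_path: PathLike, groups_path: PathLike
                    ) -> tuple[pd.DataFrame, dict[str, str]]:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col="probe")
    gdf = pd.read_csv(groups_path, sep="\t")
    return matrix, dict(zip(gdf["sample"].astype(str), gdf["group"].astype(str)))


def write_fasta(records: Sequence[tuple[str, str]], path: PathLike,
                line_width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def read_windows_fasta(path: PathLike, width: int = 300) -> WindowSet:
    """Read peak windows from FASTA; a ``category=...`` token in the header
    (if present) becomes the window's category label."""
    windows = []
    name, cat, chunks = None, "", []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    windows.append(Window(name, "".join(chunks), cat))
                fields = line[1:].split()
                name = fields[0]
                cat = ""
                for tok in fields[1:]:
                    if tok.startswith("category="):
                        cat = tok.split("=", 1)[1]
                chunks = []
            else:
                chunks.append(line.strip())
    if name is not None:
        windows.append(Window(name, "".join(chunks), cat))
    return WindowSet(windows, width=width)


def load_genome(path: PathLike):
    """Open a genome FASTA as a chromosome-name -> sequence mapping (pyfaidx)."""
    from pyfaidx import Fasta

    return Fasta(str(path))


def read_motif_library(path: PathLike) -> list[Motif]:
    df = pd.read_csv(path, sep="\t")
    return [Motif(str(r.name), str(r.consensus)) for r in df.itertuples(index=False)]


def write_motif_library(library: Sequence[Motif], path: PathLike) -> None:
    pd.DataFrame([(m.name, m.consensus) for m in library],
                 columns=["name", "consensus"]).to_csv(path, sep="\t", index=False)


def write_json(obj, path: PathLike) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def read_json(path: PathLike):
    return json.loads(Path(path).read_text())


def write_keyvalue(pairs: Mapping[str, object], path: PathLike) -> None:
    with open(path, "w") as fh:
        for k, v in pairs.items():
            fh.write(f"{k} = {v}\n")


def read_keyvalue(path: PathLike) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed key-value line: {line!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out
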