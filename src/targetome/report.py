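"""Pipeline assembly: configuration, fixture simulation, stage execution, report.

``run_simulate`` writes a complete fixture bundle (peaks, annotation,
region sets, expression matrix, motif windows and the planted-truth JSON)
to disk; ``run_pipeline`` executes intersect -> DE -> annotate ->
targetome -> motifs on any conforming inputs and assembles the
figure-level summary report with a provenance block.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from . import io
from .diffexpr import DEFAULT_PERMUTATIONS, ExpressionMatrix, Q_THRESHOLD, call_de, de_table
from .fixtures import chromatin_fixture, positional_fixture, replicate_fixture
from .integrate import (
    build_targetome,
    summarize_binding_venn,
    summarize_chromatin_context,
    summarize_distribution,
)
from .intervals import MAX_TSS_DISTANCE, height_correlation, intersect_peaksets
from .motifs import WINDOW_WIDTH, default_motif_library, extract_windows, rank_motifs
from .synthetic import ExpressionTruth, generate_expression_matrix, generate_sequences

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """Wraps a stage failure with the stage name for actionable CLI errors."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Input paths and thresholds for a pipeline run.

    Any unset optional input simply skips its section of the report.
    """

    peaks1: Optional[str] = None
    peaks2: Optional[str] = None
    annotation: Optional[str] = None
    expression: Optional[str] = None
    groups: Optional[str] = None
    dhs: Optional[str] = None
    cofactor: Optional[str] = None
    windows_fasta: Optional[str] = None
    genome_fasta: Optional[str] = None
    motif_library: Optional[str] = None
    outdir: str = "targetome_out"
    max_tss_distance: int = MAX_TSS_DISTANCE
    q_threshold: float = Q_THRESHOLD
    window_width: int = WINDOW_WIDTH
    permutations: int = DEFAULT_PERMUTATIONS
    motif_shuffles: int = 50
    seed: int = 42

    def __post_init__(self) -> None:
        if self.max_tss_distance <= 0 or self.window_width <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 <= self.q_threshold <= 1:
            raise ValueError("q threshold must lie in [0, 1]")

    @classmethod
    def from_file(cls, path, overrides: Optional[dict] = None) -> "RunConfig":
        raw = io.read_keyvalue(path)
        raw.update({k: v for k, v in (overrides or {}).items() if v is not None})
        kwargs: dict = {}
        for f in cls.__dataclass_fields__.values():  # type: ignore[attr-defined]
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.type.startswith("int") or f.name in ("max_tss_distance", "window_width",
                                                      "permutations", "motif_shuffles",
                                                      "seed"):
                kwargs[f.name] = int(v)
            elif f.name == "q_threshold":
                kwargs[f.name] = float(v)
            else:
                kwargs[f.name] = str(v)
        return cls(**kwargs)

    def digest(self) -> str:
        payload = "\n".join(f"{k}={v}" for k, v in sorted(asdict(self).items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_simulate(outdir, seed: int = 42, scale: float = 1.0,
                 n_positional: int = 1_000, n_expression_probes: int = 20_000,
                 windows_per_category: int = 60) -> dict:
    """Write the full fixture bundle; returns the manifest of written files.

    Re-running with the same seed reproduces every file byte-identically.
    ``scale`` shrinks the replicate scenario for quick runs.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "files": {}}
    rel_files: dict[str, str] = {}

    def _write(key: str, path: Path):
        manifest["files"][key] = str(path)
        rel_files[key] = str(path.relative_to(out))
        return path

    # replicate / Venn scenario
    fx = replicate_fixture(seed=seed, scale=scale)
    d = out / "replicates"
    d.mkdir(exist_ok=True)
    io.write_bed(fx.replicate1, _write("replicate1", d / "replicate1.bed"))
    io.write_bed(fx.replicate2, _write("replicate2", d / "replicate2.bed"))
    io.write_annotation(fx.annotation, _write("annotation", d / "annotation.tsv"))
    io.write_json(
        {
            "up_genes": sorted(fx.up_genes),
            "down_genes": sorted(fx.down_genes),
            "planted_peaks": [
                {"index": p.index, "gene": p.gene_id, "direction": p.direction,
                 "category": p.category, "signed_distance": p.signed_distance}
                for p in fx.planted
            ],
        },
        _write("replicate_truth", d / "truth.json"),
    )
    io.write_keyvalue(asdict(fx.spec), _write("replicate_spec", d / "spec.txt"))

    # positional-distribution scenario
    pfx = positional_fixture(n_per_direction=n_positional, seed=seed)
    d = out / "positional"
    d.mkdir(exist_ok=True)
    io.write_bed(pfx.peaks, _write("positional_peaks", d / "peaks.bed"))
    io.write_annotation(pfx.annotation, _write("positional_annotation", d / "annotation.tsv"))
    io.write_json(
        {"up_genes": sorted(pfx.up_genes), "down_genes": sorted(pfx.down_genes)},
        _write("positional_truth", d / "truth.json"),
    )

    # chromatin-context scenario
    cfx = chromatin_fixture(n_per_direction=n_positional, seed=seed)
    d = out / "chromatin"
    d.mkdir(exist_ok=True)
    io.write_bed(cfx.peaks, _write("chromatin_peaks", d / "peaks.bed"))
    io.write_annotation(cfx.annotation, _write("chromatin_annotation", d / "annotation.tsv"))
    io.write_regions_bed(cfx.dhs, _write("dhs", d / "dhs.bed"))
    io.write_regions_bed(cfx.cofactor, _write("cofactor", d / "cofactor.bed"))
    io.write_json(
        {"up_genes": sorted(cfx.up_genes), "down_genes": sorted(cfx.down_genes)},
        _write("chromatin_truth", d / "truth.json"),
    )

    # expression scenario: probes are the fixture's gene ids, effects planted
    # on the regulated genes, everything else null
    ids = fx.annotation.gene_ids
    directions = fx.gene_directions
    effects = np.array([
        2.0 if directions.get(g) == "up" else -2.0 if directions.get(g) == "down" else 0.0
        for g in ids
    ])
    labels = [directions.get(g, "null") for g in ids]
    truth = ExpressionTruth(list(ids), effects, labels, sigma=0.5)
    matrix, groups = generate_expression_matrix(truth, seed=seed)
    d = out / "expression"
    d.mkdir(exist_ok=True)
    io.write_expression(matrix, groups, _write("expression_matrix", d / "matrix.tsv"),
                        _write("expression_groups", d / "groups.tsv"))
    io.write_json(
        {"up_probes": sorted(truth.up_probes), "down_probes": sorted(truth.down_probes),
         "sigma": truth.sigma},
        _write("expression_truth", d / "truth.json"),
    )

    # motif windows: NBRE planted in 30% of windows per category
    library = default_motif_library()
    nbre = library[0]
    rng = np.random.default_rng(seed)
    records = []
    plant_quota = {"up_distal_upstream": 0.30, "down_distal_upstream": 0.30,
                   "up_proximal": 0.0}
    truth_counts: dict[str, int] = {}
    for cat, rate in plant_quota.items():
        n_planted = int(round(windows_per_category * rate))
        counts = [1] * n_planted + [0] * (windows_per_category - n_planted)
        names = [f"{cat}_{i:03d} category={cat}" for i in range(windows_per_category)]
        records.extend(
            generate_sequences(names, counts, nbre, seed=int(rng.integers(0, 2**31 - 1)))
        )
        truth_counts[cat] = n_planted
    d = out / "motifs"
    d.mkdir(exist_ok=True)
    io.write_fasta(records, _write("windows", d / "windows.fa"))
    io.write_motif_library(library, _write("motif_library", d / "library.tsv"))
    io.write_json({"planted_windows_per_category": truth_counts, "motif": nbre.name},
                  _write("motif_truth", d / "truth.json"))

    # on-disk manifest keeps paths relative to the bundle, so identical seeds
    # give byte-identical bundles wherever they are written
    io.write_json({"seed": seed, "files": rel_files}, out / "manifest.json")
    return manifest


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage and write the assembled report.

    Required inputs: the two replicate peak lists and the gene annotation.
    Expression, chromatin and motif inputs are optional; their sections are
    marked ``skipped`` when absent.  Any stage failure aborts with the
    stage name and the offending context.
    """
    if not (config.peaks1 and config.peaks2 and config.annotation):
        raise ValueError("peaks1, peaks2 and annotation are required inputs")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "package_version": __version__,
            "config_digest": config.digest(),
            "seed": config.seed,
            "config": asdict(config),
        }
    }

    @_stage("intersect")
    def _intersect():
        r1 = io.read_bed(config.peaks1)
        r2 = io.read_bed(config.peaks2)
        if len(r1) == 0 or len(r2) == 0:
            raise ValueError("replicate peak files must be non-empty")
        hc, conc = intersect_peaksets(r1, r2)
        h1 = [r1[i].height for i, _ in conc.pairs]
        h2 = [r2[j].height for _, j in conc.pairs]
        section = conc.to_dict()
        if len(h1) >= 3:
            r_full, r_2dp = height_correlation(h1, h2)
            section["height_r"] = r_full
            section["height_r_2dp"] = r_2dp
        return hc, section

    hc_peaks, report["concordance"] = _intersect()

    @_stage("differential_expression")
    def _de():
        matrix_df, groups = io.read_expression(config.expression, config.groups)
        matrix = ExpressionMatrix.from_groups(matrix_df, groups)
        table = de_table(matrix, permutations=config.permutations,
                         seed=config.seed, threshold=config.q_threshold)
        up, down = call_de(table, threshold=config.q_threshold)
        table.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
        return up, down, {"n_up": len(up), "n_down": len(down),
                          "q_threshold": config.q_threshold,
                          "permutations": config.permutations}

    if config.expression and config.groups:
        up_genes, down_genes, report["differential_expression"] = _de()
    else:
        up_genes, down_genes = set(), set()
        report["differential_expression"] = {"skipped": True}

    @_stage("targetome")
    def _targetome():
        annotation = io.read_annotation(config.annotation)
        t = build_targetome(hc_peaks, up_genes, down_genes, annotation,
                            max_dist=config.max_tss_distance)
        t.gene_table.to_csv(outdir / "targetome_genes.tsv", sep="\t", index=False)
        t.peak_table.to_csv(outdir / "targetome_peaks.tsv", sep="\t", index=False)
        section = {
            "n_direct_targets": len(t.direct_targets),
            "venn": summarize_binding_venn(t),
            "distribution": summarize_distribution(t),
        }
        return t, section

    targetome_obj, report["targetome"] = _targetome()

    @_stage("chromatin_context")
    def _chromatin():
        dhs = io.read_regions_bed(config.dhs)
        cofactor = io.read_regions_bed(config.cofactor) if config.cofactor else None
        return summarize_chromatin_context(targetome_obj, dhs, cofactor)

    if config.dhs:
        report["chromatin_context"] = _chromatin()
    else:
        report["chromatin_context"] = {"skipped": True}
        logger.info("no DHS input; chromatin-context section skipped")

    @_stage("motifs")
    def _motifs():
        if config.windows_fasta:
            windows = io.read_windows_fasta(config.windows_fasta,
                                            width=config.window_width)
        else:
            # cut windows around the peaks attributed to regulated genes,
            # labelled by direction x positional class
            genome = io.load_genome(config.genome_fasta)
            pt = targetome_obj.peak_table
            from .intervals import PeakSet as _PeakSet

            subset = _PeakSet(targetome_obj.peaks[i] for i in pt["peak_index"])
            cats = [f"{d}_{c}" for d, c in zip(pt["direction"], pt["position_class"])]
            windows = extract_windows(subset, genome, width=config.window_width,
                                      categories=cats)
        library = (io.read_motif_library(config.motif_library)
                   if config.motif_library else default_motif_library())
        ranked = rank_motifs(windows, library, shuffles=config.motif_shuffles,
                             seed=config.seed)
        rows_flat = [
            {"category": cat, "motif": r.motif, "z": r.z, "observed": r.observed,
             "background_mean": r.background_mean, "n_windows": r.n_windows}
            for cat, rows in ranked.items() for r in rows
        ]
        import pandas as pd

        pd.DataFrame(rows_flat).to_csv(outdir / "motif_enrichment.tsv",
                                       sep="\t", index=False)
        return {
            cat: [
                {"motif": r.motif, "z": r.z, "observed": r.observed,
                 "background_mean": r.background_mean, "n_windows": r.n_windows}
                for r in rows
            ]
            for cat, rows in ranked.items()
        }

    if config.windows_fasta or config.genome_fasta:
        report["motifs"] = _motifs()
    else:
        report["motifs"] = {"skipped": True}

    io.write_json(report, outdir / "report.json")
    (outdir / "report.txt").write_text(render_text_report(report))
    return report


def render_text_report(report: dict) -> str:
    """Human-readable one-page summary of a pipeline report."""
    lines = ["targetome pipeline report",
             f"config {report['provenance']['config_digest']}  "
             f"seed {report['provenance']['seed']}", ""]
    c = report["concordance"]
    lines.append(
        f"replicates: {c['n_replicate1']} and {c['n_replicate2']} peaks; "
        f"{c['shared']} shared (concordance "
        f"{c['concordance_replicate1']:.1%} / {c['concordance_replicate2']:.1%}, "
        f"mean {c['mean_concordance']:.1%})"
    )
    if "height_r_2dp" in c:
        lines.append(f"paired peak-height correlation r = {c['height_r_2dp']}")
    de = report["differential_expression"]
    if de.get("skipped"):
        lines.append("differential expression: skipped (no input)")
    else:
        lines.append(
            f"differential expression: {de['n_up']} up, {de['n_down']} down "
            f"at q <= {de['q_threshold']}"
        )
    t = report["targetome"]
    v = t["venn"]
    lines.append(
        f"targetome: {t['n_direct_targets']} direct targets "
        f"({v['bound_genes']} bound genes, {v['regulated_genes']} regulated)"
    )
    for direction, label in (("up", "induced"), ("down", "repressed")):
        pct = t["distribution"][direction]["percent"]
        if pct:
            lines.append(
                f"{label} sites: {pct['proximal']}% proximal, "
                f"{pct['distal_upstream']}% distal upstream, "
                f"{pct['distal_downstream']}% distal downstream"
            )
    ctx = report["chromatin_context"]
    if not ctx.get("skipped"):
        for direction, label in (("up", "induced"), ("down", "repressed")):
            e = ctx[direction]
            if e["n_peaks"]:
                cof = (f", {e['pct_cofactor']}% cofactor-occupied"
                       if "pct_cofactor" in e else "")
                lines.append(f"{label} sites: {e['pct_dhs']}% in DHS regions{cof}")
    m = report["motifs"]
    if not m.get("skipped"):
        for cat, rows in m.items():
            if rows:
                top = rows[0]
                lines.append(f"top motif in {cat}: {top['motif']} (z = {top['z']:.1f})")
    return "\n".join(lines) + "\n"
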