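"""End-to-end orchestration: simulate -> score -> correct -> combine ->
hits -> overlap -> enrich, from a single config with deterministic seeding.

Every stage reads and writes TSV (images only at the front of the
pipeline); floats are written at six significant digits so reruns with the
same config produce byte-identical outputs.  A run manifest accounts for
every record entering and leaving each filtering stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import enrichgraph, imgquant, platecorr, screenstats, synthgen
from .synthgen import GridGeometry, SimParams, derive_seed

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"

STAGES = ("simulate", "score", "correct", "combine", "hits", "overlap", "enrich")


@dataclass
class RunConfig:
    """All knobs of a pipeline run; round-trips through YAML unchanged."""

    seed: int = 0
    outdir: str = "crispa_run"

    # study design
    n_genes: int = 384
    n_screens: int = 4
    scheme: str = "randomized"
    cell_px: int = 16
    image_format: str = "png"

    # synthetic truth (None = SimParams default)
    bulk_sd: float = 0.3
    n_yellow: int | None = None
    n_white: int | None = None
    yellow_effect: float = 3.0
    white_effect: float = -3.0
    noise_sd: float = 0.3
    contamination_rate: float = 0.01
    missing_rate: float = 0.01
    plate_bias_sd: float = 0.05
    edge_bias: list = field(default_factory=lambda: [1.25, 1.25])

    # analysis
    n_frames: int = 2
    pixel_quantile: float = 0.5
    grubbs_alpha: float = 0.05
    min_replicates: int = 3
    sd_threshold: float = 1.2
    cyan_size_min: float = 0.0
    k_list_size: int = 192
    q_threshold: float = 0.05
    annotations: str | None = None

    def __post_init__(self) -> None:
        if self.scheme not in ("block", "randomized"):
            raise ValueError("scheme must be 'block' or 'randomized'")
        if not 0 < self.grubbs_alpha < 1:
            raise ValueError("grubbs_alpha must be in (0, 1)")
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")
        if not 0 <= self.pixel_quantile < 1:
            raise ValueError("pixel_quantile must be in [0, 1)")
        if self.min_replicates < 1 or self.k_list_size < 1 or self.n_frames < 1:
            raise ValueError("counts must be positive")
        if self.image_format not in ("png", "tiff"):
            raise ValueError("image_format must be 'png' or 'tiff'")

    def sim_params(self) -> SimParams:
        return SimParams(
            bulk_sd=self.bulk_sd, n_yellow=self.n_yellow, n_white=self.n_white,
            yellow_effect=self.yellow_effect, white_effect=self.white_effect,
            noise_sd=self.noise_sd, contamination_rate=self.contamination_rate,
            missing_rate=self.missing_rate, plate_bias_sd=self.plate_bias_sd,
            edge_bias=tuple(self.edge_bias),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Per-stage record accounting for one pipeline run."""

    version: str
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, n_in: int, n_out: int, **extra) -> None:
        self.stages[stage] = {"in": int(n_in), "out": int(n_out),
                              "dropped": int(n_in - n_out), **extra}

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True) + "\n")


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def _image_path(imgdir: Path, plate_id: str, fmt: str) -> Path:
    ext = "png" if fmt == "png" else "tif"
    return imgdir / f"{plate_id.replace('-', '_')}.{ext}"


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs carry a .partial marker."""


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order and write every output under outdir."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    imgdir = out / "images"
    imgdir.mkdir(exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = RunManifest(__version__, config.config_hash(), config.seed)

    stage = "simulate"
    try:
        geometry = GridGeometry.for_format(1536, config.cell_px)
        params = config.sim_params()
        library = synthgen.generate_library(config.n_genes, config.seed)
        layouts = []
        for s in range(1, config.n_screens + 1):
            layouts += synthgen.randomize_layout(
                library, config.scheme,
                derive_seed(config.seed, f"layout:{s}"), screen_id=f"S{s}",
            )
        truth = synthgen.simulate_truth(layouts, params, config.seed)
        synthgen.write_layouts(layouts, out / "layouts.tsv")
        truth.write(out / "truth.tsv")
        images = []
        for lay in layouts:
            img = synthgen.render_plate(lay, truth, geometry, config.seed,
                                        noise_sd=params.noise_sd)
            iio.imwrite(_image_path(imgdir, lay.plate_id, config.image_format),
                        img.pixels)
            images.append(img)
        manifest.record(stage, config.n_genes, config.n_genes,
                        n_plates=len(layouts),
                        n_missing=len(truth.missing),
                        n_contaminated=len(truth.contamination))

        stage = "score"
        measurements = imgquant.score_plates(images, layouts,
                                             quantile=config.pixel_quantile)
        _write_tsv(measurements, out / "measurements.tsv")
        manifest.record(stage, len(measurements), len(measurements))

        stage = "correct"
        screen_tables = []
        for s in range(1, config.n_screens + 1):
            table = platecorr.ScreenTable.from_measurements(
                measurements, screen_id=f"S{s}")
            table = platecorr.edge_correct(table, n_frames=config.n_frames)
            table = platecorr.normalize_screen(table)
            screen_tables.append(table)
        corrected = pd.concat([t.data for t in screen_tables], ignore_index=True)
        _write_tsv(corrected, out / "corrected.tsv")
        manifest.record(stage, len(measurements), len(corrected))

        stage = "combine"
        records = platecorr.derandomize(screen_tables, layouts)
        summaries = screenstats.combine_screens(
            [records], min_replicates=config.min_replicates,
            grubbs_alpha=config.grubbs_alpha)
        manifest.record(stage, config.n_genes, len(summaries),
                        n_records=len(records))
        if summaries.empty:
            logger.warning("combine: every gene dropped "
                           "(min_replicates=%d)", config.min_replicates)

        stage = "hits"
        hits = screenstats.call_hits(summaries, config.sd_threshold,
                                     config.sd_threshold, config.cyan_size_min)
        _write_tsv(hits, out / "gene_summary.tsv")
        manifest.record(stage, len(summaries), len(hits),
                        n_yellow=int((hits["group"] == "yellow").sum()) if len(hits) else 0,
                        n_white=int((hits["group"] == "white").sum()) if len(hits) else 0,
                        n_cyan=int(hits["cyan"].sum()) if len(hits) else 0)

        stage = "overlap"
        per_screen = {
            t.screen_id: screenstats.aggregate_genes(
                platecorr.derandomize([t], layouts),
                config.min_replicates, config.grubbs_alpha)
            for t in screen_tables
        }
        rows = []
        sids = sorted(per_screen)
        for a, b in zip(sids, sids[1:]):
            sa, sb = per_screen[a], per_screen[b]
            common = set(sa["gene_id"]) & set(sb["gene_id"])
            if len(common) < max(3, config.k_list_size):
                logger.warning("overlap %s/%s skipped: only %d common genes",
                               a, b, len(common))
                continue
            r = screenstats.pearson(sa.set_index("gene_id")["mean_yellow"],
                                    sb.set_index("gene_id")["mean_yellow"])
            for tail in ("top", "bottom"):
                res = screenstats.top_bottom_overlap(sa, sb,
                                                     config.k_list_size, tail)
                rows.append((a, b, tail, res.M, res.n, res.N, res.k,
                             res.p_value, r))
        overlaps = pd.DataFrame(rows, columns=[
            "screen_a", "screen_b", "tail", "M", "n", "N", "k",
            "p_value", "pearson"])
        _write_tsv(overlaps, out / "overlap.tsv")
        manifest.record(stage, len(rows), len(rows))

        stage = "enrich"
        study = sorted(hits.loc[hits["group"] == "yellow", "gene_id"]) if len(hits) else []
        if not study:
            logger.warning("enrich skipped: no yellow hit genes")
            manifest.record(stage, 0, 0)
        else:
            if config.annotations:
                ann = enrichgraph.read_annotations(config.annotations)
            else:
                ann = synthgen.generate_annotations(
                    sorted(truth.gene_effects),
                    truth.genes_in_group("yellow"), config.seed)
            population = sorted(hits["gene_id"])
            terms = enrichgraph.enrich(study, population, ann,
                                       config.q_threshold)
            _write_tsv(terms, out / "enrichment.tsv")
            enriched = terms[terms["enriched"]]
            graph = enrichgraph.build_term_graph(
                enriched, ann,
                color_keywords=("mitochondri", "translation", "vacuol"))
            enrichgraph.write_term_graph(graph, out / "term_graph.graphml",
                                         out / "term_edges.tsv")
            manifest.record(stage, len(terms), len(enriched))
    except Exception as exc:
        (out / f"{stage}.partial").touch()
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.write(out / "manifest.json")
    return manifest
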