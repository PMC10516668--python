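"""Synthetic colony-array screens with known ground truth.

High-density yeast screens pin an arrayed deletion library (384-colony
storage format) in quadruplicate onto 1536-colony screening plates and read
a pigment phenotype (colony "yellowness") plus colony size (fitness proxy)
from plate photographs.  This module generates seeded synthetic screens with
the statistical structure the downstream analysis assumes:

* library layouts and their quadruplicate 1536-format randomization, where
  each of the four replicate arrays of a library plate lands on a different
  screening plate (row/column positions unchanged, only the 2x2 interleave
  offset varies);
* per-gene ground-truth effects drawn from a three-part mixture — a null
  bulk, a yellow (pigment-up) tail whose members carry a fitness penalty,
  and a white (pigment-down) tail;
* plate-level and edge (outer-frame) multiplicative biases, a small rate of
  missing colonies and of colonies contaminated by white cells;
* rendered 8-bit RGB plate images in which colony color has a fixed yellow
  hue, saturation follows a logistic map of the pigment effect, and disc
  area is monotone in fitness.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

logger = logging.getLogger(__name__)

#: colony formats supported: positions -> (rows, cols)
FORMATS = {384: (16, 24), 1536: (32, 48)}

#: 2x2 interleave offsets (dr, dc), in replicate order for the block scheme
OFFSETS = ((0, 0), (0, 1), (1, 0), (1, 1))

#: default colony brightness (HSV value) under the renderer
COLONY_VALUE = 0.9

#: pigment effect assigned to contaminating white cells
WHITE_CELL_PIGMENT = -3.0


def derive_seed(seed: int, label: str) -> int:
    """Stable per-stage sub-seed: hash of (seed, label), below 2**31."""
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# geometry and layouts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridGeometry:
    """Pixel geometry of a colony grid.

    ``origin_px`` is the (y, x) pixel coordinate of the top-left cell
    *center*; cell centers are spaced ``cell_px`` apart in both directions.
    """

    n_rows: int
    n_cols: int
    cell_px: int = 16
    origin_px: tuple[int, int] = (16, 16)

    def __post_init__(self) -> None:
        if (self.n_rows, self.n_cols) not in FORMATS.values():
            raise ValueError(
                f"unsupported grid {self.n_rows}x{self.n_cols}; "
                f"expected one of {sorted(FORMATS.values())}"
            )
        if self.cell_px < 8:
            raise ValueError("cell_px must be >= 8")
        oy, ox = self.origin_px
        if oy < 0 or ox < 0:
            raise ValueError("origin must be inside the image")

    @classmethod
    def for_format(cls, fmt: int, cell_px: int = 16) -> "GridGeometry":
        rows, cols = FORMATS[fmt]
        return cls(rows, cols, cell_px, (cell_px, cell_px))

    @property
    def format(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def image_shape(self) -> tuple[int, int]:
        oy, ox = self.origin_px
        return (
            2 * oy + (self.n_rows - 1) * self.cell_px,
            2 * ox + (self.n_cols - 1) * self.cell_px,
        )

    def cell_center(self, row: int, col: int) -> tuple[int, int]:
        oy, ox = self.origin_px
        return oy + row * self.cell_px, ox + col * self.cell_px


class LayoutEntry(NamedTuple):
    row: int
    col: int
    gene_id: str | None
    source_plate_id: str
    source_row: int
    source_col: int
    replicate_index: int


LAYOUT_COLUMNS = [
    "plate_id",
    "row",
    "col",
    "gene_id",
    "source_plate_id",
    "source_row",
    "source_col",
    "replicate_index",
]


@dataclass
class PlateLayout:
    """Position -> gene mapping for one plate, with source-plate provenance.

    Coordinates are 0-based, row 0 at the image top.  Blank positions are
    kept as entries with ``gene_id=None``.
    """

    plate_id: str
    format: int
    entries: list[LayoutEntry] = field(default_factory=list)
    screen_id: str | None = None

    def __post_init__(self) -> None:
        if self.format not in FORMATS:
            raise ValueError(f"format must be one of {sorted(FORMATS)}")
        seen = {(e.row, e.col) for e in self.entries}
        if len(seen) != len(self.entries):
            raise ValueError(f"duplicate positions on plate {self.plate_id}")

    @property
    def shape(self) -> tuple[int, int]:
        return FORMATS[self.format]

    def filled(self) -> list[LayoutEntry]:
        return [e for e in self.entries if e.gene_id]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.entries, columns=LayoutEntry._fields)
        df.insert(0, "plate_id", self.plate_id)
        df["gene_id"] = df["gene_id"].fillna("")
        return df[LAYOUT_COLUMNS]


def layouts_to_frame(layouts: Iterable[PlateLayout]) -> pd.DataFrame:
    return pd.concat([p.to_frame() for p in layouts], ignore_index=True)


def write_layouts(layouts: Iterable[PlateLayout], path) -> None:
    layouts_to_frame(layouts).to_csv(path, sep="\t", index=False)


def read_layouts(path) -> list[PlateLayout]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, keep_default_na=False)
    layouts = []
    for plate_id, grp in df.groupby("plate_id", sort=True):
        fmt = 1536 if (grp["row"].max() >= 16 or grp["col"].max() >= 24) else 384
        if len(grp) == 1536:
            fmt = 1536
        entries = [
            LayoutEntry(
                int(r.row), int(r.col), r.gene_id or None,
                str(r.source_plate_id), int(r.source_row), int(r.source_col),
                int(r.replicate_index),
            )
            for r in grp.itertuples()
        ]
        layouts.append(PlateLayout(str(plate_id), fmt, entries))
    return layouts


def generate_library(
    n_genes: int, seed: int = 0, gene_ids: Sequence[str] | None = None,
    plate_prefix: str = "LIB",
) -> list[PlateLayout]:
    """Lay out ``n_genes`` genes left-to-right, top-to-bottom on 384 plates.

    The assignment is deterministic; ``seed`` is accepted for interface
    uniformity with the other generators.  Unfilled positions on the last
    plate are marked empty.
    """
    if n_genes < 1:
        raise ValueError("library must contain at least one gene")
    if gene_ids is None:
        width = max(4, len(str(n_genes)))
        gene_ids = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")

    rows, cols = FORMATS[384]
    n_plates = math.ceil(n_genes / 384)
    layouts = []
    for p in range(n_plates):
        pid = f"{plate_prefix}{p + 1:02d}"
        entries = []
        for pos in range(384):
            i = p * 384 + pos
            gene = gene_ids[i] if i < n_genes else None
            r, c = divmod(pos, cols)
            entries.append(LayoutEntry(r, c, gene, pid, r, c, 0))
        layouts.append(PlateLayout(pid, 384, entries))
    return layouts


def empty_plate(plate_id: str) -> PlateLayout:
    rows, cols = FORMATS[384]
    entries = [
        LayoutEntry(r, c, None, plate_id, r, c, 0)
        for r in range(rows) for c in range(cols)
    ]
    return PlateLayout(plate_id, 384, entries)


def latin_square_4(rng: np.random.Generator) -> np.ndarray:
    """Seeded 4x4 Latin square (row/column permutations of the cyclic square)."""
    base = (np.arange(4)[:, None] + np.arange(4)[None, :]) % 4
    return base[rng.permutation(4)][:, rng.permutation(4)]


def randomize_layout(
    library: Sequence[PlateLayout],
    scheme: str = "randomized",
    seed: int = 0,
    screen_id: str = "S1",
) -> list[PlateLayout]:
    """Assemble 1536-format screening plates from 384-format library plates.

    ``"block"``: the four replicates of each colony form a 2x2 block on a
    single screening plate (one screening plate per library plate).

    ``"randomized"``: within each group of four library plates, every
    library plate contributes one replicate array to each of four screening
    plates; the interleave offset of library plate *i* on screening plate
    *j* follows a seeded 4x4 Latin square, so each plate uses each offset
    exactly once and no two arrays collide.  Within-array row/column
    positions are never altered.
    """
    if scheme not in ("block", "randomized"):
        raise ValueError(f"unknown randomization scheme {scheme!r}")
    if not library:
        raise ValueError("empty library")
    for p in library:
        if p.format != 384:
            raise ValueError("library plates must be 384 format")

    plates = list(library)
    pad = (-len(plates)) % 4
    for i in range(pad):
        plates.append(empty_plate(f"{screen_id}-PAD{i + 1}"))

    rng = np.random.default_rng(derive_seed(seed, f"randomize:{screen_id}"))
    screens: list[PlateLayout] = []
    for g in range(len(plates) // 4):
        group = plates[g * 4:(g + 1) * 4]
        square = latin_square_4(rng)
        for j in range(4):
            pid = f"{screen_id}-P{g * 4 + j + 1}"
            entries = []
            for i, lib in enumerate(group):
                if scheme == "block":
                    if i != j:
                        continue
                    # all four offsets from one library plate
                    for rep, (dr, dc) in enumerate(OFFSETS, start=1):
                        for e in lib.entries:
                            entries.append(LayoutEntry(
                                2 * e.row + dr, 2 * e.col + dc, e.gene_id,
                                lib.plate_id, e.row, e.col, rep,
                            ))
                else:
                    dr, dc = OFFSETS[square[i, j]]
                    for e in lib.entries:
                        entries.append(LayoutEntry(
                            2 * e.row + dr, 2 * e.col + dc, e.gene_id,
                            lib.plate_id, e.row, e.col, j + 1,
                        ))
            screens.append(PlateLayout(pid, 1536, sorted(entries), screen_id))
    return screens


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimParams:
    """Generator defaults = the study conditions being emulated.

    Pigment and fitness effects are on the z scale of the downstream screen
    normalization.  The effect distribution is a three-part mixture: a null
    bulk (N(0, bulk_sd)), a yellow tail planted at +``yellow_effect`` whose
    members carry a mean fitness penalty, and a white tail planted at
    ``white_effect`` with a broad fitness range.
    """

    bulk_sd: float = 0.3
    yellow_frac: float = 0.05
    white_frac: float = 0.05
    n_yellow: int | None = None
    n_white: int | None = None
    yellow_effect: float = 3.0
    white_effect: float = -3.0
    yellow_fitness_penalty: float = -1.5
    yellow_fitness_sd: float = 0.3
    white_fitness_sd: float = 1.0
    noise_sd: float = 0.3
    contamination_rate: float = 0.01
    missing_rate: float = 0.01
    plate_bias_sd: float = 0.05
    edge_bias: tuple[float, ...] = (1.25, 1.25)

    def __post_init__(self) -> None:
        for name in ("bulk_sd", "yellow_frac", "white_frac", "yellow_fitness_sd",
                     "white_fitness_sd", "noise_sd", "contamination_rate",
                     "missing_rate", "plate_bias_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(b <= 0 for b in self.edge_bias):
            raise ValueError("edge bias factors must be positive")


@dataclass
class SyntheticTruth:
    """Planted gene effects and nuisance structure of a synthetic study."""

    gene_effects: dict[str, tuple[float, float]]  # gene -> (pigment, fitness)
    planted_group: dict[str, str]                 # gene -> yellow|white|none
    plate_bias: dict[str, float]
    edge_bias: tuple[float, ...]
    contamination: list[tuple[str, int, int, float]]  # plate, row, col, white_fraction
    missing: set[tuple[str, int, int]]
    seed: int

    def genes_in_group(self, group: str) -> list[str]:
        return sorted(g for g, grp in self.planted_group.items() if grp == group)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, pe, fe, self.planted_group[g])
            for g, (pe, fe) in sorted(self.gene_effects.items())
        ]
        return pd.DataFrame(
            rows, columns=["gene_id", "pigment_effect", "fitness_effect", "planted_group"]
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def simulate_truth(
    layouts: Sequence[PlateLayout],
    params: SimParams = SimParams(),
    seed: int = 0,
) -> SyntheticTruth:
    """Draw gene effects, plate biases, contamination and missingness.

    Deterministic for a fixed seed.  Planted yellow/white genes receive
    exactly ``yellow_effect`` / ``white_effect`` as pigment effect so the
    planted hit lists are unambiguous in the truth table.
    """
    rng = np.random.default_rng(derive_seed(seed, "truth"))
    genes = sorted({e.gene_id for p in layouts for e in p.filled()})
    n = len(genes)
    if n == 0:
        raise ValueError("layouts contain no genes")

    n_yellow = params.n_yellow if params.n_yellow is not None else round(params.yellow_frac * n)
    n_white = params.n_white if params.n_white is not None else round(params.white_frac * n)
    if n_yellow + n_white > n:
        raise ValueError("more planted hits than genes")

    picked = rng.choice(n, size=n_yellow + n_white, replace=False)
    yellow = {genes[i] for i in picked[:n_yellow]}
    white = {genes[i] for i in picked[n_yellow:]}

    gene_effects: dict[str, tuple[float, float]] = {}
    planted_group: dict[str, str] = {}
    for g in genes:
        if g in yellow:
            pe = params.yellow_effect
            fe = params.yellow_fitness_penalty + rng.normal(0, params.yellow_fitness_sd)
            grp = "yellow"
        elif g in white:
            pe = params.white_effect
            fe = rng.normal(0, params.white_fitness_sd)
            grp = "white"
        else:
            pe = rng.normal(0, params.bulk_sd)
            fe = rng.normal(0, params.bulk_sd)
            grp = "none"
        gene_effects[g] = (float(pe), float(fe))
        planted_group[g] = grp

    plate_bias = {
        p.plate_id: float(np.exp(rng.normal(0, params.plate_bias_sd)))
        for p in layouts
    }

    contamination: list[tuple[str, int, int, float]] = []
    missing: set[tuple[str, int, int]] = set()
    for p in layouts:
        for e in p.filled():
            if rng.random() < params.missing_rate:
                missing.add((p.plate_id, e.row, e.col))
            elif rng.random() < params.contamination_rate:
                wf = float(rng.beta(1, 9))
                contamination.append((p.plate_id, e.row, e.col, wf))

    return SyntheticTruth(
        gene_effects, planted_group, plate_bias, tuple(params.edge_bias),
        contamination, missing, seed,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


@dataclass
class PlateImage:
    """8-bit RGB rendering of one plate plus its grid geometry."""

    pixels: np.ndarray
    geometry: GridGeometry
    plate_id: str
    clipped: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be HxWx3")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit")


def colony_color(pigment: float, value: float = COLONY_VALUE,
                 edge_factor: float = 1.0) -> tuple[int, int, int]:
    """8-bit RGB of a colony: fixed yellow hue, saturation = logistic(pigment).

    At hue 1/6 the RGB triple is (V, V, V*(1-S)); quantization to 8 bits is
    part of the color model (see :func:`colony_sv`).
    """
    s = min(float(expit(pigment)) * edge_factor, 1.0)
    vint = int(round(255 * value))
    vint = max(0, min(255, vint))
    b = int(round(vint * (1.0 - s)))
    return vint, vint, b


def colony_sv(pigment: float, value: float = COLONY_VALUE,
              edge_factor: float = 1.0) -> tuple[float, float]:
    """Exact (saturation, value) of the rendered 8-bit colony color."""
    r, _, b = colony_color(pigment, value, edge_factor)
    if r == 0:
        return 0.0, 0.0
    return (r - b) / r, r / 255.0


def planted_yellowness(pigment: float, value: float = COLONY_VALUE) -> float:
    """sqrt(S*V) of the rendered colony color for a planted pigment effect."""
    s, v = colony_sv(pigment, value)
    return math.sqrt(s * v)


def ring_index(row: int, col: int, n_rows: int, n_cols: int) -> int:
    """Distance of a grid position to the nearest plate border (ring 0 = outermost)."""
    return min(row, col, n_rows - 1 - row, n_cols - 1 - col)


def render_plate(
    layout: PlateLayout,
    truth: SyntheticTruth,
    geometry: GridGeometry,
    seed: int = 0,
    noise_sd: float | None = None,
    base_radius: float | None = None,
    background: int = 40,
    fitness_scale: float = 0.15,
) -> PlateImage:
    """Render one plate: each non-missing colony as a filled disc.

    Disc area is ``pi*r0^2 * exp(fitness_scale*(fitness+noise)) * plate_bias
    * edge_bias(ring)``; colony saturation is ``logistic(pigment+noise)``
    scaled by the plate/edge bias (capped at 1).  Contaminated colonies mix
    in white-cell pixels at their planted fraction.  Radii exceeding half
    the cell pitch are clipped and recorded in ``PlateImage.clipped``.
    """
    if layout.format != geometry.format:
        raise ValueError("layout format does not match geometry")
    if noise_sd is None:
        noise_sd = 0.3
    if base_radius is None:
        base_radius = geometry.cell_px / 3.0
    max_radius = geometry.cell_px / 2.0 - 0.5

    rng = np.random.default_rng(derive_seed(seed, f"render:{layout.plate_id}"))
    h, w = geometry.image_shape
    img = np.full((h, w, 3), background, dtype=np.uint8)
    clipped: list[tuple[int, int]] = []

    pbias = truth.plate_bias.get(layout.plate_id, 1.0)
    contam = {
        (r, c): wf for pid, r, c, wf in truth.contamination
        if pid == layout.plate_id
    }
    n_rows, n_cols = layout.shape
    white_rgb = colony_color(WHITE_CELL_PIGMENT)

    for e in sorted(layout.filled()):
        # draw noise for every colony so the stream is independent of missingness
        pig_noise = rng.normal(0, noise_sd) if noise_sd > 0 else 0.0
        fit_noise = rng.normal(0, noise_sd) if noise_sd > 0 else 0.0
        if (layout.plate_id, e.row, e.col) in truth.missing:
            continue
        pe, fe = truth.gene_effects[e.gene_id]
        ring = ring_index(e.row, e.col, n_rows, n_cols)
        ebias = truth.edge_bias[ring] if ring < len(truth.edge_bias) else 1.0

        area_factor = math.exp(fitness_scale * (fe + fit_noise)) * pbias * ebias
        radius = base_radius * math.sqrt(area_factor)
        if radius > max_radius:
            radius = max_radius
            clipped.append((e.row, e.col))

        rgb = colony_color(pe + pig_noise, edge_factor=pbias * ebias)
        cy, cx = geometry.cell_center(e.row, e.col)
        rr = int(math.ceil(radius))
        yy, xx = np.mgrid[-rr:rr + 1, -rr:rr + 1]
        disc = (yy**2 + xx**2) <= radius**2
        ys, xs = np.nonzero(disc)
        ys = ys - rr + cy
        xs = xs - rr + cx
        keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        ys, xs = ys[keep], xs[keep]
        img[ys, xs] = rgb

        wf = contam.get((e.row, e.col))
        if wf:
            n_white = int(round(wf * len(ys)))
            if n_white > 0:
                idx = rng.choice(len(ys), size=n_white, replace=False)
                img[ys[idx], xs[idx]] = white_rgb

    return PlateImage(img, geometry, layout.plate_id, clipped)


# ---------------------------------------------------------------------------
# synthetic annotations (for enrichment recovery studies)
# ---------------------------------------------------------------------------

_TERM_WORDS = [
    "translation elongation", "ribosome biogenesis", "vacuolar transport",
    "protein folding", "lipid metabolic process", "DNA repair",
    "cell wall organization", "amino acid biosynthesis", "autophagy",
    "chromatin remodeling", "tRNA modification", "vesicle fusion",
]

_DESIGNATED = [
    ("TY1", "mitochondrial respiratory chain complex assembly"),
    ("TY2", "mitochondrial electron transport"),
    ("TY3", "mitochondrion organization"),
]


def generate_annotations(
    genes: Sequence[str],
    planted_yellow: Sequence[str],
    seed: int = 0,
    n_background_terms: int = 25,
    term_size: int = 12,
):
    """Synthetic gene->term annotation table with three designated terms.

    The designated terms tile the planted yellow genes with pairwise
    overlaps (so the enriched terms form a connected component in the term
    graph) plus a little background; the remaining terms are random gene
    sets.  Returns an :class:`crispa.enrichgraph.AnnotationSet`.
    """
    from .enrichgraph import AnnotationSet

    rng = np.random.default_rng(derive_seed(seed, "annotations"))
    genes = list(genes)
    yellow = list(planted_yellow)
    terms: dict[str, tuple[str, frozenset]] = {}

    if yellow:
        n = len(yellow)
        thirds = max(1, n // 3)
        slices = [
            yellow[0:thirds + max(1, thirds // 3)],
            yellow[max(0, thirds - max(1, thirds // 3)):2 * thirds + 1],
            yellow[max(0, 2 * thirds - 1):],
        ]
        for (tid, desc), members in zip(_DESIGNATED, slices):
            extra = rng.choice(genes, size=2, replace=False).tolist()
            terms[tid] = (desc, frozenset(members) | frozenset(extra))

    for i in range(n_background_terms):
        size = max(2, int(rng.integers(term_size // 2, term_size * 2)))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        desc = _TERM_WORDS[i % len(_TERM_WORDS)]
        terms[f"TB{i + 1:02d}"] = (desc, frozenset(members.tolist()))

    parents = {tid: {"TPAR"} for tid, _ in _DESIGNATED if tid in terms}
    terms["TPAR"] = ("mitochondria", frozenset(
        g for tid, _ in _DESIGNATED if tid in terms for g in terms[tid][1]
    ))
    return AnnotationSet(terms=terms, parents=parents)
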