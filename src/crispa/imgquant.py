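"""Colony segmentation and per-colony size / yellowness extraction.

A plate photograph is reduced to one record per grid position: the number
of pixels assigned to the colony (size, a fitness proxy) and a yellowness
score in [0, 1] defined as the geometric mean of HSV Saturation and Value,
averaged over the brighter colony pixels.  The color model assumes a fixed
yellow hue, so sqrt(S*V) captures pigment intensity regardless of hue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .synthgen import GridGeometry, PlateImage, PlateLayout

logger = logging.getLogger(__name__)

# Rec. 709 luma, as used by skimage.color.rgb2gray
_LUMA = np.array([0.2125, 0.7154, 0.0721])

MEASUREMENT_COLUMNS = [
    "screen_id", "plate_id", "row", "col", "gene_id",
    "source_plate_id", "source_row", "source_col", "replicate_index",
    "size_px", "yellowness_raw", "flags",
]


@dataclass
class ColonyMask:
    """Pixels assigned to one grid position on one plate."""

    plate_id: str
    row: int
    col: int
    ys: np.ndarray
    xs: np.ndarray

    @property
    def size(self) -> int:
        return len(self.ys)


@dataclass
class ColonyRecord:
    plate_id: str
    row: int
    col: int
    gene_id: str | None
    size_px: int
    yellowness: float | None
    flags: set = field(default_factory=set)


def yellowness_pixel(r, g, b):
    """sqrt(S*V) of an 8-bit RGB pixel under the hexcone HSV model.

    V = max/255 and S = (max-min)/max with S := 0 when the max channel is 0.
    Accepts scalars or arrays; channel values must lie in [0, 255].
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any((r < 0) | (r > 255) | (g < 0) | (g > 255) | (b < 0) | (b > 255)):
        raise ValueError("channel values must lie in [0, 255]")
    mx = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    v = mx / 255.0
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(mx > 0, (mx - mn) / np.where(mx > 0, mx, 1.0), 0.0)
    out = np.sqrt(s * v)
    return float(out) if out.ndim == 0 else out


def _grayscale(pixels: np.ndarray) -> np.ndarray:
    return pixels.astype(float) @ _LUMA


def segment_colonies(
    image: PlateImage | np.ndarray,
    geometry: GridGeometry | None = None,
    threshold: float | None = None,
) -> list[ColonyMask]:
    """Assign foreground pixels to grid cells.

    Foreground is found by Otsu global thresholding on grayscale (the
    background is darker than any colony); each foreground pixel is assigned
    to the nearest cell center, capped at one cell pitch so an overgrown
    colony cannot annex a neighboring cell.  Every grid position yields a
    mask, possibly empty.  ``threshold`` (grayscale in [0, 255]-luma units)
    overrides Otsu.
    """
    if isinstance(image, PlateImage):
        pixels, geometry, plate_id = image.pixels, image.geometry, image.plate_id
    else:
        pixels, plate_id = np.asarray(image), ""
        if geometry is None:
            raise ValueError("geometry required when passing a bare array")
    if pixels.shape[:2] != geometry.image_shape:
        raise ValueError(
            f"image shape {pixels.shape[:2]} does not match geometry "
            f"{geometry.image_shape}"
        )

    gray = _grayscale(pixels)
    if threshold is None:
        if np.ptp(gray) < 1e-9:
            # featureless image: no foreground
            fg = np.zeros_like(gray, dtype=bool)
        else:
            fg = gray > threshold_otsu(gray)
    else:
        fg = gray > threshold

    oy, ox = geometry.origin_px
    cp = geometry.cell_px
    ys, xs = np.nonzero(fg)
    rows = np.clip(np.round((ys - oy) / cp).astype(int), 0, geometry.n_rows - 1)
    cols = np.clip(np.round((xs - ox) / cp).astype(int), 0, geometry.n_cols - 1)
    dy = ys - (oy + rows * cp)
    dx = xs - (ox + cols * cp)
    keep = dy * dy + dx * dx <= cp * cp
    ys, xs, rows, cols = ys[keep], xs[keep], rows[keep], cols[keep]

    buckets: dict[tuple[int, int], list] = {}
    order = np.lexsort((xs, ys, cols, rows))
    ys, xs, rows, cols = ys[order], xs[order], rows[order], cols[order]
    cell = rows * geometry.n_cols + cols
    bounds = np.flatnonzero(np.diff(cell)) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [len(cell)]])
    for s, e in zip(starts, ends):
        if e > s:
            buckets[(int(rows[s]), int(cols[s]))] = (ys[s:e], xs[s:e])

    masks = []
    empty = np.empty(0, dtype=int)
    for r in range(geometry.n_rows):
        for c in range(geometry.n_cols):
            py, px = buckets.get((r, c), (empty, empty))
            masks.append(ColonyMask(plate_id, r, c, py, px))
    return masks


def score_colony(
    image: PlateImage | np.ndarray,
    mask: ColonyMask,
    gene_id: str | None = None,
    quantile: float | None = 0.5,
    contamination_sd: float = 0.05,
) -> ColonyRecord:
    """Score one colony: unfiltered pixel count plus filtered mean yellowness.

    The pixel filter retains mask pixels with grayscale intensity at or
    above the ``quantile`` of the mask's own intensities (default: the
    brighter half), excluding dim rim / background-bleed pixels; yellowness
    is the arithmetic mean of per-pixel sqrt(S*V) over retained pixels.
    ``quantile=None`` (or 0) disables the filter.  An empty mask yields
    ``size_px=0``, a ``missing`` flag and no yellowness; a high dispersion
    of pixel yellowness raises a ``contaminated-suspect`` flag.
    """
    pixels = image.pixels if isinstance(image, PlateImage) else np.asarray(image)
    if mask.size == 0:
        return ColonyRecord(mask.plate_id, mask.row, mask.col, gene_id, 0, None,
                            {"missing"})

    rgb = pixels[mask.ys, mask.xs].astype(float)
    yellow_all = yellowness_pixel(rgb[:, 0], rgb[:, 1], rgb[:, 2])
    yellow_all = np.atleast_1d(yellow_all)

    if quantile:
        gray = rgb @ _LUMA
        thr = np.quantile(gray, quantile)
        retained = yellow_all[gray >= thr]
    else:
        retained = yellow_all

    flags = set()
    if yellow_all.size >= 2 and float(np.std(yellow_all)) > contamination_sd:
        flags.add("contaminated-suspect")
    return ColonyRecord(
        mask.plate_id, mask.row, mask.col, gene_id,
        int(mask.size), float(np.mean(retained)), flags,
    )


def score_plate(
    image: PlateImage,
    layout: PlateLayout,
    screen_id: str | None = None,
    quantile: float | None = 0.5,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Segment and score every layout position of one plate image."""
    if layout.format != image.geometry.format:
        raise ValueError("layout format does not match image geometry")
    masks = {(m.row, m.col): m for m in segment_colonies(image, threshold=threshold)}
    entry_at = {(e.row, e.col): e for e in layout.entries}
    sid = screen_id if screen_id is not None else (layout.screen_id or "")

    rows = []
    for (r, c), e in sorted(entry_at.items()):
        rec = score_colony(image, masks[(r, c)], e.gene_id, quantile=quantile)
        rows.append((
            sid, layout.plate_id, r, c, e.gene_id or "",
            e.source_plate_id, e.source_row, e.source_col, e.replicate_index,
            rec.size_px,
            np.nan if rec.yellowness is None else rec.yellowness,
            ";".join(sorted(rec.flags)),
        ))
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def score_plates(
    images: Iterable[PlateImage],
    layouts: Iterable[PlateLayout],
    quantile: float | None = 0.5,
) -> pd.DataFrame:
    """Score a collection of plates; layouts are matched by plate_id."""
    by_id = {p.plate_id: p for p in layouts}
    frames = []
    for img in images:
        if img.plate_id not in by_id:
            raise KeyError(f"no layout for plate {img.plate_id}")
        frames.append(score_plate(img, by_id[img.plate_id], quantile=quantile))
    if not frames:
        return pd.DataFrame(columns=MEASUREMENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)
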