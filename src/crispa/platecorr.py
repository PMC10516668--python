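"""Spatial-bias correction and screen normalization.

Colony size and yellowness in high-density arrays are inflated near plate
borders (more agar per colony) and vary plate to plate.  Position
randomization spreads the four replicates of each strain over four
screening plates; the residual, non-random edge effect is removed per plate
by scaling each outer frame ring so its median matches the plate-center
median.  Each screen is then normalized to z-scores over all of its
colonies (pooled across plates), after which replicate measurements are
re-keyed by gene via the inverse of the layout randomization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthgen import FORMATS, PlateLayout

logger = logging.getLogger(__name__)

STATES = ("raw", "edge_corrected", "normalized")

_METRIC_SOURCE = {"yellowness": "yellowness_raw", "size": "size_px"}
_METRIC_CORRECTED = {"yellowness": "yellowness_corrected", "size": "size_corrected"}
_METRIC_Z = {"yellowness": "z_yellow", "size": "z_size"}


@dataclass
class ScreenTable:
    """All colony measurements of one screen plus normalization state.

    ``data`` holds one row per plate position (see
    :data:`crispa.imgquant.MEASUREMENT_COLUMNS`); missing colonies carry
    NaN yellowness and ``size_px == 0``.  The state machine enforces the
    order raw -> edge_corrected -> normalized.
    """

    screen_id: str
    data: pd.DataFrame
    state: str = "raw"
    format: int = 1536

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.format not in FORMATS:
            raise ValueError("format must be 384 or 1536")

    @property
    def shape(self) -> tuple[int, int]:
        return FORMATS[self.format]

    @classmethod
    def from_measurements(cls, df: pd.DataFrame, screen_id: str | None = None,
                          format: int = 1536) -> "ScreenTable":
        if screen_id is None:
            ids = df["screen_id"].unique()
            if len(ids) != 1:
                raise ValueError("measurements span multiple screens; pass screen_id")
            screen_id = str(ids[0])
            sub = df
        else:
            sub = df[df["screen_id"] == screen_id]
        return cls(screen_id, sub.reset_index(drop=True).copy(), "raw", format)


def _valid_values(df: pd.DataFrame, column: str) -> pd.Series:
    """Metric values with missing colonies (and blanks) as NaN."""
    vals = df[column].astype(float).copy()
    missing = (df["size_px"] == 0) | (df["gene_id"] == "")
    vals[missing] = np.nan
    return vals


def edge_correct(table: ScreenTable, n_frames: int = 2,
                 metric: str = "both") -> ScreenTable:
    """Equalize outer-frame ring medians to the plate-center median.

    For each plate and each frame ring r in {0..n_frames-1} (ring 0
    outermost; ring = minimum grid distance to the plate border), every
    value in ring r is multiplied by median(center)/median(ring r), where
    the center is all colonies at border distance >= n_frames.  Missing
    colonies are ignored; a ring (or center) without valid colonies, or a
    zero ring median, leaves that ring uncorrected with a logged warning.
    """
    if table.state != "raw":
        raise ValueError(f"edge_correct requires state 'raw', got {table.state!r}")
    n_rows, n_cols = table.shape
    if n_frames < 1 or 2 * n_frames >= min(n_rows, n_cols):
        raise ValueError("n_frames must be >= 1 and leave a center region")
    metrics = ("yellowness", "size") if metric == "both" else (metric,)
    for m in metrics:
        if m not in _METRIC_SOURCE:
            raise ValueError(f"unknown metric {m!r}")

    df = table.data.copy()
    ring = np.minimum.reduce([
        df["row"].to_numpy(), df["col"].to_numpy(),
        n_rows - 1 - df["row"].to_numpy(), n_cols - 1 - df["col"].to_numpy(),
    ])

    for m in ("yellowness", "size"):
        df[_METRIC_CORRECTED[m]] = _valid_values(df, _METRIC_SOURCE[m])

    for m in metrics:
        col = _METRIC_CORRECTED[m]
        vals = df[col].to_numpy(copy=True)
        for plate_id, idx in df.groupby("plate_id").groups.items():
            idx = np.asarray(idx)
            pring = ring[idx]
            pvals = vals[idx]
            center = pvals[pring >= n_frames]
            center = center[~np.isnan(center)]
            if center.size == 0:
                logger.warning("plate %s: no valid center colonies; %s uncorrected",
                               plate_id, m)
                continue
            center_med = float(np.median(center))
            for r in range(n_frames):
                ring_vals = pvals[pring == r]
                ring_vals = ring_vals[~np.isnan(ring_vals)]
                if ring_vals.size == 0:
                    logger.warning("plate %s ring %d: all missing; %s uncorrected",
                                   plate_id, r, m)
                    continue
                ring_med = float(np.median(ring_vals))
                if ring_med == 0:
                    logger.warning("plate %s ring %d: zero median; %s uncorrected",
                                   plate_id, r, m)
                    continue
                sel = idx[pring == r]
                vals[sel] = vals[sel] * (center_med / ring_med)
        df[col] = vals

    return ScreenTable(table.screen_id, df, "edge_corrected", table.format)


def normalize_screen(table: ScreenTable) -> ScreenTable:
    """Z-normalize each metric over all non-missing colonies of the screen.

    z = (value - screen mean) / screen sd, pooled over every plate of the
    screen, sample sd (denominator n-1).  Applied independently to
    yellowness and size.  Renormalizing an already-normalized table is the
    identity (z of z).  A degenerate (constant) screen raises.
    """
    if table.state == "raw":
        raise ValueError("normalize_screen requires an edge-corrected table")
    df = table.data.copy()
    for m in ("yellowness", "size"):
        src = _METRIC_Z[m] if table.state == "normalized" else _METRIC_CORRECTED[m]
        vals = df[src].astype(float)
        mu = vals.mean()
        sd = vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"degenerate screen: {m} has zero variance")
        df[_METRIC_Z[m]] = (vals - mu) / sd
    return ScreenTable(table.screen_id, df, "normalized", table.format)


def derandomize(
    tables: Iterable[ScreenTable],
    layouts: Sequence[PlateLayout],
) -> pd.DataFrame:
    """Key normalized colony records by (gene_id, replicate_index).

    Inverts the position randomization using the layouts' provenance
    columns.  Records at blank positions are dropped (count logged); a
    measured position absent from the layouts raises.
    """
    lookup = {}
    for p in layouts:
        for e in p.entries:
            lookup[(p.plate_id, e.row, e.col)] = e

    frames = []
    n_blank = 0
    for table in tables:
        df = table.data
        keep_rows = []
        for t in df.itertuples():
            key = (t.plate_id, t.row, t.col)
            if key not in lookup:
                raise KeyError(f"position {key} not found in layouts")
            e = lookup[key]
            if not e.gene_id:
                n_blank += 1
                continue
            keep_rows.append((
                e.gene_id, e.replicate_index, table.screen_id, t.plate_id,
                t.row, t.col, e.source_plate_id, e.source_row, e.source_col,
                t.size_px,
                getattr(t, "z_yellow", np.nan), getattr(t, "z_size", np.nan),
                getattr(t, "flags", ""),
            ))
        frames.append(pd.DataFrame(keep_rows, columns=[
            "gene_id", "replicate_index", "screen_id", "plate_id", "row", "col",
            "source_plate_id", "source_row", "source_col",
            "size_px", "z_yellow", "z_size", "flags",
        ]))
    if n_blank:
        logger.info("derandomize: dropped %d records at blank positions", n_blank)
    if not frames:
        return pd.DataFrame(columns=[
            "gene_id", "replicate_index", "screen_id", "plate_id", "row", "col",
            "source_plate_id", "source_row", "source_col",
            "size_px", "z_yellow", "z_size", "flags",
        ])
    return pd.concat(frames, ignore_index=True)
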