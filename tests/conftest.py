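"""Shared fixtures: a full synthetic study run once per session."""

import pytest

from crispa.imgquant import score_plates
from crispa.platecorr import ScreenTable, derandomize, edge_correct, normalize_screen
from crispa.screenstats import aggregate_genes, call_hits, combine_screens
from crispa.synthgen import (
    GridGeometry,
    SimParams,
    derive_seed,
    generate_library,
    randomize_layout,
    render_plate,
    simulate_truth,
)

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study():
    """End-to-end synthetic study: 384 genes, 20 planted yellow (+3) and 20
    white (-3), four randomized screens of four 1536 plates each, 1%
    contamination and missingness, 1.25x edge bias on the two outer rings,
    per-colony noise sd equal to the bulk effect sd (0.3).

    Runs the full image pipeline in memory and returns every intermediate.
    """
    params = SimParams(n_yellow=20, n_white=20)
    library = generate_library(384, STUDY_SEED)
    layouts = []
    for s in range(1, 5):
        layouts += randomize_layout(
            library, "randomized", derive_seed(STUDY_SEED, f"layout:{s}"),
            screen_id=f"S{s}")
    truth = simulate_truth(layouts, params, STUDY_SEED)
    geometry = GridGeometry.for_format(1536, 16)

    tables = []
    for s in range(1, 5):
        screen_layouts = [l for l in layouts if l.screen_id == f"S{s}"]
        images = [
            render_plate(l, truth, geometry, STUDY_SEED, noise_sd=params.noise_sd)
            for l in screen_layouts
        ]
        measurements = score_plates(images, screen_layouts)
        table = ScreenTable.from_measurements(measurements, f"S{s}")
        tables.append(normalize_screen(edge_correct(table)))

    records = derandomize(tables, layouts)
    summaries = combine_screens([records])
    hits = call_hits(summaries)
    per_screen = {
        t.screen_id: aggregate_genes(derandomize([t], layouts)) for t in tables
    }
    return {
        "params": params,
        "library": library,
        "layouts": layouts,
        "truth": truth,
        "geometry": geometry,
        "tables": tables,
        "records": records,
        "summaries": summaries,
        "hits": hits,
        "per_screen": per_screen,
    }
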