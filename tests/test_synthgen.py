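"""Layout generation, randomization round-trips, truth and rendering."""

import numpy as np
import pytest

from crispa.imgquant import score_plate, segment_colonies
from crispa.synthgen import (
    FORMATS,
    OFFSETS,
    GridGeometry,
    PlateLayout,
    SimParams,
    SyntheticTruth,
    colony_sv,
    generate_library,
    latin_square_4,
    planted_yellowness,
    randomize_layout,
    read_layouts,
    render_plate,
    simulate_truth,
    write_layouts,
)


def make_truth(gene_effects, plate_ids, edge_bias=(1.0,), **kw):
    defaults = dict(
        planted_group={g: "none" for g in gene_effects},
        plate_bias={p: 1.0 for p in plate_ids},
        edge_bias=edge_bias, contamination=[], missing=set(), seed=0,
    )
    defaults.update(kw)
    return SyntheticTruth(gene_effects=gene_effects, **defaults)


class TestGenerateLibrary:
    @pytest.mark.parametrize("n_genes,n_plates,last_filled", [
        (384, 1, 384),
        (4788, 13, 180),   # 4788 - 12*384 = 180
        (1, 1, 1),
        (385, 2, 1),
    ])
    def test_plate_counts(self, n_genes, n_plates, last_filled):
        plates = generate_library(n_genes)
        assert len(plates) == n_plates
        assert len(plates[-1].filled()) == last_filled
        assert all(len(p.entries) == 384 for p in plates)

    def test_left_to_right_top_to_bottom(self):
        plates = generate_library(30)
        filled = sorted(plates[0].filled())
        assert [(e.row, e.col) for e in filled[:3]] == [(0, 0), (0, 1), (0, 2)]
        assert (filled[-1].row, filled[-1].col) == (1, 5)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            generate_library(0)


class TestRandomizeLayout:
    def test_four_library_plates_make_four_screen_plates(self):
        lib = generate_library(4 * 384)
        screens = randomize_layout(lib, "randomized", seed=3)
        assert len(screens) == 4
        assert all(p.format == 1536 for p in screens)
        # each screen plate holds one replicate array of every library plate
        for p in screens:
            assert {e.source_plate_id for e in p.filled()} == \
                {q.plate_id for q in lib}

    @pytest.mark.parametrize("scheme,n_plates_per_gene", [
        ("randomized", 4), ("block", 1),
    ])
    def test_replicate_dispersion(self, scheme, n_plates_per_gene):
        lib = generate_library(100)
        screens = randomize_layout(lib, scheme, seed=5)
        where = {}
        for p in screens:
            for e in p.filled():
                where.setdefault(e.gene_id, []).append((p.plate_id, e.replicate_index))
        for gene, locs in where.items():
            assert len(locs) == 4
            assert len({pid for pid, _ in locs}) == n_plates_per_gene
            assert sorted(rep for _, rep in locs) == [1, 2, 3, 4]

    def test_positions_follow_interleave_formula(self):
        lib = generate_library(384)
        for p in randomize_layout(lib, "randomized", seed=9):
            for e in p.filled():
                dr, dc = e.row - 2 * e.source_row, e.col - 2 * e.source_col
                assert (dr, dc) in OFFSETS

    def test_latin_square_offsets_balanced(self):
        # the four replicate arrays of one library plate use each
        # interleave offset exactly once across the four screen plates
        lib = generate_library(2 * 384)
        screens = randomize_layout(lib, "randomized", seed=11)
        offsets = {}
        for p in screens:
            for e in p.filled():
                off = (e.row % 2, e.col % 2)
                offsets.setdefault(e.source_plate_id, set()).add(off)
        assert all(offs == set(OFFSETS) for offs in offsets.values())

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            randomize_layout(generate_library(10), "shuffled", seed=0)

    def test_determinism_and_seed_sensitivity(self):
        lib = generate_library(384)
        a = randomize_layout(lib, "randomized", seed=1)
        b = randomize_layout(lib, "randomized", seed=1)
        c = randomize_layout(lib, "randomized", seed=2)
        assert [p.entries for p in a] == [p.entries for p in b]
        assert any(p.entries != q.entries for p, q in zip(a, c))

    def test_layout_tsv_round_trip(self, tmp_path):
        screens = randomize_layout(generate_library(50), "randomized", seed=4)
        path = tmp_path / "layouts.tsv"
        write_layouts(screens, path)
        back = read_layouts(path)
        assert {p.plate_id: sorted(p.entries) for p in back} == \
            {p.plate_id: sorted(p.entries) for p in screens}

    def test_latin_square_property(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            sq = latin_square_4(rng)
            assert all(sorted(row) == [0, 1, 2, 3] for row in sq)
            assert all(sorted(col) == [0, 1, 2, 3] for col in sq.T)


class TestSimulateTruth:
    def test_planted_effects_echoed_exactly(self):
        layouts = randomize_layout(generate_library(384), "randomized", seed=0)
        params = SimParams(n_yellow=20, n_white=10)
        truth = simulate_truth(layouts, params, seed=0)
        yellow = truth.genes_in_group("yellow")
        assert len(yellow) == 20
        assert all(truth.gene_effects[g][0] == 3.0 for g in yellow)
        assert len(truth.genes_in_group("white")) == 10

    def test_zero_rates_give_empty_collections(self):
        layouts = randomize_layout(generate_library(96), "block", seed=0)
        params = SimParams(contamination_rate=0.0, missing_rate=0.0)
        truth = simulate_truth(layouts, params, seed=1)
        assert truth.contamination == [] and truth.missing == set()

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SimParams(contamination_rate=-0.1)
        with pytest.raises(ValueError):
            SimParams(noise_sd=-1)

    def test_determinism(self):
        layouts = randomize_layout(generate_library(96), "randomized", seed=0)
        t1 = simulate_truth(layouts, SimParams(), seed=7)
        t2 = simulate_truth(layouts, SimParams(), seed=7)
        assert t1.gene_effects == t2.gene_effects
        assert t1.missing == t2.missing and t1.contamination == t2.contamination

    def test_yellow_tail_carries_fitness_penalty(self):
        layouts = randomize_layout(generate_library(384), "randomized", seed=0)
        truth = simulate_truth(layouts, SimParams(n_yellow=20), seed=3)
        fit = [truth.gene_effects[g][1] for g in truth.genes_in_group("yellow")]
        assert np.mean(fit) < -1.0


class TestRenderPlate:
    def small_setup(self, pigments, **params_kw):
        genes = [f"G{i:02d}" for i in range(len(pigments))]
        lib = generate_library(len(genes), gene_ids=genes)
        layout = randomize_layout(lib, "block", seed=0)[0]
        effects = {g: (p, 0.0) for g, p in zip(genes, pigments)}
        truth = make_truth(effects, [layout.plate_id], **params_kw)
        geometry = GridGeometry.for_format(1536, 16)
        return layout, truth, geometry

    def test_missing_position_has_no_foreground(self):
        layout, truth, geom = self.small_setup([0.0, 0.0])
        filled = layout.filled()
        truth.missing.add((layout.plate_id, filled[0].row, filled[0].col))
        img = render_plate(layout, truth, geom, seed=0, noise_sd=0.0)
        masks = {(m.row, m.col): m for m in segment_colonies(img)}
        assert masks[(filled[0].row, filled[0].col)].size == 0
        assert masks[(filled[1].row, filled[1].col)].size > 0

    def test_white_limit_has_near_zero_saturation(self):
        s, v = colony_sv(-30.0)
        assert s < 1e-4 and v == pytest.approx(0.9, abs=0.01)

    def test_rendered_yellowness_monotone_in_pigment(self):
        pigments = [-3.0, -1.5, -0.5, 0.0, 0.5, 1.5, 3.0]
        layout, truth, geom = self.small_setup(pigments)
        img = render_plate(layout, truth, geom, seed=0, noise_sd=0.0)
        by_gene = score_plate(img, layout).groupby("gene_id")["yellowness_raw"].mean()
        scores = [by_gene[f"G{i:02d}"] for i in range(len(pigments))]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_determinism_byte_identical(self):
        layout, truth, geom = self.small_setup([0.0, 1.0, -1.0])
        a = render_plate(layout, truth, geom, seed=5)
        b = render_plate(layout, truth, geom, seed=5)
        c = render_plate(layout, truth, geom, seed=6)
        assert np.array_equal(a.pixels, b.pixels)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_oversized_colony_clipped_and_flagged(self):
        layout, truth, geom = self.small_setup([0.0])
        g = layout.filled()[0].gene_id
        truth.gene_effects[g] = (0.0, 30.0)  # huge fitness -> radius beyond pitch
        img = render_plate(layout, truth, geom, seed=0, noise_sd=0.0)
        e = layout.filled()[0]
        assert (e.row, e.col) in img.clipped

    def test_contamination_mixes_white_pixels(self):
        layout, truth, geom = self.small_setup([3.0, 3.0])
        e = layout.filled()[0]
        truth.contamination.append((layout.plate_id, e.row, e.col, 0.5))
        img = render_plate(layout, truth, geom, seed=0, noise_sd=0.0)
        df = score_plate(img, layout, quantile=None).set_index(["row", "col"])
        clean = layout.filled()[1]
        assert df.loc[(e.row, e.col), "yellowness_raw"] < \
            df.loc[(clean.row, clean.col), "yellowness_raw"]
        assert "contaminated-suspect" in str(df.loc[(e.row, e.col), "flags"])

    def test_format_mismatch_rejected(self):
        layout, truth, _ = self.small_setup([0.0])
        with pytest.raises(ValueError):
            render_plate(layout, truth, GridGeometry.for_format(384), seed=0)


class TestGeometry:
    def test_supported_formats_only(self):
        with pytest.raises(ValueError):
            GridGeometry(10, 10)
        with pytest.raises(ValueError):
            GridGeometry(16, 24, cell_px=4)

    def test_cell_centers_inside_image(self):
        for fmt in FORMATS:
            g = GridGeometry.for_format(fmt, cell_px=12)
            h, w = g.image_shape
            cy, cx = g.cell_center(g.n_rows - 1, g.n_cols - 1)
            assert 0 <= cy < h and 0 <= cx < w


def test_median_replicates_after_losses(study):
    """Under default loss rates, pooled screens keep nearly all of the 16
    replicates per gene (median 15-16)."""
    med = study["summaries"]["n_replicates"].median()
    assert 14 <= med <= 16
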