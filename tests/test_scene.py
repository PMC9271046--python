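import numpy as np
import pytest
from scipy import stats as sps

import pairfish as pf
from pairfish.scene import CapacityError, CellGeometry


def _grid(shape=(15, 100, 100)):
    return np.zeros(shape)


class TestRenderSpot:
    def test_total_added_intensity_equals_amplitude(self):
        g = _grid()
        pf.render_spot(g, (5.0, 5.0, 3.5), 1000.0, (0.08, 0.25), (0.1, 0.5))
        assert g.sum() == pytest.approx(1000.0, rel=0.01)

    def test_two_renders_at_same_center_sum(self):
        g = _grid()
        for _ in range(2):
            pf.render_spot(g, (5.0, 5.0, 3.5), 500.0, (0.08, 0.25), (0.1, 0.5))
        assert g.sum() == pytest.approx(1000.0, rel=0.01)

    def test_argmax_within_one_voxel_of_center(self):
        g = _grid()
        pf.render_spot(g, (4.23, 6.81, 3.6), 800.0, (0.08, 0.25), (0.1, 0.5))
        z, y, x = np.unravel_index(np.argmax(g), g.shape)
        assert abs(x * 0.1 + 0.05 - 4.23) <= 0.1
        assert abs(y * 0.1 + 0.05 - 6.81) <= 0.1
        assert abs(z * 0.5 - 3.6) <= 0.5

    def test_center_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside the grid"):
            pf.render_spot(_grid(), (50.0, 5.0, 3.5), 100.0,
                           (0.08, 0.25), (0.1, 0.5))


class TestAddNoise:
    def test_pure_background_is_exact_shift(self):
        g = np.full((4, 10, 10), 7.0)
        noise = pf.NoiseParams(background=3.0, gaussian_sd=0.0, poisson=False)
        out = pf.add_noise(g, noise, np.random.default_rng(0))
        assert np.array_equal(out, np.full_like(g, 10.0, dtype=np.float32))

    def test_mean_matches_prior_plus_background(self):
        g = np.full((20, 100, 100), 50.0)
        noise = pf.NoiseParams(background=10.0, gaussian_sd=4.0, poisson=True)
        out = pf.add_noise(g, noise, np.random.default_rng(1))
        se = np.sqrt(60.0 + 16.0) / np.sqrt(g.size)
        assert abs(out.mean() - 60.0) < 3 * se

    def test_no_negative_voxels_after_clamping(self):
        g = np.zeros((4, 20, 20))
        noise = pf.NoiseParams(background=0.5, gaussian_sd=5.0, poisson=False)
        out = pf.add_noise(g, noise, np.random.default_rng(2))
        assert out.min() >= 0.0


class TestPlaceTranscriptDots:
    geom = CellGeometry(center_um=(10.0, 10.0, 4.5), radius_lateral_um=4.0,
                        radius_axial_um=3.0)

    def test_zero_rates_give_empty_lists(self):
        dots, cont = pf.place_transcript_dots(
            self.geom, 0.0, 0.0, np.random.default_rng(0), 0.5, 19)
        assert len(dots) == 0 and len(cont) == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            pf.place_transcript_dots(self.geom, -1.0, 0.0,
                                     np.random.default_rng(0), 0.5, 19)

    def test_midplane_rate_calibration(self):
        # expected dots whose nearest plane is the mid-plane equals the rate
        rate, reps = 6.0, 300
        rng = np.random.default_rng(3)
        mid_counts = []
        for _ in range(reps):
            dots, _ = pf.place_transcript_dots(self.geom, rate, 0.0, rng,
                                               0.5, 19)
            if len(dots):
                planes = np.round(dots[:, 2] / 0.5).astype(int)
                mid_counts.append(int((planes == 9).sum()))
            else:
                mid_counts.append(0)
        se = np.sqrt(rate / reps)
        assert abs(np.mean(mid_counts) - rate) < 3 * se

    def test_dots_inside_cytoplasm_only(self):
        rng = np.random.default_rng(4)
        dots, _ = pf.place_transcript_dots(self.geom, 20.0, 0.0, rng, 0.5, 19)
        assert self.geom.in_cell(dots).all()
        assert not self.geom.in_nucleus(dots).any()

    def test_contamination_on_surface_shell(self):
        rng = np.random.default_rng(5)
        _, cont = pf.place_transcript_dots(self.geom, 0.0, 30.0, rng, 0.5, 19)
        assert len(cont) > 0
        assert self.geom.in_cell(cont).all()
        # normalized spheroid radius close to 1 (the shell)
        cx, cy, cz = self.geom.center_um
        r = np.sqrt(((cont[:, 0] - cx) / 4.0) ** 2
                    + ((cont[:, 1] - cy) / 4.0) ** 2
                    + ((cont[:, 2] - cz) / 3.0) ** 2)
        assert (r > 0.9).all()


class TestGenerateScene:
    def test_identical_config_and_seed_bit_identical(self):
        cfg = pf.SceneConfig(n_cells_per_stage=2, seed=42)
        a, b = pf.generate_scene(cfg), pf.generate_scene(cfg)
        for fa, fb in zip(a.fields, b.fields):
            assert np.array_equal(fa.stack.voxels, fb.stack.voxels)
            assert np.array_equal(fa.masks, fb.masks)
        assert a.cells.equals(b.cells)
        assert a.truth.cells.equals(b.truth.cells)
        assert a.truth.spots.equals(b.truth.spots)

    def test_all_cells_paired_under_degenerate_probability(self):
        cfg = pf.SceneConfig(n_cells_per_stage=3, pairing_prob=1.0,
                             sister_split_prob=0.0, seed=1)
        scene = pf.generate_scene(cfg)
        assert (scene.truth.cells["true_state"] == "paired").all()
        assert (scene.truth.cells["true_n_foci"] == 1).all()
        assert (scene.truth.cells["true_distance_um"] == 0).all()

    def test_hemizygote_has_single_locus_focus(self):
        cfg = pf.SceneConfig(n_cells_per_stage=3, n_alleles=1,
                             sister_split_prob=0.0, seed=2)
        scene = pf.generate_scene(cfg)
        assert (scene.truth.cells["true_n_foci"] == 1).all()
        per_cell = scene.truth.spots.query("channel == 'dna'").groupby(
            "cell_id").size()
        assert (per_cell == 1).all()

    def test_paired_fraction_within_exact_binomial_ci(self):
        # 500 cells at pairing probability 0.3; lightweight geometry so the
        # check exercises the generator's sampling, not the renderer
        n, p = 500, 0.3
        cfg = pf.SceneConfig(
            n_cells_per_stage={"GSC": 0, "GB": n, "SG2_4": 0, "SG8_16": 0,
                               "SC": 0, "CySC": 0},
            pairing_prob=p, sister_split_prob=0.0, mrna_rate=0.0,
            contamination_rate=0.0, cell_radius_um=(2.0, 1.5),
            cell_spacing_um=5.5, cells_per_field=100,
            unpaired_distance_dist=(1.0, 0.3), seed=3,
        )
        scene = pf.generate_scene(cfg)
        k = int((scene.truth.cells["true_state"] == "paired").sum())
        lo, hi = sps.binom.interval(0.99, n, p)
        assert lo <= k <= hi

    def test_rendered_amplitude_conserved_without_noise(self, clean_scene):
        # channel totals equal the summed ground-truth amplitudes within 1%
        spots = clean_scene.truth.spots
        for fov in clean_scene.fields:
            for ch in ("dna", "intron", "exon"):
                expected = spots.query(
                    "field == @fov.name and channel == @ch")["amplitude"].sum()
                assert fov.stack.channel(ch).sum() == pytest.approx(
                    expected, rel=0.01)

    def test_masks_are_disjoint_and_complete(self, small_scene):
        for fov in small_scene.fields:
            labels = set(np.unique(fov.masks)) - {0}
            expected = set(
                small_scene.cells.query("field == @fov.name")["mask_label"])
            assert labels == expected

    def test_field_capacity_error(self):
        with pytest.raises(CapacityError):
            pf.generate_scene(pf.SceneConfig(cells_per_field=101))

    def test_overlapping_geometry_rejected(self):
        with pytest.raises(CapacityError, match="overlap"):
            pf.generate_scene(pf.SceneConfig(cell_spacing_um=6.0,
                                             cell_radius_um=(4.0, 3.0)))
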