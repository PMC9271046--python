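import numpy as np
import pytest

import pairfish as pf
from pairfish.config import DetectionParams
from pairfish.detect import detect_foci

PSF = (0.08, 0.25)
VOX = (0.1, 0.5)


def _stack(voxels):
    return pf.ImageStack(voxels=voxels[None].astype(np.float32),
                         lateral_size_um=0.1, z_step_um=0.5,
                         channel_names=("exon",))


def _ball_mask(shape, center_um, r_lat=3.0, r_ax=2.5, label=1):
    nz, ny, nx = shape
    zs = np.arange(nz)[:, None, None] * 0.5
    ys = (np.arange(ny)[None, :, None] + 0.5) * 0.1
    xs = (np.arange(nx)[None, None, :] + 0.5) * 0.1
    cx, cy, cz = center_um
    inside = (((xs - cx) / r_lat) ** 2 + ((ys - cy) / r_lat) ** 2
              + ((zs - cz) / r_ax) ** 2) <= 1
    m = np.zeros(shape, dtype=np.int32)
    m[inside] = label
    return m


def _noisy(g, seed=0, bg=20.0):
    rng = np.random.default_rng(seed)
    return pf.add_noise(g, pf.NoiseParams(background=bg), rng)


class TestDetectFoci:
    def test_two_separated_foci_found_with_subvoxel_accuracy(self):
        g = np.zeros((13, 90, 90))
        c1, c2 = (3.52, 4.51, 3.1), (5.23, 4.48, 3.4)  # 1.7 um apart
        pf.render_spot(g, c1, 1500.0, PSF, VOX)
        pf.render_spot(g, c2, 1500.0, PSF, VOX)
        stack = _stack(_noisy(g))
        masks = _ball_mask(g.shape, (4.5, 4.5, 3.0))
        spots = detect_foci(stack, "exon", masks)
        assert len(spots) == 2
        for cx, cy, _ in (c1, c2):
            d = np.hypot(spots["x_um"] - cx, spots["y_um"] - cy).min()
            assert d <= 0.1  # within one voxel laterally

    def test_subresolution_pair_merges_to_one(self):
        # the operational definition of "paired": one resolvable punctum
        g = np.zeros((13, 90, 90))
        pf.render_spot(g, (4.45, 4.5, 3.0), 1500.0, PSF, VOX)
        pf.render_spot(g, (4.55, 4.5, 3.0), 1500.0, PSF, VOX)
        spots = detect_foci(_stack(_noisy(g)), "exon",
                            _ball_mask(g.shape, (4.5, 4.5, 3.0)))
        assert len(spots) == 1

    def test_pure_noise_yields_no_detections(self):
        g = np.zeros((13, 90, 90))
        spots = detect_foci(_stack(_noisy(g, seed=3)), "exon",
                            _ball_mask(g.shape, (4.5, 4.5, 3.0)))
        assert len(spots) == 0

    def test_shape_mismatch_rejected(self):
        g = np.zeros((13, 90, 90))
        with pytest.raises(ValueError, match="shape"):
            detect_foci(_stack(g), "exon", np.zeros((13, 80, 80)))


class TestIntegrateIntensity:
    def _measure(self, centers_amps, bg=0.0):
        g = np.zeros((13, 90, 90))
        for c, a in centers_amps:
            pf.render_spot(g, c, a, PSF, VOX)
        stack = _stack(g + bg)
        masks = _ball_mask(g.shape, (4.5, 4.5, 3.0))
        return detect_foci(stack, "exon", masks)

    @pytest.mark.parametrize("zc", [3.0, 3.25])  # on-plane and between-plane
    def test_amplitude_recovered_within_five_percent(self, zc):
        spots = self._measure([((4.5, 4.5, zc), 2000.0)])
        assert len(spots) == 1
        assert spots["integrated_intensity"].iloc[0] == pytest.approx(
            2000.0, rel=0.05)
        assert spots["plane_span"].iloc[0] in (1, 2, 3)

    def test_constant_background_removed(self):
        spots = self._measure([((4.5, 4.5, 3.0), 2000.0)], bg=40.0)
        assert spots["integrated_intensity"].iloc[0] == pytest.approx(
            2000.0, rel=0.05)

    def test_colocalized_alleles_integrate_to_double(self):
        # a paired punctum carries two alleles' label: twice the intensity
        spots = self._measure([((4.5, 4.5, 3.0), 1200.0),
                               ((4.5, 4.5, 3.0), 1200.0)])
        assert len(spots) == 1
        assert spots["integrated_intensity"].iloc[0] == pytest.approx(
            2400.0, rel=0.05)

    def test_integration_is_linear_in_amplitude(self):
        lo = self._measure([((4.5, 4.5, 3.1), 1000.0)])
        hi = self._measure([((4.5, 4.5, 3.1), 2000.0)])
        ratio = hi["integrated_intensity"].iloc[0] / \
            lo["integrated_intensity"].iloc[0]
        assert ratio == pytest.approx(2.0, rel=0.01)


class TestDotCounting:
    def test_empty_cell_counts_zero(self):
        g = np.zeros((13, 90, 90))
        masks = _ball_mask(g.shape, (4.5, 4.5, 3.0))
        stack = _stack(_noisy(g, seed=5))
        assert pf.count_midplane_dots(stack, masks, 1, 6) == 0

    def test_bright_multimolecule_dot_counts_as_one(self):
        # a dot at 3x the standard amplitude still contributes exactly 1
        g = np.zeros((13, 90, 90))
        pf.render_spot(g, (3.5, 4.5, 3.0), 3 * 1200.0, PSF, VOX)
        pf.render_spot(g, (5.5, 4.5, 3.0), 1200.0, PSF, VOX)
        stack = _stack(_noisy(g, seed=6))
        masks = _ball_mask(g.shape, (4.5, 4.5, 3.0))
        assert pf.count_midplane_dots(stack, masks, 1, 6) == 2

    def test_molecule_spanning_planes_counts_once_wholecell(self):
        g = np.zeros((13, 90, 90))
        pf.render_spot(g, (4.5, 4.5, 3.25), 1500.0, PSF, VOX)  # between planes
        stack = _stack(_noisy(g, seed=7))
        masks = _ball_mask(g.shape, (4.5, 4.5, 3.0))
        assert pf.count_wholecell_dots(stack, masks, 1) == 1

    def test_wholecell_equals_truth_on_sparse_noise_free_scene(self, clean_scene):
        # exact equality holds wherever the true dots are mutually resolvable
        # (no pair closer than the optical merge range); unresolvable pairs
        # merge by design, so those few cells are checked for the merge count
        spots = clean_scene.truth.spots.query("channel == 'exon'")
        resolvable = {}
        for cell_id, sub in spots.groupby("cell_id"):
            xy = sub[["x_um", "y_um"]].to_numpy()
            zp = sub["z_plane"].to_numpy()
            close = 0
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    d_lat = np.hypot(*(xy[i] - xy[j]))
                    if d_lat < 0.3 and abs(zp[i] - zp[j]) <= 1:
                        close += 1
            resolvable[cell_id] = close == 0
        counts = pf.count_dots_for_cells(clean_scene.fields, clean_scene.cells,
                                         "exon", mode="wholecell")
        truth = clean_scene.truth.cells.set_index("cell_id")
        merged = counts.join(truth[["true_wholecell_dots"]], on="cell_id")
        clean = merged[merged["cell_id"].map(resolvable).fillna(True)]
        assert len(clean) >= 0.6 * len(merged)
        assert (clean["count"] == clean["true_wholecell_dots"]).all()

    def test_midplane_out_of_range_rejected(self, clean_scene):
        fov = clean_scene.fields[0]
        with pytest.raises(ValueError, match="mid_plane"):
            pf.count_midplane_dots(fov.stack, fov.masks, 1, 99)

    def test_counts_translation_invariant(self, clean_scene):
        # shifting the whole field by whole voxels leaves counts unchanged
        fov = clean_scene.fields[0]
        cells = clean_scene.cells.query("field == @fov.name")
        shift = (0, 7, -5)
        moved = pf.ImageStack(
            voxels=np.roll(fov.stack.voxels, shift, axis=(1, 2, 3)),
            lateral_size_um=0.1, z_step_um=0.5,
            channel_names=fov.stack.channel_names)
        moved_masks = np.roll(fov.masks, shift, axis=(0, 1, 2))
        for rec in cells.itertuples():
            a = pf.count_midplane_dots(fov.stack, fov.masks,
                                       int(rec.mask_label), int(rec.mid_plane))
            b = pf.count_midplane_dots(moved, moved_masks,
                                       int(rec.mask_label), int(rec.mid_plane))
            assert a == b


def test_midplane_mean_tracks_ground_truth():
    # sparse smFISH: the detected mean must sit within 3 SE of the truth mean
    cfg = pf.SceneConfig(
        n_cells_per_stage={"GSC": 0, "GB": 200, "SG2_4": 0, "SG8_16": 0,
                           "SC": 0, "CySC": 0},
        mrna_rate=3.0, contamination_rate=0.0, seed=31)
    scene = pf.generate_scene(cfg)
    counts = pf.count_dots_for_cells(scene.fields, scene.cells, "exon",
                                     mode="midplane")
    truth = scene.truth.cells.set_index("cell_id")
    merged = counts.join(truth[["true_mid_dots"]], on="cell_id")
    se = np.sqrt(merged["true_mid_dots"].var(ddof=1) / len(merged))
    assert abs(merged["count"].mean()
               - merged["true_mid_dots"].mean()) < 3 * se
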