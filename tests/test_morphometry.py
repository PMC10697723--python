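"""Morphometry: segmentation, shape, invasion, adhesions, collagen, motility."""
import numpy as np
import pandas as pd
import pytest
from skimage import draw as skdraw

from vesselflux import (
    LabelMask,
    SimulationConfig,
    aspect_ratio_map,
    collagen_contraction_ratio,
    count_adhesions,
    invasion_distances,
    motility_metrics,
    segment_cells,
    shape_descriptors,
)
from vesselflux.exceptions import ParameterError
from vesselflux.synthetic import (
    simulate_adhesion_image,
    simulate_contraction_field,
    simulate_disk_field,
    simulate_invasion_field,
    simulate_tracks,
)


def disk_mask(radius=30, pad=10, pixel_size=1.0):
    size = 2 * (radius + pad)
    img = np.zeros((size, size), dtype=np.int32)
    rr, cc = skdraw.disk((size // 2, size // 2), radius)
    img[rr, cc] = 1
    return LabelMask(img, pixel_size)


def ellipse_mask(a=60, b=15, pad=10, rotation=0.0):
    size = 2 * (a + pad)
    img = np.zeros((size, size), dtype=np.int32)
    rr, cc = skdraw.ellipse(size // 2, size // 2, a, b, rotation=rotation)
    img[rr, cc] = 1
    return LabelMask(img, 1.0)


class TestSegmentation:
    def test_blank_image_yields_empty_mask(self):
        mask = segment_cells(np.zeros((64, 64)), pixel_size=1.0)
        assert mask.n_cells == 0

    def test_disk_field_fully_recovered_with_good_iou(self, cfg):
        image, truth = simulate_disk_field(cfg, n_disks=50, radius_px=10, snr=10)
        mask = segment_cells(image, pixel_size=cfg.pixel_size, blur_sigma=1.5)
        assert mask.n_cells == 50
        for rid in range(1, 51):
            t = truth.labels == rid
            overlap_labels = mask.labels[t]
            lab = np.bincount(overlap_labels[overlap_labels > 0]).argmax()
            m = mask.labels == lab
            iou = (t & m).sum() / (t | m).sum()
            assert iou > 0.7

    def test_separated_disks_get_distinct_labels(self):
        img = np.zeros((80, 80))
        rr, cc = skdraw.disk((20, 20), 8)
        img[rr, cc] = 1.0
        rr, cc = skdraw.disk((60, 60), 8)
        img[rr, cc] = 1.0
        mask = segment_cells(img, pixel_size=1.0, blur_sigma=0.5)
        assert mask.n_cells == 2


class TestShapeDescriptors:
    def test_disk_is_round(self):
        rec = shape_descriptors(disk_mask(radius=30)).iloc[0]
        assert rec["circularity"] >= 0.9
        assert rec["aspect_ratio"] <= 1.1

    def test_four_to_one_ellipse_aspect_ratio(self):
        rec = shape_descriptors(ellipse_mask(a=60, b=15)).iloc[0]
        assert 3.6 <= rec["aspect_ratio"] <= 4.4

    def test_single_pixel_object_excluded(self):
        img = np.zeros((32, 32), dtype=np.int32)
        img[5, 5] = 1
        rr, cc = skdraw.disk((20, 20), 6)
        img[rr, cc] = 2
        records = shape_descriptors(LabelMask(img, 1.0))
        assert list(records["cell_id"]) == [2]

    def test_border_touching_cell_flagged_not_dropped(self):
        img = np.zeros((40, 40), dtype=np.int32)
        rr, cc = skdraw.disk((0, 20), 8, shape=img.shape)
        img[rr, cc] = 1
        rec = shape_descriptors(LabelMask(img, 1.0))
        assert len(rec) == 1 and bool(rec.iloc[0]["touches_border"])

    def test_circularity_capped_with_raw_retained(self):
        records = shape_descriptors(disk_mask(radius=30))
        assert records["circularity"].iloc[0] <= 1.0
        assert records["circularity_raw"].iloc[0] <= 1.05

    def test_rotation_invariance_within_rasterization_tolerance(self):
        r0 = shape_descriptors(ellipse_mask(a=60, b=15, rotation=0.0)).iloc[0]
        r90 = shape_descriptors(ellipse_mask(a=60, b=15, rotation=np.pi / 2)).iloc[0]
        assert r90["aspect_ratio"] == pytest.approx(r0["aspect_ratio"], rel=0.03)
        assert r90["circularity"] == pytest.approx(r0["circularity"], rel=0.03)

    def test_metrics_invariant_to_translation(self):
        img = np.zeros((100, 100), dtype=np.int32)
        rr, cc = skdraw.ellipse(30, 30, 20, 8)
        img[rr, cc] = 1
        shifted = np.roll(np.roll(img, 25, axis=0), 30, axis=1)
        a = shape_descriptors(LabelMask(img, 1.0)).iloc[0]
        b = shape_descriptors(LabelMask(shifted, 1.0)).iloc[0]
        for key in ("area_um2", "perimeter_um", "circularity", "aspect_ratio"):
            assert b[key] == pytest.approx(a[key], rel=1e-9)

    def test_pixel_size_scaling_preserves_micron_values(self):
        m1 = disk_mask(radius=30, pixel_size=1.0)
        m2 = disk_mask(radius=15, pixel_size=2.0)
        a = shape_descriptors(m1).iloc[0]
        b = shape_descriptors(m2).iloc[0]
        assert b["area_um2"] == pytest.approx(a["area_um2"], rel=0.05)
        assert b["perimeter_um"] == pytest.approx(a["perimeter_um"], rel=0.05)


class TestInvasionDistances:
    def test_edge_cells_have_zero_mean(self):
        res = invasion_distances(np.full(5, 42.0), channel_edge_x=42.0)
        assert res.mean == 0.0

    def test_signed_arithmetic(self):
        res = invasion_distances(np.array([100.0, 200.0, 300.0]), 100.0)
        np.testing.assert_array_equal(res.distances, [0.0, 100.0, 200.0])
        assert res.mean == 100.0

    def test_normalization_to_control_mean(self):
        res = invasion_distances(np.array([100.0, 300.0]), 100.0, control_mean=100.0)
        np.testing.assert_array_equal(res.normalized, [0.0, 2.0])

    def test_empty_input_raises(self):
        with pytest.raises(ParameterError):
            invasion_distances(np.array([]), 0.0)

    def test_bias_detected_against_unbiased_fields(self):
        """A displacement bias equal to 2x the placement SD separates the
        group means in every seeded replicate here (acceptance covers 20)."""
        wins = 0
        for seed in range(5):
            cfg_b = SimulationConfig(seed=seed)
            cfg_u = SimulationConfig(seed=seed + 1000)
            _, biased = simulate_invasion_field(
                cfg_b, n_cells=80, bias=200.0, placement_sd_um=100.0
            )
            _, unbiased = simulate_invasion_field(
                cfg_u, n_cells=80, bias=0.0, placement_sd_um=100.0
            )
            wins += biased["invasion_distance_um"].mean() > unbiased[
                "invasion_distance_um"
            ].mean()
        assert wins == 5


class TestAdhesions:
    def test_uniform_image_has_no_adhesions(self):
        mask = disk_mask(radius=20)
        counts = count_adhesions(np.ones(mask.labels.shape), mask)
        assert counts["adhesion_count"].iloc[0] == 0

    def test_seeded_puncta_counts_recovered(self):
        cfg = SimulationConfig(seed=9)
        mask, _ = simulate_invasion_field(
            cfg, n_cells=10, mean_radius_um=25.0, ar_gain_per_100um=0.0,
            field_size_um=(600.0, 600.0), placement_sd_um=120.0,
        )
        wanted = {cid: (3 if cid % 2 else 8) for cid in range(1, 11)}
        pfak = simulate_adhesion_image(cfg, mask, wanted, snr=10)
        counts = count_adhesions(pfak, mask, min_size_um2=6.0)
        hits = sum(
            counts.set_index("cell_id").loc[cid, "adhesion_count"] == k
            for cid, k in wanted.items()
        )
        assert hits >= 9  # >= 90% of cells exact

    def test_count_decreases_monotonically_with_min_size(self):
        cfg = SimulationConfig(seed=10)
        mask = disk_mask(radius=25)
        pfak = simulate_adhesion_image(cfg, mask, {1: 6}, snr=10)
        sizes = [0.2, 2.0, 10.0, 50.0]
        counts = [
            count_adhesions(pfak, mask, min_size_um2=s)["adhesion_count"].iloc[0]
            for s in sizes
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestCollagenContraction:
    def test_homogeneous_field_gives_unity_ratio(self):
        mask = disk_mask(radius=20, pad=40)
        result = collagen_contraction_ratio(np.ones(mask.labels.shape), mask)
        assert result["ratio"] == pytest.approx(1.0, abs=0.02)

    def test_two_fold_peripheral_contrast_recovered(self):
        cfg = SimulationConfig(seed=12)
        mask = disk_mask(radius=25, pad=80)
        img = simulate_contraction_field(cfg, mask, peripheral_contrast=2.0)
        result = collagen_contraction_ratio(img, mask)
        assert 1.8 <= result["ratio"] <= 2.2

    def test_invariant_to_global_intensity_scaling(self):
        cfg = SimulationConfig(seed=12)
        mask = disk_mask(radius=25, pad=80)
        img = simulate_contraction_field(cfg, mask, peripheral_contrast=1.5)
        r1 = collagen_contraction_ratio(img, mask)["ratio"]
        r2 = collagen_contraction_ratio(img * 7.3, mask)["ratio"]
        assert r2 == pytest.approx(r1, rel=1e-9)

    def test_dense_field_without_bulk_raises(self):
        mask = disk_mask(radius=28, pad=2)
        with pytest.raises(ParameterError, match="larger field"):
            collagen_contraction_ratio(np.ones(mask.labels.shape), mask,
                                       ring_width_um=30.0)


class TestMotility:
    def test_stationary_track_has_zero_speed(self):
        tracks = pd.DataFrame(
            {"track_id": 0, "t_s": [0, 1200, 2400], "x_um": 0.0, "y_um": 0.0}
        )
        speeds, _ = motility_metrics(tracks)
        assert speeds["mean_speed_um_min"].iloc[0] == 0.0

    def test_straight_track_speed_in_um_per_min(self):
        tracks = pd.DataFrame(
            {"track_id": 1, "t_s": [0.0, 1200.0], "x_um": [0.0, 10.0], "y_um": 0.0}
        )
        speeds, _ = motility_metrics(tracks)
        assert speeds["mean_speed_um_min"].iloc[0] == pytest.approx(0.5)

    def test_duplicate_timestamps_rejected(self):
        tracks = pd.DataFrame(
            {"track_id": 0, "t_s": [0.0, 0.0, 10.0], "x_um": [0, 1, 2], "y_um": 0.0}
        )
        with pytest.raises(ParameterError):
            motility_metrics(tracks)

    def test_random_walk_msd_slope_matches_theory(self):
        """MSD(t) of an isotropic 2D walk grows as 2 sigma^2 t / dt."""
        cfg = SimulationConfig(seed=21)
        sigma, dt = 5.0, 1200.0
        tracks = simulate_tracks(cfg, n_tracks=200, n_steps=30, dt_s=dt,
                                 step_sd_um=sigma)
        _, paths = motility_metrics(tracks)
        msd = paths.assign(r2=paths.x_um**2 + paths.y_um**2).groupby("t_s")["r2"].mean()
        slope = np.polyfit(msd.index.to_numpy(), msd.to_numpy(), 1)[0]
        assert slope == pytest.approx(2 * sigma**2 / dt, rel=0.15)

    def test_paths_are_origin_centered(self):
        cfg = SimulationConfig(seed=22)
        tracks = simulate_tracks(cfg, n_tracks=3, n_steps=5)
        _, paths = motility_metrics(tracks + 0)  # copy
        starts = paths.groupby("track_id").first()
        assert (starts[["x_um", "y_um"]] == 0).all().all()


class TestAspectRatioMap:
    @staticmethod
    def _two_cell_setup(ar_values):
        img = np.zeros((60, 120), dtype=np.int32)
        rr, cc = skdraw.disk((30, 30), 10)
        img[rr, cc] = 1
        rr, cc = skdraw.disk((30, 90), 10)
        img[rr, cc] = 2
        mask = LabelMask(img, 1.0)
        records = pd.DataFrame({"cell_id": [1, 2], "aspect_ratio": ar_values})
        return mask, records

    def test_equal_ar_gives_single_color(self):
        mask, records = self._two_cell_setup([2.0, 2.0])
        rgb, _ = aspect_ratio_map(mask, records, ar_range=(1.0, 4.0))
        c1 = rgb[mask.labels == 1][0]
        c2 = rgb[mask.labels == 2][0]
        np.testing.assert_array_equal(c1, c2)

    def test_extreme_ars_map_to_colormap_ends(self):
        mask, records = self._two_cell_setup([1.0, 4.0])
        rgb, meta = aspect_ratio_map(mask, records)
        import matplotlib

        cmap = matplotlib.colormaps[meta["colormap"]].resampled(256)
        np.testing.assert_allclose(rgb[mask.labels == 1][0], cmap(0)[:3])
        np.testing.assert_allclose(rgb[mask.labels == 2][0], cmap(255)[:3])

    def test_colors_decode_back_to_ar_within_quantization(self):
        mask, records = self._two_cell_setup([1.7, 3.2])
        rgb, meta = aspect_ratio_map(mask, records, ar_range=(1.0, 4.0))
        import matplotlib

        cmap = matplotlib.colormaps[meta["colormap"]].resampled(256)
        lut = np.array([cmap(i)[:3] for i in range(256)])
        step = (meta["vmax"] - meta["vmin"]) / 255
        for cell_id, true_ar in zip([1, 2], [1.7, 3.2]):
            color = rgb[mask.labels == cell_id][0]
            level = np.argmin(((lut - color) ** 2).sum(axis=1))
            decoded = meta["vmin"] + level * step
            assert decoded == pytest.approx(true_ar, abs=step)

    def test_missing_records_raise(self):
        mask, records = self._two_cell_setup([1.0, 2.0])
        with pytest.raises(ParameterError):
            aspect_ratio_map(mask, records.iloc[:1])
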