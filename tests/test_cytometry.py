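import itertools
import math

import numpy as np
import pandas as pd
import pytest

import gradientchip as gc
from gradientchip.errors import DegenerateGradientError, RegistrationError


def _blob_image(rng, shape=(64, 64), n_blobs=6):
    img = np.zeros(shape)
    for _ in range(n_blobs):
        y, x = rng.uniform(12, shape[0] - 12), rng.uniform(12, shape[1] - 12)
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        img += np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / 18.0)
    return img


def _disk(shape, cy, cx, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return ((yy - cy) ** 2 + (xx - cx) ** 2 <= r**2).astype(float)


class TestRegistration:
    def test_identical_images_zero_shift(self):
        img = _blob_image(np.random.default_rng(0))
        (dx, dy), reg = gc.register_translation(img, img)
        assert (dx, dy) == (0, 0)
        assert np.allclose(reg, img)

    def test_known_integer_shift_recovered(self):
        img = _blob_image(np.random.default_rng(1))
        moved = np.roll(np.roll(img, 5, axis=0), 3, axis=1)  # displaced (+3, +5)
        (dx, dy), reg = gc.register_translation(img, moved)
        assert (dx, dy) == (3, 5)
        assert np.allclose(reg[8:-8, 8:-8], img[8:-8, 8:-8])

    def test_noisy_shift_matches_exhaustive_search(self):
        rng = np.random.default_rng(2)
        img = _blob_image(rng)
        moved = np.roll(np.roll(img, 5, axis=0), 3, axis=1)
        moved = moved + rng.normal(0, 0.05 * np.ptp(img), img.shape)
        (dx, dy), _ = gc.register_translation(img, moved)

        # independent oracle: brute-force integer-shift correlation search
        best, best_score = None, -np.inf
        for sy, sx in itertools.product(range(-8, 9), repeat=2):
            shifted = np.roll(np.roll(moved, -sy, axis=0), -sx, axis=1)
            score = float((shifted * img).sum())
            if score > best_score:
                best_score, best = score, (sx, sy)
        assert (dx, dy) == best == (3, 5)

    def test_flat_image_rejected(self):
        flat = np.zeros((32, 32))
        with pytest.raises(RegistrationError):
            gc.register_translation(flat, flat)


class TestSegment:
    def test_blank_image_gives_empty_labelmap(self):
        labels = gc.segment(np.zeros((64, 64)))
        assert labels.max() == 0

    def test_two_separated_disks(self):
        img = 100.0 * (_disk((128, 128), 30, 30, 12) + _disk((128, 128), 90, 95, 12))
        labels = gc.segment(img, min_area_px=20)
        assert labels.max() == 2

    def test_touching_disks_split_by_watershed(self):
        # centers 1.8 r apart: ~20% overlap of a radius
        r = 14
        img = 100.0 * np.maximum(_disk((96, 128), 48, 50, r), _disk((96, 128), 48, 75, r))
        labels = gc.segment(img, min_area_px=20, split_touching=True, min_distance_px=8)
        assert labels.max() == 2
        meas = gc.measure(labels).sort_values("x_px")
        assert abs(meas.iloc[0]["x_px"] - 50) < 3 and abs(meas.iloc[0]["y_px"] - 48) < 3
        assert abs(meas.iloc[1]["x_px"] - 75) < 3 and abs(meas.iloc[1]["y_px"] - 48) < 3

    def test_labels_consecutive(self):
        rng = np.random.default_rng(3)
        img = np.zeros((256, 256))
        for _ in range(8):
            img += 100.0 * _disk(img.shape, rng.uniform(20, 236), rng.uniform(20, 236), 9)
        labels = gc.segment(np.minimum(img, 100.0), min_area_px=20)
        found = np.unique(labels)
        assert found[0] == 0
        assert np.array_equal(found[1:], np.arange(1, labels.max() + 1))


class TestMeasure:
    def test_circle_has_near_zero_eccentricity(self):
        labels = _disk((64, 64), 32, 32, 20).astype(np.int32)
        m = gc.measure(labels)
        assert m.iloc[0]["eccentricity"] < 0.05

    def test_two_to_one_ellipse_eccentricity(self):
        yy, xx = np.mgrid[:128, :128]
        labels = (((xx - 64) / 40.0) ** 2 + ((yy - 64) / 20.0) ** 2 <= 1.0).astype(np.int32)
        m = gc.measure(labels)
        assert m.iloc[0]["eccentricity"] == pytest.approx(math.sqrt(1 - 0.25), abs=0.02)

    def test_disk_area_matches_analytic(self):
        labels = _disk((64, 64), 32, 32, 20).astype(np.int32)
        m = gc.measure(labels)
        assert m.iloc[0]["area_px"] == pytest.approx(math.pi * 400.0, rel=0.05)

    def test_eccentricity_scale_invariant(self):
        yy, xx = np.mgrid[:128, :128]
        small = (((xx - 40) / 24.0) ** 2 + ((yy - 40) / 15.0) ** 2 <= 1.0).astype(np.int32)
        yy, xx = np.mgrid[:256, :256]
        big = (((xx - 100) / 48.0) ** 2 + ((yy - 100) / 30.0) ** 2 <= 1.0).astype(np.int32)
        e_small = gc.measure(small).iloc[0]["eccentricity"]
        e_big = gc.measure(big).iloc[0]["eccentricity"]
        assert abs(e_small - e_big) < 0.03


class TestSegmentationRecovery:
    def test_recovers_ground_truth_cells_and_areas(
        self, default_dataset, default_pipeline_config
    ):
        """Default synthetic frame: >= 90% of cells found (centroid within
        5 px) and median area error < 10%."""
        cfg = default_pipeline_config
        gt = default_dataset.ground_truth
        gt0 = gt[gt["time_min"] == 0.0]
        labels = gc.segment(
            default_dataset.green[0].astype(float),
            smoothing_sigma=cfg.segmentation.smoothing_sigma,
            min_area_px=cfg.segmentation.min_area_px,
            split_touching=cfg.segmentation.split_touching,
            min_distance_px=cfg.segmentation.min_distance_px,
        )
        meas = gc.measure(labels)
        gx = cfg.imaging.um_to_px(gt0["x_um"].to_numpy())
        gy = cfg.imaging.um_to_px(gt0["y_um"].to_numpy())
        areas_px = gt0["area_um2"].to_numpy() / cfg.imaging.pixel_size_um**2

        rel_errors, found = [], 0
        mx = meas["x_px"].to_numpy()
        my = meas["y_px"].to_numpy()
        for x, y, a in zip(gx, gy, areas_px):
            d = np.hypot(mx - x, my - y)
            k = int(np.argmin(d))
            if d[k] <= 5.0:
                found += 1
                rel_errors.append(abs(meas.iloc[k]["area_px"] - a) / a)
        assert found >= 0.9 * len(gt0)
        assert np.median(rel_errors) < 0.10


def _frame(points):
    return pd.DataFrame(
        [
            {"label": i + 1, "x_px": x, "y_px": y, "area_px": 100, "eccentricity": 0.5}
            for i, (x, y) in enumerate(points)
        ],
        columns=["label", "x_px", "y_px", "area_px", "eccentricity"],
    )


class TestTrack:
    def test_single_drifting_object_complete_track(self):
        frames = [_frame([(10.0 + 4 * i, 20.0)]) for i in range(5)]
        tracks = gc.track(frames, max_displacement_px=10)
        assert tracks["track_id"].nunique() == 1
        assert (tracks["status"] == "complete").all()

    def test_disappearing_object_truncated(self):
        frames = [_frame([(10.0, 10.0), (50.0, 50.0)]) for _ in range(3)]
        frames += [_frame([(10.0, 10.0)]) for _ in range(2)]
        tracks = gc.track(frames, max_displacement_px=10)
        lengths = tracks.groupby("track_id").size()
        assert sorted(lengths) == [3, 5]
        short = lengths.idxmin()
        assert (tracks[tracks["track_id"] == short]["status"] == "truncated").all()
        assert (tracks[tracks["track_id"] != short]["status"] == "complete").all()

    def test_jump_beyond_max_displacement_opens_new_track(self):
        frames = [_frame([(10.0, 10.0)]), _frame([(90.0, 90.0)])]
        tracks = gc.track(frames, max_displacement_px=20)
        assert tracks["track_id"].nunique() == 2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_assignment_matches_brute_force_optimum(self, seed):
        """Hungarian linking equals exhaustive minimum-total-distance matching."""
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 7)
        p0 = rng.uniform(0, 60, size=(n, 2))
        p1 = p0 + rng.normal(0, 4, size=(n, 2))
        tracks = gc.track([_frame(p0), _frame(p1)], max_displacement_px=1e9)

        cost = np.linalg.norm(p0[:, None, :] - p1[None, :, :], axis=2)
        best_perm = min(
            itertools.permutations(range(n)), key=lambda p: sum(cost[i, p[i]] for i in range(n))
        )
        linked = tracks.pivot(index="track_id", columns="frame", values="label").dropna()
        got = {(int(a) - 1, int(b) - 1) for a, b in linked[[0, 1]].to_numpy()}
        assert got == {(i, best_perm[i]) for i in range(n)}


class TestQuantifyGradient:
    def test_noiseless_ramp_is_linear_with_full_span(self):
        img = np.tile(np.linspace(1000.0, 100.0, 200), (100, 1))
        mask = np.ones_like(img, bool)
        prof = gc.quantify_gradient(img, mask, pixel_size_um=2.0, edge_trim_px=0, median_size=1)
        assert prof.intensity_pct[0] == pytest.approx(100.0, abs=3.0)
        assert prof.intensity_pct[-1] == pytest.approx(0.0, abs=3.0)
        x = prof.positions_um
        fit = np.polyfit(x, prof.intensity_pct, 1)
        assert np.max(np.abs(np.polyval(fit, x) - prof.intensity_pct)) < 1.0

    def test_uniform_image_degenerate(self):
        img = np.full((50, 80), 500.0)
        with pytest.raises(DegenerateGradientError):
            gc.quantify_gradient(img, np.ones_like(img, bool), pixel_size_um=2.0)

    def test_noisy_ramp_within_five_points_of_linear(self):
        rng = np.random.default_rng(4)
        img = np.tile(np.linspace(1000.0, 100.0, 200), (100, 1))
        img = img + rng.normal(0, 0.02 * 900.0, img.shape)
        mask = np.ones_like(img, bool)
        prof = gc.quantify_gradient(img, mask, pixel_size_um=2.0, edge_trim_px=0)
        ideal = np.linspace(100.0, 0.0, 200)
        span = ideal[0] - ideal[-1]
        ideal_at = np.interp(prof.positions_um, (np.arange(200) + 0.5) * 2.0, ideal)
        assert np.max(np.abs(prof.intensity_pct - ideal_at)) < 5.0

    def test_rendered_dye_field_reproduces_simulation(
        self, default_dataset, hex_chamber, steady_field, default_pipeline_config
    ):
        """Rendering + quantification round-trips the simulated profile (< 5 pp)."""
        from gradientchip.synth import footprint_mask_px

        imaging = default_pipeline_config.imaging
        mask_px = footprint_mask_px(hex_chamber, imaging)
        prof = gc.quantify_gradient(
            default_dataset.red[0].astype(float),
            mask_px,
            imaging.pixel_size_um,
            origin_offset_px=imaging.pad_px,
        )
        norm = steady_field.normalized()[0]
        col_mean = np.nanmean(np.where(hex_chamber.mask, norm, np.nan), axis=0)
        keep = ~np.isnan(col_mean)
        sim_pct = np.interp(prof.positions_um, hex_chamber.x_um[keep], 100.0 * col_mean[keep])
        assert np.max(np.abs(prof.intensity_pct - sim_pct)) < 5.0
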