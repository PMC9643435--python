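import itertools

import numpy as np
import pytest

from lymphodyn.tracking import (
    Detection,
    detect_cells,
    detect_movie,
    impute_gaps,
    link_tracks,
)

from conftest import make_track


def blob_frame(centers, shape=(128, 128), sigma=4.0, amp=255.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    frame = np.zeros(shape)
    for cx, cy, a in centers:
        frame += a * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
    return frame


class TestDetect:
    def test_two_well_separated_blobs(self):
        frame = blob_frame([(40, 40, 255), (80, 80, 255)])
        dets = detect_cells(frame, diameter=15, separation=15, minmass=2000)
        assert len(dets) == 2
        found = sorted((d.x, d.y) for d in dets)
        assert found[0] == pytest.approx((40, 40), abs=0.5)
        assert found[1] == pytest.approx((80, 80), abs=0.5)

    def test_minmass_filters_dim_blob(self):
        frame = blob_frame([(40, 40, 255), (90, 90, 3)])
        dets = detect_cells(frame, diameter=15, separation=15, minmass=5000)
        assert len(dets) == 1

    def test_close_blobs_suppressed_to_one(self):
        # 10 px apart < separation 15 → single detection; verified against
        # exhaustive local-maxima enumeration with suppression
        frame = blob_frame([(60, 60, 255), (70, 60, 200)], sigma=3.0)
        dets = detect_cells(frame, diameter=15, separation=15, minmass=1000)
        assert len(dets) == 1
        # oracle: enumerate all local maxima, suppress within separation,
        # keep the brightest
        from scipy.ndimage import gaussian_filter, maximum_filter

        bp = np.clip(gaussian_filter(frame, 1.0) - gaussian_filter(frame, 7.5), 0, None)
        is_max = (maximum_filter(bp, size=3) == bp) & (bp > 0.05 * bp.max())
        cand = sorted(zip(*np.nonzero(is_max)), key=lambda p: -bp[p])
        kept = []
        for p in cand:
            if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= 15 for q in kept):
                kept.append(p)
        assert len(kept) == 1
        assert dets[0].x == pytest.approx(kept[0][1], abs=3)

    def test_empty_frame(self):
        assert detect_cells(np.zeros((32, 32))) == []


def dets_from_path(path):
    """path: list per frame of (x, y) or None."""
    out = []
    for f, pos in enumerate(path):
        frame_dets = []
        if pos is not None:
            for x, y in (pos if isinstance(pos, list) else [pos]):
                frame_dets.append(Detection(frame=f, x=x, y=y, mass=1e4, diameter_est=10))
        out.append(frame_dets)
    return out


class TestLink:
    def test_single_moving_cell(self):
        path = [(3.0 * f, 10.0) for f in range(30)]
        tracks = link_tracks(dets_from_path(path), filter_frames=20)
        assert len(tracks) == 1
        assert len(tracks[0]) == 30

    def test_memory_bridges_gap(self):
        path = [(2.0 * f, 5.0) if not 10 <= f < 15 else None for f in range(40)]
        tracks = link_tracks(dets_from_path(path), memory=10, filter_frames=20)
        assert len(tracks) == 1
        assert tracks[0].t[0] == 0 and tracks[0].t[-1] == 39

    def test_gap_beyond_memory_splits(self):
        path = [(2.0 * f, 5.0) if not 10 <= f < 25 else None for f in range(60)]
        tracks = link_tracks(dets_from_path(path), memory=10, filter_frames=10)
        assert len(tracks) == 2

    def test_jump_beyond_max_speed_refused(self):
        path = [(0.0, float(f)) for f in range(25)] + [
            (25.0 + 0.0, float(f)) for f in range(25, 50)
        ]
        # jump of 25 px between frames 24→25 exceeds max_speed=20
        tracks = link_tracks(dets_from_path(path), max_speed=20, memory=0, filter_frames=20)
        assert len(tracks) == 2
        short = link_tracks(dets_from_path(path[:35]), max_speed=20, memory=0, filter_frames=20)
        # second fragment has 10 < 20 frames → dropped
        assert len(short) == 1

    def test_three_cell_assignment_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        prev = [(10.0, 10.0), (30.0, 10.0), (50.0, 10.0)]
        nxt = [(12.0, 11.0), (28.0, 12.0), (53.0, 9.0)]
        order = rng.permutation(3)
        frames = [
            [Detection(0, x, y, 1e4, 10) for x, y in prev],
            [Detection(1, *nxt[i], 1e4, 10) for i in order],
        ]
        tracks = link_tracks(frames, max_speed=20, filter_frames=2)
        # oracle: enumerate all 6 assignments, pick minimal total squared cost
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(3)):
            cost = sum(
                (prev[i][0] - nxt[perm[i]][0]) ** 2 + (prev[i][1] - nxt[perm[i]][1]) ** 2
                for i in range(3)
            )
            if cost < best_cost:
                best, best_cost = perm, cost
        assert len(tracks) == 3
        for tr in tracks:
            start = (tr.x[0], tr.y[0])
            end = (tr.x[1], tr.y[1])
            i = prev.index(start)
            assert end == nxt[best[i]]

    def test_no_shared_detections_and_min_length(self):
        rng = np.random.default_rng(1)
        paths = [
            [(10.0 + 2 * f + rng.normal(0, 0.3), 20.0 * k) for f in range(30)]
            for k in range(3)
        ]
        per_frame = [
            [Detection(f, *paths[k][f], 1e4, 10) for k in range(3)] for f in range(30)
        ]
        tracks = link_tracks(per_frame, filter_frames=20)
        seen = set()
        for tr in tracks:
            assert len(tr) >= 20
            for t, x, y in zip(tr.t, tr.x, tr.y):
                key = (int(t), round(float(x), 6), round(float(y), 6))
                assert key not in seen
                seen.add(key)


class TestImpute:
    def test_no_gaps_identity(self):
        tr = make_track([(i, float(i), 0.0) for i in range(5)])
        out = impute_gaps(tr)
        np.testing.assert_array_equal(out.t, tr.t)
        assert not out.imputed_mask.any()

    def test_midpoint_interpolation(self):
        tr = make_track([(0, 0.0, 0.0), (2, 2.0, 2.0)])
        out = impute_gaps(tr)
        assert list(out.t) == [0, 1, 2]
        assert out.x[1] == pytest.approx(1.0)
        assert out.y[1] == pytest.approx(1.0)
        assert list(out.imputed_mask) == [False, True, False]

    def test_multiframe_gap_on_chord(self):
        tr = make_track([(0, 0.0, 0.0), (4, 8.0, 4.0)])
        out = impute_gaps(tr)
        # closed-form affine interpolation oracle
        for i, f in enumerate(out.t):
            assert out.x[i] == pytest.approx(8.0 * f / 4)
            assert out.y[i] == pytest.approx(4.0 * f / 4)

    def test_observed_points_unchanged(self):
        tr = make_track([(0, 0.0, 0.0), (3, 5.0, -2.0), (7, 1.0, 1.0)])
        out = impute_gaps(tr)
        for f, x, y in zip(tr.t, tr.x, tr.y):
            i = list(out.t).index(f)
            assert out.x[i] == x and out.y[i] == y
            assert not out.imputed_mask[i]


def test_pipeline_recovers_ground_truth_points():
    """≥99% point-wise recovery on a noise-free, well-separated scene."""
    from lymphodyn.io_preprocess import normalize_and_blur
    from lymphodyn.synthetic import PhenotypePreset, SceneConfig, render_scene
    from lymphodyn.tracking import track_movie_channel

    preset = PhenotypePreset(
        name="CD3", mean_speed=2.0, speed_dispersion=0.4, turning_angle_std=0.8,
        directed_fraction=0.3, cell_diameter_mean=8.0, eccentricity_mean=0.3,
    )
    cfg = SceneConfig(
        n_cells_per_phenotype=8, n_frames=30, frame_shape=(256, 256),
        seed=5, min_separation_px=40,
    )
    movie, truth = render_scene(cfg, {"CD3": preset}, include_fdc=False)
    pre = normalize_and_blur(movie, blur_sigma=1.0)
    tracks = track_movie_channel(
        pre.channels["CD3"], cfg.pixel_size, cfg.frame_interval,
        diameter=15, separation=10, minmass=2000,
    )
    assert len(tracks) == len(truth.tracks)
    correct = total = 0
    for gt in truth.tracks:
        gt_pos = {int(t): (x, y) for t, x, y in zip(gt.t, gt.x, gt.y)}
        best = max(
            tracks,
            key=lambda tr: sum(
                1
                for i, t in enumerate(tr.t)
                if int(t) in gt_pos
                and np.hypot(tr.x[i] - gt_pos[int(t)][0], tr.y[i] - gt_pos[int(t)][1]) < 3
            ),
        )
        n_ok = sum(
            1
            for i, t in enumerate(best.t)
            if int(t) in gt_pos
            and np.hypot(best.x[i] - gt_pos[int(t)][0], best.y[i] - gt_pos[int(t)][1]) < 3
        )
        total += len(gt.t)
        correct += n_ok
    assert correct / total >= 0.99
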