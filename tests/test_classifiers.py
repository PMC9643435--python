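import numpy as np
import pytest

from lymphodyn.classifiers import (
    LEVEL_TABLE,
    Level1Model,
    LevelSpec,
    build_model,
    level1_inputs,
    level2_inputs,
    make_folds,
    run_task,
    sample_patches,
    truncate_tracks,
)
from lymphodyn.features import FEATURE_NAMES

from conftest import random_walk_track


class TestLevelSpec:
    def test_level_input_model_bijection(self):
        kinds = {LevelSpec(level=i).input_kind for i in range(1, 5)}
        families = {LevelSpec(level=i).model_family for i in range(1, 5)}
        assert len(kinds) == 4 and len(families) == 4
        assert LEVEL_TABLE[1][1] == "linear"
        assert LEVEL_TABLE[4][1] == "conv-3d"

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            LevelSpec(level=5)


class TestBuildModel:
    def test_level1_has_15_coefficients(self, rng):
        model = build_model(LevelSpec(level=1), seed=0)
        x = rng.normal(size=(40, 15))
        y = rng.integers(0, 2, 40)
        model.fit(x, y)
        assert model.coef_.shape == (15,)
        assert isinstance(model.intercept_, float)

    def test_level4_shape_contract(self):
        spec = LevelSpec(level=4)
        build_model(spec, input_shape=(1, 16, 64, 64), seed=0)
        with pytest.raises(ValueError, match=r"16, 64, 64"):
            build_model(spec, input_shape=(1, 8, 64, 64), seed=0)

    def test_level1_rejects_wrong_width(self, rng):
        model = build_model(LevelSpec(level=1), seed=0)
        with pytest.raises(ValueError, match="15"):
            model.fit(rng.normal(size=(10, 14)), rng.integers(0, 2, 10))


class TestRepresentations:
    def test_level1_shape(self, rng):
        tracks = [random_walk_track(rng, n=25, track_id=i) for i in range(4)]
        assert level1_inputs(tracks).shape == (4, 15)

    def test_level2_padding(self, rng):
        tracks = [random_walk_track(rng, n=25, track_id=i) for i in range(3)]
        x = level2_inputs(tracks, max_len=60)
        assert x.shape == (3, 3, 60)
        assert np.all(x[:, :, 23:] == 0)  # length 25 → 23 valid triples

    def test_sample_patches_shapes(self, rng):
        frames = rng.uniform(size=(10, 80, 80))
        tracks = [random_walk_track(rng, n=10)]
        p2d = sample_patches(frames, tracks, 5, patch_size=64, rng=rng)
        assert p2d.shape == (5, 1, 64, 64)
        p3d = sample_patches(frames, tracks, 5, patch_size=64, t_window=8, rng=rng)
        assert p3d.shape == (5, 1, 8, 64, 64)


class TestTruncate:
    def test_identity_when_longer_than_all(self, rng):
        tracks = [random_walk_track(rng, n=20)]
        assert truncate_tracks(tracks, 50)[0] is tracks[0]

    def test_clipping_contract(self, rng):
        tracks = [random_walk_track(rng, n=40, track_id=i) for i in range(3)]
        out = truncate_tracks(tracks, 20)
        assert all(len(tr) <= 20 for tr in out)

    def test_minimum_length_guard(self, rng):
        with pytest.raises(ValueError):
            truncate_tracks([random_walk_track(rng)], 2)


class TestFolds:
    def test_intra_leave_one_movie_out(self):
        movies = np.repeat([f"m{i}" for i in range(5)], 4)
        patients = np.repeat("p0", 20)
        folds = make_folds(movies, patients, "intra")
        assert len(folds) == 5
        for _, test in folds:
            assert len(set(movies[test])) == 1

    def test_inter_patient_disjoint(self):
        patients = np.repeat([f"p{i}" for i in range(6)], 3)
        movies = np.arange(18).astype(str)
        folds = make_folds(movies, patients, "inter", seed=3)
        test_sets = [set(patients[test]) for _, test in folds]
        assert all(len(s) == 2 for s in test_sets)
        for i in range(3):
            for j in range(i + 1, 3):
                assert not (test_sets[i] & test_sets[j])

    def test_partition_invariant(self):
        patients = np.repeat([f"p{i}" for i in range(4)], 2)
        movies = np.arange(8).astype(str)
        for scheme in ("intra", "inter"):
            for train, test in make_folds(movies, patients, scheme):
                assert set(train) | set(test) == set(range(8))
                assert not (set(train) & set(test))

    def test_errors(self):
        with pytest.raises(ValueError):
            make_folds(["m0"] * 4, ["p0"] * 4, "intra")
        with pytest.raises(ValueError):
            make_folds(["m0", "m1"], ["p0", "p1"], "inter")
        with pytest.raises(ValueError):
            make_folds(["m0"], ["p0"], "bogus")

    def test_seed_determinism(self):
        patients = np.repeat([f"p{i}" for i in range(6)], 2)
        movies = np.arange(12).astype(str)
        f1 = make_folds(movies, patients, "inter", seed=9)
        f2 = make_folds(movies, patients, "inter", seed=9)
        for (a, b), (c, d) in zip(f1, f2):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)


def _toy_feature_dataset(rng, n_per=160, informative=True):
    x = rng.normal(size=(2 * n_per, 15))
    y = np.array([0] * n_per + [1] * n_per)
    if informative:
        x[y == 1, 13] += 3.0  # net_distance column
    patients = np.tile([f"p{i}" for i in range(4)], 2 * n_per // 4)
    movies = patients  # one movie per patient is fine for inter folds
    return x, y, movies, patients


class TestRunTask:
    def test_identical_populations_auc_near_half(self, rng):
        x, y, movies, patients = _toy_feature_dataset(rng, informative=False)
        res = run_task(x, y, movies, patients, LevelSpec(level=1), n_repeats=2, seed=0)
        assert res.mean_auc == pytest.approx(0.5, abs=0.1)

    def test_informative_feature_high_auc(self, rng):
        x, y, movies, patients = _toy_feature_dataset(rng)
        res = run_task(x, y, movies, patients, LevelSpec(level=1), n_repeats=2, seed=0)
        assert res.mean_auc > 0.95

    def test_shuffled_labels_permutation_control(self, rng):
        x, y, movies, patients = _toy_feature_dataset(rng)
        y_shuffled = rng.permutation(y)
        res = run_task(
            x, y_shuffled, movies, patients, LevelSpec(level=1), n_repeats=2, seed=0
        )
        assert res.mean_auc == pytest.approx(0.5, abs=0.12)

    def test_level1_seed_determinism(self, rng):
        x, y, movies, patients = _toy_feature_dataset(rng)
        m1 = Level1Model(seed=1).fit(x, y)
        m2 = Level1Model(seed=1).fit(x, y)
        np.testing.assert_allclose(m1.coef_, m2.coef_)

    def test_single_class_fold_skipped(self, rng):
        x = rng.normal(size=(30, 15))
        # p0 carries a single class; p1 and p2 are mixed
        y = np.array([0] * 10 + [0] * 5 + [1] * 5 + [0] * 5 + [1] * 5)
        patients = np.array(["p0"] * 10 + ["p1"] * 10 + ["p2"] * 10)
        with pytest.warns(UserWarning, match="single-class"):
            res = run_task(
                x, y, patients, patients, LevelSpec(level=1), n_repeats=1, seed=0
            )
        assert res.skipped_folds


def test_truncation_ablation_auc_nondecreasing():
    """Level-1 AUC on a directed-vs-undirected task grows (on average over
    5 seeds) with the available temporal context."""
    from sklearn.metrics import roc_auc_score

    from lymphodyn.synthetic import PhenotypePreset, SceneConfig, simulate_tracks

    lengths = (5, 12, 40)
    mean_aucs = []
    for max_len in lengths:
        aucs = []
        for seed in range(5):
            preset = PhenotypePreset(
                name="X", mean_speed=2.0, speed_dispersion=0.4,
                turning_angle_std=1.8, directed_fraction=0.5,
                cell_diameter_mean=7.0, eccentricity_mean=0.3,
            )
            cfg = SceneConfig(n_frames=60, seed=seed)
            tracks = simulate_tracks(
                preset, cfg, n_tracks=160, rng=np.random.default_rng(seed)
            )
            tracks = truncate_tracks(tracks, max_len)
            x = level1_inputs(tracks)
            y = np.array([1 if tr.regime == "directed" else 0 for tr in tracks])
            model = Level1Model(seed=seed).fit(x[:100], y[:100])
            aucs.append(roc_auc_score(y[100:], model.predict_proba(x[100:])[:, 1]))
        mean_aucs.append(np.mean(aucs))
    assert mean_aucs[0] <= mean_aucs[1] + 0.02
    assert mean_aucs[1] <= mean_aucs[2] + 0.02
    assert mean_aucs[2] > mean_aucs[0]


def test_standardization_is_fold_local(rng):
    """Scaler statistics must come from the training data only."""
    x = rng.normal(size=(50, 15))
    y = rng.integers(0, 2, 50)
    model = Level1Model(seed=0).fit(x[:30], y[:30])
    np.testing.assert_allclose(model.scaler.mean_, x[:30].mean(axis=0))
    with np.testing.assert_raises(AssertionError):
        np.testing.assert_allclose(model.scaler.mean_, x.mean(axis=0))
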