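"""The four information levels and their cross-validated evaluation.

Level 1: logistic regression on the 15 summary features (long-term
movement).  Level 2: 1D CNN on padded (v, a, r) sequences (short-term
movement).  Level 3: 2D CNN on single-frame patches (morphology).
Level 4: 3D CNN on video patches (morphology + movement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler

from lymphodyn.features import FEATURE_NAMES, feature_vector, relative_track
from lymphodyn.nn import (
    ConvND,
    Dense,
    Dropout,
    GlobalConcatPool,
    MaxPoolND,
    ReLU,
    Sequential,
)

#: per-level defaults: input kind, model family, conv filter banks.
LEVEL_TABLE = {
    1: ("track-features", "linear", None),
    2: ("raw-track", "conv-1d", (128, 64, 32)),
    3: ("frame-patch", "conv-2d", (256, 128, 64)),
    4: ("video-patch", "conv-3d", (256, 128, 64)),
}

DEFAULT_INPUT_SHAPES = {
    2: (3, 60),
    3: (1, 64, 64),
    4: (1, 16, 64, 64),
}


@dataclass(frozen=True)
class LevelSpec:
    """One information level with optional scaled-down overrides.

    Defaults reproduce the reference architectures; ``filters`` and
    ``input_shape`` may be overridden for desk-scale experiments.
    """

    level: int
    filters: tuple | None = None
    dropout: float = 0.25
    input_shape: tuple | None = None
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.level not in LEVEL_TABLE:
            raise ValueError("level must be 1, 2, 3 or 4")

    @property
    def input_kind(self) -> str:
        return LEVEL_TABLE[self.level][0]

    @property
    def model_family(self) -> str:
        return LEVEL_TABLE[self.level][1]

    @property
    def effective_filters(self) -> tuple | None:
        return self.filters if self.filters is not None else LEVEL_TABLE[self.level][2]

    @property
    def expected_input_shape(self) -> tuple | None:
        if self.level == 1:
            return (len(FEATURE_NAMES),)
        return (
            self.input_shape
            if self.input_shape is not None
            else DEFAULT_INPUT_SHAPES[self.level]
        )

    @property
    def optimizer(self) -> str:
        # the sequence model trains with plain gradient descent; the
        # image/video models with Adam — all at learning rate 1e-3
        return "sgd" if self.level == 2 else "adam"


class Level1Model:
    """Standardize-then-logistic-regression on the 15 summary features.

    Standardization statistics are fit on the training fold only, so there
    is no leakage into evaluation data.
    """

    def __init__(self, seed: int = 0, l2: float = 1e-3):
        self.scaler = StandardScaler()
        # C = 1/l2 maps the weight penalty onto sklearn's parametrization
        self.clf = LogisticRegression(C=1.0 / max(l2, 1e-12), random_state=seed, max_iter=1000)
        self.fitted = False
        self.feature_names = list(FEATURE_NAMES)

    def fit(self, x: np.ndarray, y: np.ndarray, **_ignored) -> "Level1Model":
        x = np.asarray(x, dtype=float)
        if x.shape[1] != len(FEATURE_NAMES):
            raise ValueError(
                f"expected {len(FEATURE_NAMES)} features, got {x.shape[1]}"
            )
        self._train_corr = np.corrcoef(x, rowvar=False)
        self.clf.fit(self.scaler.fit_transform(x), y)
        self.fitted = True
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.clf.predict_proba(self.scaler.transform(np.asarray(x, dtype=float)))

    @property
    def coef_(self) -> np.ndarray:
        return self.clf.coef_[0]

    @property
    def intercept_(self) -> float:
        return float(self.clf.intercept_[0])


def build_model(spec: LevelSpec, input_shape: tuple | None = None, seed: int = 0):
    """Instantiate the model for a level, validating the input shape."""
    expected = spec.expected_input_shape
    if input_shape is not None and tuple(input_shape) != tuple(expected):
        raise ValueError(
            f"level {spec.level} expects input shape {expected}, got {tuple(input_shape)}"
        )
    if spec.level == 1:
        return Level1Model(seed=seed)
    rng = np.random.default_rng(seed)
    ndim = {2: 1, 3: 2, 4: 3}[spec.level]
    in_ch = expected[0]
    layers = []
    prev = in_ch
    for f in spec.effective_filters:
        layers += [
            ConvND(prev, f, kernel_size=3, ndim=ndim, rng=rng),
            ReLU(),
            MaxPoolND(ndim=ndim, size=2),
            Dropout(spec.dropout, rng=rng),
        ]
        prev = f
    layers += [GlobalConcatPool(), Dense(2 * prev, 2, rng=rng)]
    return Sequential(layers, rng=rng)


# ---------------------------------------------------------------------------
# representations


def level1_inputs(tracks, scheme: str = "forward") -> np.ndarray:
    """(N, 15) raw (unstandardized) summary features."""
    return np.stack([feature_vector(tr, scheme=scheme) for tr in tracks])


def level2_inputs(tracks, max_len: int = 60, scheme: str = "forward") -> np.ndarray:
    """(N, 3, max_len) zero-padded (v, a, r) sequences."""
    out = np.zeros((len(tracks), 3, max_len))
    for i, tr in enumerate(tracks):
        arr = relative_track(tr, scheme=scheme).as_array().T  # (3, L)
        length = min(arr.shape[1], max_len)
        out[i, :, :length] = arr[:, :length]
    return out


def sample_patches(
    frames: np.ndarray,
    tracks,
    n_patches: int,
    patch_size: int = 64,
    t_window: int | None = None,
    p_centered: float = 0.5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Random spatial (or spatio-temporal) patches from one channel.

    With probability ``p_centered`` a patch is centred on a tracked cell
    position, otherwise placed uniformly — so both the cells and their
    context appear in the training data.  Returns (N, 1, [T,] H, W).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    m, ylim, xlim = frames.shape
    half = patch_size // 2
    if ylim < patch_size or xlim < patch_size:
        raise ValueError("frames smaller than patch size")
    cells = []
    for tr in tracks:
        for i in range(len(tr)):
            cells.append((int(tr.t[i]), tr.x[i], tr.y[i]))
    out = []
    for _ in range(n_patches):
        if cells and rng.random() < p_centered:
            t0, cx, cy = cells[rng.integers(len(cells))]
        else:
            t0 = int(rng.integers(m))
            cx = rng.uniform(half, xlim - half)
            cy = rng.uniform(half, ylim - half)
        x0 = int(np.clip(round(cx) - half, 0, xlim - patch_size))
        y0 = int(np.clip(round(cy) - half, 0, ylim - patch_size))
        if t_window is None:
            out.append(frames[min(t0, m - 1), y0 : y0 + patch_size, x0 : x0 + patch_size])
        else:
            t0 = int(np.clip(t0, 0, m - t_window))
            out.append(
                frames[t0 : t0 + t_window, y0 : y0 + patch_size, x0 : x0 + patch_size]
            )
    return np.asarray(out)[:, None]


def truncate_tracks(tracks, max_length: int):
    """Clip every track to its first ``max_length`` points."""
    if max_length < 3:
        raise ValueError("max_length must be ≥ 3")
    out = []
    for tr in tracks:
        if len(tr) <= max_length:
            out.append(tr)
        else:
            from lymphodyn.tracks import Track

            out.append(
                Track(
                    track_id=tr.track_id,
                    t=tr.t[:max_length],
                    x=tr.x[:max_length],
                    y=tr.y[:max_length],
                    phenotype=tr.phenotype,
                    regime=tr.regime,
                    pixel_size=tr.pixel_size,
                    frame_interval=tr.frame_interval,
                    movie_id=tr.movie_id,
                    patient_id=tr.patient_id,
                    imputed_mask=tr.imputed_mask[:max_length],
                )
            )
    return out


# ---------------------------------------------------------------------------
# cross-validation


def make_folds(movie_ids, patient_ids, scheme: str, n_folds: int = 3, seed: int = 0):
    """Fold assignments as (train_idx, test_idx) pairs.

    ``intra``: leave-one-movie-out.  ``inter``: patients partitioned into
    ``n_folds`` disjoint groups (no patient appears in two folds).
    """
    movie_ids = np.asarray(movie_ids)
    patient_ids = np.asarray(patient_ids)
    idx = np.arange(len(movie_ids))
    if scheme == "intra":
        movies = sorted(set(movie_ids))
        if len(movies) < 2:
            raise ValueError("intra-patient folding needs at least 2 movies")
        return [
            (idx[movie_ids != mv], idx[movie_ids == mv]) for mv in movies
        ]
    if scheme == "inter":
        patients = sorted(set(patient_ids))
        if len(patients) < n_folds:
            raise ValueError(f"inter-patient folding needs at least {n_folds} patients")
        rng = np.random.default_rng(seed)
        shuffled = list(rng.permutation(patients))
        groups = [set(shuffled[i::n_folds]) for i in range(n_folds)]
        folds = []
        for grp in groups:
            test = np.isin(patient_ids, list(grp))
            folds.append((idx[~test], idx[test]))
        return folds
    raise ValueError("scheme must be 'intra' or 'inter'")


@dataclass
class CVResult:
    task: str
    scheme: str
    level: int
    aucs: list  # one entry per (fold, repeat)
    mean_auc: float
    std_auc: float
    n_folds: int
    n_repeats: int
    skipped_folds: list = field(default_factory=list)


def _balance_indices(y, idx, rng):
    """Subsample the majority class to a 1:1 ratio (train folds only)."""
    pos = idx[y[idx] == 1]
    neg = idx[y[idx] == 0]
    n = min(len(pos), len(neg))
    return np.concatenate([rng.permutation(pos)[:n], rng.permutation(neg)[:n]])


def run_task(
    x: np.ndarray,
    y: np.ndarray,
    movie_ids,
    patient_ids,
    spec: LevelSpec,
    scheme: str = "inter",
    n_repeats: int = 5,
    seed: int = 0,
    task: str = "",
    fit_kwargs: dict | None = None,
    balance: bool = True,
) -> CVResult:
    """Cross-validated binary classification at one information level.

    Per fold the model is fitted on the training split (with fold-local
    standardization for level 1 and 1:1 class balancing) and scored by
    sample-level AUC on the test split; each fold is refitted
    ``n_repeats`` times with different initializations.  Test folds with
    a single class are skipped with a warning.
    """
    y = np.asarray(y, dtype=int)
    fit_kwargs = dict(fit_kwargs or {})
    folds = make_folds(movie_ids, patient_ids, scheme, seed=seed)
    rng = np.random.default_rng(seed)
    aucs, skipped = [], []
    for fi, (train_idx, test_idx) in enumerate(folds):
        if len(np.unique(y[test_idx])) < 2 or len(np.unique(y[train_idx])) < 2:
            warnings.warn(f"fold {fi}: single-class split, skipped")
            skipped.append(fi)
            continue
        tr = _balance_indices(y, train_idx, rng) if balance else train_idx
        for rep in range(n_repeats):
            rep_seed = int(rng.integers(2**31))
            model = build_model(spec, seed=rep_seed)
            if spec.level == 1:
                model.fit(x[tr], y[tr])
            else:
                model.fit(x[tr], y[tr], optimizer=spec.optimizer,
                          lr=spec.learning_rate, **fit_kwargs)
            probs = model.predict_proba(x[test_idx])[:, 1]
            aucs.append(float(roc_auc_score(y[test_idx], probs)))
    if not aucs:
        raise ValueError("all folds were skipped")
    return CVResult(
        task=task,
        scheme=scheme,
        level=spec.level,
        aucs=aucs,
        mean_auc=float(np.mean(aucs)),
        std_auc=float(np.std(aucs)),
        n_folds=len(folds) - len(skipped),
        n_repeats=n_repeats,
        skipped_folds=skipped,
    )
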