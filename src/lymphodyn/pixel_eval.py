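"""Unified pixel-level evaluation.

Every model's predictions are rendered onto a per-frame per-pixel score
map of identical shape, blank pixels are filled by nearest-scored-pixel
assignment in (t, y, x) space, and AUC is computed over labelled pixels
with empty areas excluded — so models with entirely different input
representations become directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.metrics import roc_auc_score


@dataclass
class PredictionMap:
    """(M, Y, X) per-pixel positive-class scores; NaN marks blank pixels."""

    scores: np.ndarray
    provenance: str = ""
    filled_mask: np.ndarray | None = None  # True where watershed-filled

    @property
    def blank_mask(self) -> np.ndarray:
        return np.isnan(self.scores)


def render_spatial_predictions(
    score_fn,
    frames: np.ndarray,
    window: int,
    stride: int,
    t_window: int | None = None,
    t_stride: int | None = None,
    batch_size: int = 64,
    provenance: str = "",
) -> PredictionMap:
    """Score overlapping moving windows and average them per pixel.

    ``score_fn`` maps a batch of windows (N, 1, [T,] H, W) to
    positive-class probabilities.  Starts include a final border-aligned
    window so no margin stays unscored.  ``stride`` must not exceed
    ``window`` (coverage gap).
    """
    if stride > window:
        raise ValueError("stride > window leaves coverage gaps")
    m, ylim, xlim = frames.shape
    if t_window is not None:
        if t_stride is None:
            t_stride = t_window
        if t_stride > t_window:
            raise ValueError("t_stride > t_window leaves coverage gaps")

    def starts(extent, w, s):
        out = list(range(0, extent - w + 1, s))
        if not out or out[-1] != extent - w:
            out.append(extent - w)
        return out

    acc = np.zeros((m, ylim, xlim))
    cnt = np.zeros((m, ylim, xlim))
    xs = starts(xlim, window, stride)
    ys = starts(ylim, window, stride)
    ts = starts(m, t_window, t_stride) if t_window is not None else range(m)

    windows, places = [], []

    def flush():
        nonlocal windows, places
        if not windows:
            return
        probs = score_fn(np.asarray(windows)[:, None])
        for p, (t0, y0, x0) in zip(probs, places):
            if t_window is None:
                acc[t0, y0 : y0 + window, x0 : x0 + window] += p
                cnt[t0, y0 : y0 + window, x0 : x0 + window] += 1
            else:
                acc[t0 : t0 + t_window, y0 : y0 + window, x0 : x0 + window] += p
                cnt[t0 : t0 + t_window, y0 : y0 + window, x0 : x0 + window] += 1
        windows, places = [], []

    for t0 in ts:
        for y0 in ys:
            for x0 in xs:
                if t_window is None:
                    windows.append(frames[t0, y0 : y0 + window, x0 : x0 + window])
                else:
                    windows.append(
                        frames[t0 : t0 + t_window, y0 : y0 + window, x0 : x0 + window]
                    )
                places.append((t0, y0, x0))
                if len(windows) >= batch_size:
                    flush()
    flush()
    scores = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return PredictionMap(scores=scores, provenance=provenance)


def render_track_predictions(
    tracks,
    track_scores,
    shape: tuple[int, int, int],
    paint_width: int = 5,
    provenance: str = "",
) -> PredictionMap:
    """Paint each track's score on a disk around each (t, x, y) point.

    Overlapping paints average; everything else stays blank pending
    watershed fill.
    """
    m, ylim, xlim = shape
    acc = np.zeros(shape)
    cnt = np.zeros(shape)
    r = paint_width
    for tr, score in zip(tracks, track_scores):
        for i in range(len(tr)):
            t = int(tr.t[i])
            if not 0 <= t < m:
                continue
            cy, cx = tr.y[i], tr.x[i]
            y0, y1 = max(0, int(cy) - r), min(ylim, int(cy) + r + 1)
            x0, x1 = max(0, int(cx) - r), min(xlim, int(cx) + r + 1)
            if y0 >= y1 or x0 >= x1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            acc[t, y0:y1, x0:x1][disk] += score
            cnt[t, y0:y1, x0:x1][disk] += 1
    scores = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return PredictionMap(scores=scores, provenance=provenance)


def watershed_fill(pmap: PredictionMap, time_weight: float = 1.0) -> PredictionMap:
    """Assign every blank pixel the score of its nearest scored pixel.

    Distance is Euclidean in (t, y, x) with the temporal axis scaled by
    ``time_weight`` (1 frame ≡ ``time_weight`` pixels).  Scored pixels
    never change, making the operation idempotent.  Equidistant seeds
    resolve deterministically (fixed KD-tree construction over seeds in
    (t, y, x) scan order).
    """
    blank = pmap.blank_mask
    if not (~blank).any():
        raise ValueError("fully blank map cannot be filled")
    if not blank.any():
        return PredictionMap(
            scores=pmap.scores.copy(),
            provenance=pmap.provenance,
            filled_mask=np.zeros_like(blank),
        )
    seed_coords = np.argwhere(~blank)  # sorted in (t, y, x) scan order
    query_coords = np.argwhere(blank)
    scale = np.array([time_weight, 1.0, 1.0])
    tree = cKDTree(seed_coords * scale)
    _, nearest = tree.query(query_coords * scale)
    filled = pmap.scores.copy()
    seed_scores = pmap.scores[tuple(seed_coords.T)]
    filled[tuple(query_coords.T)] = seed_scores[nearest]
    return PredictionMap(
        scores=filled, provenance=pmap.provenance, filled_mask=blank.copy()
    )


def pixel_auc(
    pmap: PredictionMap,
    truth: np.ndarray,
    context_mask: np.ndarray | None = None,
    subsample: int | None = None,
    seed: int = 0,
) -> float:
    """AUC over evaluated pixels.

    ``context_mask`` (True = keep) excludes empty areas with no cell
    context; ``subsample`` draws a seeded random pixel subset for
    tractability on large volumes.  A single-class truth after exclusion
    is undefined and raises.
    """
    scores = pmap.scores
    truth = np.asarray(truth, dtype=bool)
    if truth.shape != scores.shape:
        raise ValueError("truth mask must match prediction-map shape")
    keep = ~np.isnan(scores)
    if context_mask is not None:
        keep &= context_mask
    s = scores[keep]
    t = truth[keep]
    if subsample is not None and s.size > subsample:
        sel = np.random.default_rng(seed).choice(s.size, subsample, replace=False)
        s, t = s[sel], t[sel]
    if np.unique(t).size < 2:
        raise ValueError("single-class truth after exclusion: AUC undefined")
    return float(roc_auc_score(t, s))


def context_mask_from_channels(
    channels: dict[str, np.ndarray],
    relevant: list[str],
    floor_fraction: float = 0.05,
    blur_sigma: float = 2.0,
) -> np.ndarray:
    """Pixels with signal above ``floor_fraction`` of the per-frame max in
    at least one relevant channel."""
    from scipy.ndimage import gaussian_filter

    mask = None
    for name in relevant:
        arr = gaussian_filter(channels[name], sigma=(0, blur_sigma, blur_sigma))
        per_frame_max = arr.max(axis=(1, 2), keepdims=True)
        m = arr > floor_fraction * np.maximum(per_frame_max, 1e-12)
        mask = m if mask is None else (mask | m)
    return mask
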