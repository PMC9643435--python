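"""Ellipse morphology per detection and the morphology↔velocity PCA."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as sk_label
from skimage.measure import regionprops


@dataclass
class CellShape:
    """Ellipse fit of one detection, axes in μm."""

    major_axis: float  # "cell size"
    minor_axis: float
    eccentricity: float
    orientation: float
    frame: int
    track_id: object = None
    border_flag: bool = False

    def __post_init__(self) -> None:
        if self.minor_axis <= 0 or self.major_axis < self.minor_axis:
            raise ValueError("need major_axis ≥ minor_axis > 0")
        if not 0 <= self.eccentricity < 1:
            raise ValueError("eccentricity must be in [0, 1)")


def fit_ellipse(
    frame: np.ndarray,
    x: float,
    y: float,
    pixel_size: float,
    patch_radius: int = 16,
    threshold_fraction: float = 0.5,
    frame_index: int = 0,
    track_id=None,
) -> CellShape | None:
    """Second-moment ellipse of the blob at (x, y).

    The patch is background-subtracted (patch minimum), thresholded at
    ``threshold_fraction`` of the local peak and the connected component
    containing the centre is measured.  Blobs touching the patch border
    are flagged and excluded from statistics (``None`` is returned).
    """
    ylim, xlim = frame.shape
    x0, x1 = int(round(x)) - patch_radius, int(round(x)) + patch_radius + 1
    y0, y1 = int(round(y)) - patch_radius, int(round(y)) + patch_radius + 1
    cx0, cx1 = max(0, x0), min(xlim, x1)
    cy0, cy1 = max(0, y0), min(ylim, y1)
    patch = frame[cy0:cy1, cx0:cx1].astype(float)
    if patch.size == 0 or patch.max() == patch.min():
        return None
    patch = patch - patch.min()
    mask = patch >= threshold_fraction * patch.max()
    labels = sk_label(mask)
    cy, cx = int(round(y)) - cy0, int(round(x)) - cx0
    cy = np.clip(cy, 0, patch.shape[0] - 1)
    cx = np.clip(cx, 0, patch.shape[1] - 1)
    lbl = labels[cy, cx]
    if lbl == 0:
        # centre fell off the mask (sub-pixel offset); take largest blob
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        if counts.max() == 0:
            return None
        lbl = int(np.argmax(counts))
    blob = labels == lbl
    ys, xs = np.nonzero(blob)
    touches_border = (
        ys.min() == 0
        or xs.min() == 0
        or ys.max() == patch.shape[0] - 1
        or xs.max() == patch.shape[1] - 1
    )
    if touches_border:
        return None
    props = regionprops(blob.astype(int))[0]
    major = props.axis_major_length * pixel_size
    minor = props.axis_minor_length * pixel_size
    if minor <= 0:
        return None
    return CellShape(
        major_axis=major,
        minor_axis=minor,
        eccentricity=float(props.eccentricity),
        orientation=float(props.orientation),
        frame=frame_index,
        track_id=track_id,
    )


def track_morphology(frames: np.ndarray, track, pixel_size: float, **kwargs) -> pd.DataFrame:
    """Per-frame ellipse fits along a track; flagged frames are skipped."""
    rows = []
    for i, f in enumerate(track.t):
        if f >= frames.shape[0]:
            continue
        shape = fit_ellipse(
            frames[f], track.x[i], track.y[i], pixel_size,
            frame_index=int(f), track_id=track.track_id, **kwargs,
        )
        if shape is not None:
            rows.append(
                {
                    "track_id": track.track_id,
                    "frame": int(f),
                    "major_axis": shape.major_axis,
                    "minor_axis": shape.minor_axis,
                    "eccentricity": shape.eccentricity,
                    "orientation": shape.orientation,
                }
            )
    return pd.DataFrame(rows)


def per_track_summary(shape_df: pd.DataFrame) -> pd.DataFrame:
    """Median size/eccentricity (plus eccentricity std) per track."""
    if shape_df.empty:
        raise ValueError("no shapes to summarize")
    return (
        shape_df.groupby("track_id")
        .agg(
            median_size=("major_axis", "median"),
            median_eccentricity=("eccentricity", "median"),
            eccentricity_std=("eccentricity", "std"),
            n_shapes=("frame", "count"),
        )
        .reset_index()
    )


def morphology_pca(per_track: pd.DataFrame, velocity: pd.Series | None = None) -> dict:
    """First principal component of (median size, median eccentricity).

    Features are standardized; the size loading is forced positive so the
    sign of the eccentricity loading is reproducible.  When per-track
    velocities are supplied, the Pearson correlation of PC1 scores (and of
    eccentricity std, if present) with velocity is reported.
    """
    if len(per_track) < 3:
        raise ValueError("PCA needs at least 3 tracks")
    feats = per_track[["median_size", "median_eccentricity"]].to_numpy(dtype=float)
    std = feats.std(axis=0)
    for name, s in zip(("median_size", "median_eccentricity"), std):
        if s == 0:
            raise ValueError(f"degenerate (constant) feature: {name}")
    z = (feats - feats.mean(axis=0)) / std
    cov = np.cov(z, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pc1 = evecs[:, 0]
    if pc1[0] < 0:
        pc1 = -pc1
    scores = z @ pc1
    result = {
        "loadings": {"median_size": float(pc1[0]), "median_eccentricity": float(pc1[1])},
        "explained_variance_ratio": (evals / evals.sum()).tolist(),
        "scores": scores,
    }
    if velocity is not None:
        v = np.asarray(velocity, dtype=float)
        result["pc1_velocity_correlation"] = float(np.corrcoef(scores, v)[0, 1])
        if "eccentricity_std" in per_track:
            es = per_track["eccentricity_std"].to_numpy(dtype=float)
            ok = np.isfinite(es)
            if ok.sum() >= 3:
                if es[ok].std() > 0 and v[ok].std() > 0:
                    result["ecc_std_velocity_correlation"] = float(
                        np.corrcoef(es[ok], v[ok])[0, 1]
                    )
            else:
                warnings.warn("too few eccentricity std values for correlation")
    return result
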