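"""Movie container, TIFF I/O and preprocessing.

Preprocessing follows a fixed order — low-intensity cut-off, Gaussian
blur, per-channel rescale to [0, 1] — and records it in the movie
metadata, because blurring measurably changes downstream velocity
estimates and provenance must stay explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from lymphodyn.tracks import DEFAULT_CONVERSION_FACTOR  # noqa: F401 (re-export)


@dataclass
class Movie:
    """Multi-channel 2D time-lapse with calibration metadata.

    channels maps channel name → (M, Y, X) float array.  All channels
    share the frame count and frame shape.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float  # μm / pixel
    frame_interval: float  # seconds / frame
    patient_id: str = ""
    movie_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("movie needs at least one channel")
        shapes = {arr.shape for arr in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        (shape,) = shapes
        if len(shape) != 3:
            raise ValueError("each channel must be (frames, Y, X)")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        for name, arr in self.channels.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[1:]

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def conversion_factor(self) -> float:
        """μm/min per pixel/frame implied by the calibration."""
        return self.pixel_size * 60.0 / self.frame_interval


def max_intensity_project(zstack_channels: dict[str, np.ndarray], **movie_kwargs) -> Movie:
    """Collapse (M, Z, Y, X) channels to (M, Y, X) by per-pixel max over z.

    Already-projected (M, Y, X) input passes through unchanged, making the
    operation idempotent.
    """
    projected = {}
    for name, arr in zstack_channels.items():
        arr = np.asarray(arr)
        if arr.ndim == 3:
            projected[name] = arr.copy()
        elif arr.ndim == 4:
            if arr.shape[1] == 0:
                raise ValueError(f"channel {name!r} has an empty z-axis")
            projected[name] = arr.max(axis=1)
        else:
            raise ValueError(f"channel {name!r}: expected 3D or 4D, got {arr.ndim}D")
    return Movie(channels=projected, **movie_kwargs)


def normalize_and_blur(
    movie: Movie, low_cut: float | None = None, blur_sigma: float = 1.0
) -> Movie:
    """Cut-off → blur → per-channel min-max rescale to [0, 1].

    ``low_cut`` is an absolute intensity; ``None`` uses 2% of the channel
    max.  A channel that is constant after the cut-off carries no signal
    and maps to zeros (with a warning) rather than dividing by zero.
    """
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be ≥ 0")
    out = {}
    for name, arr in movie.channels.items():
        cut = 0.02 * arr.max() if low_cut is None else low_cut
        work = np.where(arr < cut, 0.0, arr.astype(float))
        if blur_sigma > 0:
            work = gaussian_filter(work, sigma=(0, blur_sigma, blur_sigma))
        lo, hi = work.min(), work.max()
        if hi - lo == 0:
            warnings.warn(f"channel {name!r} constant after cut-off; set to zeros")
            out[name] = np.zeros_like(work)
        else:
            out[name] = (work - lo) / (hi - lo)
    meta = dict(movie.meta)
    meta.setdefault("preprocessing", []).append(
        {"order": ["low_cut", "blur", "rescale"], "low_cut": low_cut, "blur_sigma": blur_sigma}
    )
    return Movie(
        channels=out,
        pixel_size=movie.pixel_size,
        frame_interval=movie.frame_interval,
        patient_id=movie.patient_id,
        movie_id=movie.movie_id,
        meta=meta,
    )


def resample_to_common_grid(
    movie: Movie, target_pixel_size: float, target_interval: float
) -> Movie:
    """Bilinear spatial resampling + nearest-frame temporal selection.

    Metadata is updated so unit conversion downstream stays consistent.
    Upsampling beyond 4× triggers a warning (fabricated detail).
    """
    if target_pixel_size <= 0 or target_interval <= 0:
        raise ValueError("target scales must be positive")
    scale = movie.pixel_size / target_pixel_size
    if scale > 4:
        warnings.warn(f"spatial upsampling {scale:.1f}× exceeds 4×")
    if movie.frame_interval / target_interval > 4:
        warnings.warn("temporal upsampling exceeds 4×")
    same_space = np.isclose(scale, 1.0)
    same_time = np.isclose(target_interval, movie.frame_interval)
    if same_space and same_time:
        return movie

    y, x = movie.frame_shape
    new_shape = (max(1, round(y * scale)), max(1, round(x * scale)))
    duration = movie.n_frames * movie.frame_interval
    n_new = max(1, int(round(duration / target_interval)))
    src_idx = np.clip(
        np.round(np.arange(n_new) * target_interval / movie.frame_interval).astype(int),
        0,
        movie.n_frames - 1,
    )
    out = {}
    for name, arr in movie.channels.items():
        sel = arr[src_idx]
        if same_space:
            out[name] = sel.astype(float)
        else:
            out[name] = np.stack(
                [resize(f, new_shape, order=1, anti_aliasing=scale < 1) for f in sel]
            )
    meta = dict(movie.meta)
    meta.setdefault("preprocessing", []).append(
        {"resampled_to": {"pixel_size": target_pixel_size, "interval": target_interval}}
    )
    return Movie(
        channels=out,
        pixel_size=target_pixel_size,
        frame_interval=target_interval,
        patient_id=movie.patient_id,
        movie_id=movie.movie_id,
        meta=meta,
    )


def write_movie(movie: Movie, out_dir) -> None:
    """One multi-page grayscale TIFF per channel plus a YAML sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, arr in movie.channels.items():
        tifffile.imwrite(
            out_dir / f"{name}.tif", arr.astype(np.float32), photometric="minisblack"
        )
    meta = {
        "pixel_size": float(movie.pixel_size),
        "frame_interval": float(movie.frame_interval),
        "patient_id": movie.patient_id,
        "movie_id": movie.movie_id,
        "channels": movie.channel_names,
    }
    (out_dir / "movie.yaml").write_text(yaml.safe_dump(meta))


def read_movie(in_dir) -> Movie:
    """Read a movie written by :func:`write_movie`."""
    in_dir = Path(in_dir)
    meta = yaml.safe_load((in_dir / "movie.yaml").read_text())
    channels = {
        name: np.asarray(tifffile.imread(in_dir / f"{name}.tif"), dtype=float)
        for name in meta["channels"]
    }
    return Movie(
        channels=channels,
        pixel_size=meta["pixel_size"],
        frame_interval=meta["frame_interval"],
        patient_id=meta.get("patient_id", ""),
        movie_id=meta.get("movie_id", ""),
    )
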