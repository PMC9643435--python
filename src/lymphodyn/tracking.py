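"""Per-frame cell detection and frame-to-frame track linking.

Detection is band-pass + local-maximum candidate search with sub-pixel
centroid refinement and a mass filter; linking is optimal bipartite
matching per frame pair with a hard per-link displacement bound, gap
memory and a minimum-length filter.  Parameter defaults follow the
pixel-unit tracking configuration used throughout
(25 / 15 / 20 / 10 / 20 / 5000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import center_of_mass, gaussian_filter
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max

from lymphodyn.tracks import (
    DEFAULT_FRAME_INTERVAL,
    DEFAULT_PIXEL_SIZE,
    Track,
)

DEFAULT_DIAMETER = 25
DEFAULT_SEPARATION = 15
DEFAULT_MAX_SPEED = 20
DEFAULT_MEMORY = 10
DEFAULT_FILTER_FRAMES = 20
DEFAULT_MINMASS = 5000


@dataclass
class Detection:
    frame: int
    x: float
    y: float
    mass: float
    diameter_est: float


def detect_cells(
    frame: np.ndarray,
    diameter: float = DEFAULT_DIAMETER,
    separation: float = DEFAULT_SEPARATION,
    minmass: float = DEFAULT_MINMASS,
    frame_index: int = 0,
    byte_scale_mass: bool = True,
) -> list[Detection]:
    """Detect blob centres in a single preprocessed frame.

    The frame is band-passed (difference of Gaussians at 1 px vs the cell
    radius); local maxima closer than ``separation`` resolve to the
    brighter one; the mass (summed raw intensity over the cell footprint)
    must reach ``minmass``.  ``byte_scale_mass`` evaluates the mass on the
    frame rescaled to 0–255, matching byte-valued raw-intensity semantics
    when the input has been normalized to [0, 1].
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0 or frame.max() == frame.min():
        return []
    radius = diameter / 2.0
    bandpassed = gaussian_filter(frame, 1.0) - gaussian_filter(frame, radius)
    bandpassed = np.clip(bandpassed, 0, None)
    peaks = peak_local_max(
        bandpassed,
        min_distance=max(1, int(round(separation))),
        threshold_abs=0.05 * bandpassed.max(),
        exclude_border=False,
    )
    if byte_scale_mass:
        mass_frame = frame / frame.max() * 255.0
    else:
        mass_frame = frame
    ylim, xlim = frame.shape
    r_int = max(1, int(round(radius)))
    out = []
    for py, px in peaks:
        y0, y1 = max(0, py - r_int), min(ylim, py + r_int + 1)
        x0, x1 = max(0, px - r_int), min(xlim, px + r_int + 1)
        patch = mass_frame[y0:y1, x0:x1]
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disk = (yy - py) ** 2 + (xx - px) ** 2 <= r_int**2
        mass = float(patch[disk].sum())
        if mass < minmass:
            continue
        # sub-pixel refinement: intensity-weighted centroid on the patch
        weights = np.where(disk, patch, 0.0)
        cy, cx = center_of_mass(weights)
        out.append(
            Detection(
                frame=frame_index,
                x=float(x0 + cx),
                y=float(y0 + cy),
                mass=mass,
                diameter_est=float(diameter),
            )
        )
    return out


def detect_movie(frames: np.ndarray, **kwargs) -> list[list[Detection]]:
    """Run :func:`detect_cells` over every frame of a channel."""
    return [
        detect_cells(frames[i], frame_index=i, **kwargs)
        for i in range(frames.shape[0])
    ]


class _OpenTrack:
    __slots__ = ("points", "last_frame")

    def __init__(self, det: Detection):
        self.points = [det]
        self.last_frame = det.frame


def link_tracks(
    detections_per_frame: list[list[Detection]],
    max_speed: float = DEFAULT_MAX_SPEED,
    memory: int = DEFAULT_MEMORY,
    filter_frames: int = DEFAULT_FILTER_FRAMES,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    phenotype: str = "",
    movie_id: str = "",
    patient_id: str = "",
) -> list[Track]:
    """Link detections into tracks by per-frame optimal assignment.

    Assignment minimizes the total squared displacement subject to a hard
    per-link bound of ``max_speed`` pixels per elapsed frame.  A track
    absent for up to ``memory`` consecutive frames may be reconnected.
    Tracks with fewer than ``filter_frames`` observed points are dropped.
    Ties resolve deterministically (earlier track wins).
    """
    open_tracks: list[_OpenTrack] = []
    closed: list[_OpenTrack] = []
    big = 1e12
    for f, dets in enumerate(detections_per_frame):
        # retire tracks that exceeded the memory window
        still_open = []
        for tr in open_tracks:
            if f - tr.last_frame > memory + 1:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open
        if not dets:
            continue
        if open_tracks:
            cost = np.full((len(open_tracks), len(dets)), big)
            for i, tr in enumerate(open_tracks):
                gap = f - tr.last_frame
                last = tr.points[-1]
                for j, det in enumerate(dets):
                    d2 = (det.x - last.x) ** 2 + (det.y - last.y) ** 2
                    if d2 <= (max_speed * gap) ** 2:
                        cost[i, j] = d2
            rows, cols = linear_sum_assignment(cost)
            assigned = set()
            for i, j in zip(rows, cols):
                if cost[i, j] < big:
                    open_tracks[i].points.append(dets[j])
                    open_tracks[i].last_frame = f
                    assigned.add(j)
            for j, det in enumerate(dets):
                if j not in assigned:
                    open_tracks.append(_OpenTrack(det))
        else:
            open_tracks = [_OpenTrack(d) for d in dets]
    closed.extend(open_tracks)

    tracks = []
    idx = 0
    for tr in closed:
        if len(tr.points) < filter_frames:
            continue
        tracks.append(
            Track(
                track_id=idx,
                t=np.array([p.frame for p in tr.points]),
                x=np.array([p.x for p in tr.points]),
                y=np.array([p.y for p in tr.points]),
                phenotype=phenotype,
                pixel_size=pixel_size,
                frame_interval=frame_interval,
                movie_id=movie_id,
                patient_id=patient_id,
            )
        )
        idx += 1
    return tracks


def impute_gaps(track: Track) -> Track:
    """Fill missing frames by linear interpolation between observed points.

    Observed points are unchanged; filled points are flagged in
    ``imputed_mask``.  Boundary gaps cannot be imputed — the track keeps
    its observed span.
    """
    t = track.t
    full = np.arange(t[0], t[-1] + 1)
    if len(full) == len(t):
        return track
    x = np.interp(full, t, track.x)
    y = np.interp(full, t, track.y)
    observed = np.isin(full, t)
    return Track(
        track_id=track.track_id,
        t=full,
        x=x,
        y=y,
        phenotype=track.phenotype,
        regime=track.regime,
        pixel_size=track.pixel_size,
        frame_interval=track.frame_interval,
        movie_id=track.movie_id,
        patient_id=track.patient_id,
        imputed_mask=~observed,
    )


def track_movie_channel(
    frames: np.ndarray,
    pixel_size: float,
    frame_interval: float,
    phenotype: str = "",
    movie_id: str = "",
    patient_id: str = "",
    **detect_kwargs,
) -> list[Track]:
    """Detect + link + impute for one channel, with default parameters."""
    dets = detect_movie(frames, **detect_kwargs)
    tracks = link_tracks(
        dets,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        phenotype=phenotype,
        movie_id=movie_id,
        patient_id=patient_id,
    )
    return [impute_gaps(tr) for tr in tracks]
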