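"""Invariant movement representation and the 15-entry summary vector.

A track of absolute positions is converted to a translation/rotation
invariant series of (speed, speed-change, turning-angle) triples, plus
three path distances.  Summaries are mean/std/min/max of each series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lymphodyn.tracks import Track

#: Canonical order of the summary features.
FEATURE_NAMES = (
    "velocity_mean",
    "velocity_std",
    "velocity_min",
    "velocity_max",
    "acceleration_mean",
    "acceleration_std",
    "acceleration_min",
    "acceleration_max",
    "angle_mean",
    "angle_std",
    "angle_min",
    "angle_max",
    "total_distance",
    "net_distance",
    "maximum_distance",
)


@dataclass
class RelativeTrack:
    """Invariant (v, a, r) series of a track.

    v in μm/min, a in μm/min per frame, r in radians ∈ [−π, π]
    (clockwise positive in image coordinates, y pointing down).
    All three series share length L = l − 2 and are aligned on the
    interior points of the source track.
    """

    v: np.ndarray
    a: np.ndarray
    r: np.ndarray
    degenerate_mask: np.ndarray  # True where an angle came from a zero step
    source_track_id: object = None

    def __len__(self) -> int:
        return len(self.v)

    def as_array(self) -> np.ndarray:
        """(L, 3) array of (v, a, r) triples — the level-2 model input."""
        return np.column_stack([self.v, self.a, self.r])


def _resolve_factor(track: Track, conversion_factor: float | None) -> float:
    if conversion_factor is None:
        return track.conversion_factor
    return float(conversion_factor)


def compute_velocity(
    track: Track,
    scheme: str = "forward",
    conversion_factor: float | None = None,
) -> np.ndarray:
    """Per-step speeds in μm/min.

    ``forward``: v_i = ‖p_{i+1} − p_i‖ / Δframe (length l−1).
    ``centered``: v_i = ‖p_{i+1} − p_{i−1}‖ / (2 Δframe) (length l−2).
    Centered differencing cancels frame-to-frame jitter, so its mean is
    never above the forward mean on noisy tracks.
    """
    p = track.positions
    factor = _resolve_factor(track, conversion_factor)
    if scheme == "forward":
        if len(p) < 2:
            raise ValueError("forward velocity needs at least 2 points")
        step = np.diff(p, axis=0)
        dt = np.diff(track.t)
        return np.linalg.norm(step, axis=1) / dt * factor
    if scheme == "centered":
        if len(p) < 3:
            raise ValueError("centered velocity needs at least 3 points")
        span = p[2:] - p[:-2]
        dt = track.t[2:] - track.t[:-2]
        return np.linalg.norm(span, axis=1) / dt * factor
    raise ValueError(f"unknown scheme {scheme!r} (use 'forward' or 'centered')")


def compute_acceleration(
    track: Track, conversion_factor: float | None = None
) -> np.ndarray:
    """Magnitude of the second position difference, unit-converted.

    Returned in μm/min per frame; length l − 2.
    """
    p = track.positions
    if len(p) < 3:
        raise ValueError("acceleration needs at least 3 points")
    factor = _resolve_factor(track, conversion_factor)
    second = p[2:] - 2 * p[1:-1] + p[:-2]
    return np.linalg.norm(second, axis=1) * factor


def compute_turning_angles(
    track: Track, return_degenerate_mask: bool = False
):
    """Signed heading change between consecutive segments, in [−π, π].

    Sign convention: clockwise positive in image coordinates (y down).
    Zero-length segments give a flagged angle of 0.
    """
    p = track.positions
    if len(p) < 3:
        raise ValueError("turning angles need at least 3 points")
    seg = np.diff(p, axis=0)
    a, b = seg[:-1], seg[1:]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = np.einsum("ij,ij->i", a, b)
    degenerate = (np.linalg.norm(a, axis=1) == 0) | (np.linalg.norm(b, axis=1) == 0)
    angles = np.where(degenerate, 0.0, np.arctan2(cross, dot))
    if return_degenerate_mask:
        return angles, degenerate
    return angles


def compute_distances(
    track: Track, conversion_factor: float | None = None
) -> tuple[float, float, float]:
    """(total, net, maximum) path distances in μm.

    total = path length, net = start-to-end displacement, maximum =
    largest excursion from the start point.  Always total ≥ maximum ≥ net.
    """
    p = track.positions * track.pixel_size
    if len(p) < 2:
        raise ValueError("distances need at least 2 points")
    total = float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())
    net = float(np.linalg.norm(p[-1] - p[0]))
    maximum = float(np.linalg.norm(p - p[0], axis=1).max())
    return total, net, maximum


def relative_track(
    track: Track,
    scheme: str = "forward",
    conversion_factor: float | None = None,
) -> RelativeTrack:
    """Build the aligned invariant series for a gap-free track.

    All three series are trimmed to the l − 2 interior points so the
    triples line up, as required by sequence models.
    """
    if len(track) < 3:
        raise ValueError("relative representation needs at least 3 points")
    v = compute_velocity(track, scheme=scheme, conversion_factor=conversion_factor)
    if scheme == "forward":
        v = v[1:]  # align forward speed at step i with interior point i
    a = compute_acceleration(track, conversion_factor=conversion_factor)
    r, degenerate = compute_turning_angles(track, return_degenerate_mask=True)
    return RelativeTrack(
        v=v, a=a, r=r, degenerate_mask=degenerate, source_track_id=track.track_id
    )


def summarize_features(
    rel: RelativeTrack, distances: tuple[float, float, float]
) -> np.ndarray:
    """The 15-entry summary vector in :data:`FEATURE_NAMES` order.

    Angles flagged as degenerate contribute 0 to mean/std but are excluded
    from min/max (an undefined heading should not create spurious extremes).
    """
    total, net, maximum = distances
    v, a, r = rel.v, rel.a, rel.r
    valid_r = r[~rel.degenerate_mask]
    if valid_r.size == 0:
        valid_r = np.zeros(1)
    out = np.array(
        [
            v.mean(), v.std(), v.min(), v.max(),
            a.mean(), a.std(), a.min(), a.max(),
            r.mean(), r.std(), valid_r.min(), valid_r.max(),
            total, net, maximum,
        ]
    )
    assert out.shape == (len(FEATURE_NAMES),)
    return out


def feature_vector(
    track: Track,
    scheme: str = "forward",
    conversion_factor: float | None = None,
) -> np.ndarray:
    """Convenience: track → 15-entry summary in one call."""
    rel = relative_track(track, scheme=scheme, conversion_factor=conversion_factor)
    return summarize_features(
        rel, compute_distances(track, conversion_factor=conversion_factor)
    )


def feature_table(tracks, scheme: str = "forward", conversion_factor=None):
    """Per-track feature table with identity columns, as a DataFrame."""
    import pandas as pd

    rows = []
    for tr in tracks:
        vec = feature_vector(tr, scheme=scheme, conversion_factor=conversion_factor)
        row = dict(zip(FEATURE_NAMES, vec))
        row.update(
            track_id=tr.track_id,
            phenotype=tr.phenotype,
            regime=tr.regime if tr.regime is not None else "",
            movie_id=tr.movie_id,
            patient_id=tr.patient_id,
        )
        rows.append(row)
    return pd.DataFrame(rows)
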