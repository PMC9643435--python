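"""Descriptive group statistics: velocity summaries, rank tests and the
displacement-vs-√time diffusion check."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from lymphodyn.features import compute_velocity


@dataclass
class GroupSummary:
    phenotype: str
    mean_velocity: float  # grand mean over all steps, μm/min
    mean_track_median_velocity: float  # mean over tracks of per-track median
    angle_abs_mean: float  # mean |turning angle|, radians
    n_tracks: int
    n_steps: int


def summarize_group(
    tracks, phenotype: str = "", scheme: str = "forward", conversion_factor=None
) -> GroupSummary:
    """Pooled mean step speed and mean of per-track median speeds.

    "Mean velocity" pools every step of every track into one grand mean;
    the track-median summary averages one median per track, so track
    lengths do not weight it.
    """
    from lymphodyn.features import compute_turning_angles

    tracks = [tr for tr in tracks if len(tr) >= 2]
    if not tracks:
        raise ValueError("empty group")
    all_speeds, medians, abs_angles = [], [], []
    for tr in tracks:
        v = compute_velocity(tr, scheme=scheme, conversion_factor=conversion_factor)
        all_speeds.append(v)
        medians.append(np.median(v))
        if len(tr) >= 3:
            abs_angles.append(np.abs(compute_turning_angles(tr)))
    pooled = np.concatenate(all_speeds)
    return GroupSummary(
        phenotype=phenotype,
        mean_velocity=float(pooled.mean()),
        mean_track_median_velocity=float(np.mean(medians)),
        angle_abs_mean=float(np.concatenate(abs_angles).mean()) if abs_angles else float("nan"),
        n_tracks=len(tracks),
        n_steps=int(pooled.size),
    )


def mannwhitney_compare(group_a, group_b, alpha: float = 1e-4):
    """Two-sided Mann–Whitney U test with the significance rule p < alpha.

    Exact enumeration for small samples (n ≤ 20 in both groups, no ties),
    normal approximation with tie correction otherwise.  Fully tied data
    across both groups gives p = 1 and is flagged.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        return float(a.size * b.size / 2), 1.0, False
    method = "exact" if (a.size <= 20 and b.size <= 20) else "asymptotic"
    try:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:  # ties with exact method
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    p = float(res.pvalue)
    return float(res.statistic), p, bool(p < alpha)


def displacement_vs_sqrt_time(tracks, max_lag: int | None = None):
    """Regress mean displacement at lag τ on √τ.

    For diffusive (uncorrelated random-walk) motion the mean displacement
    grows like √τ, so the fit is linear with intercept ≈ 0 and high R²;
    ballistic motion curves systematically.  Returns
    ``(slope, intercept, r_squared, lags, mean_displacements)``.
    """
    tracks = [tr for tr in tracks if len(tr) >= 20]
    if not tracks:
        raise ValueError("need tracks with at least 20 points")
    if max_lag is None:
        max_lag = min(len(tr) for tr in tracks) - 1
    lags = np.arange(1, max_lag + 1)
    if len(lags) < 3:
        raise ValueError("need at least 3 distinct lags")
    means = []
    for lag in lags:
        disps = []
        for tr in tracks:
            p = tr.positions * tr.pixel_size
            if len(p) > lag:
                disps.append(np.linalg.norm(p[lag:] - p[:-lag], axis=1))
        means.append(np.concatenate(disps).mean())
    means = np.array(means)
    fit = sps.linregress(np.sqrt(lags), means)
    return (
        float(fit.slope),
        float(fit.intercept),
        float(fit.rvalue**2),
        lags,
        means,
    )
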