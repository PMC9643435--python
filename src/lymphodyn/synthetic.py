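"""Synthetic movie/track generator with full ground truth.

Emulates the statistical structure of multi-channel confocal lymphocyte
movies: heavy-tailed per-frame speeds (log-normal), correlated random
walks split into directed/undirected regimes, anisotropic Gaussian cell
blobs with slowly drifting orientation, a pulsating filamentous
dendritic-network channel with an analytically known motion law, and
Poisson-Gaussian imaging noise.  Everything is deterministic under a
fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from lymphodyn.io_preprocess import Movie
from lymphodyn.tracks import Track

#: turning-angle std (radians) used for directed-regime steps; undirected
#: steps use the preset's own turning_angle_std.
DIRECTED_TURN_STD = 0.25

#: lymphocyte-to-FDC coupling radius in μm.
COUPLING_RADIUS_UM = 8.0


@dataclass(frozen=True)
class PhenotypePreset:
    """Prototypical motion/morphology parameters of one cell population."""

    name: str
    mean_speed: float  # μm/min, population mean of per-frame speeds
    speed_dispersion: float  # log-normal shape parameter (σ of log-speed)
    turning_angle_std: float  # radians, undirected-regime heading noise
    directed_fraction: float  # proportion of directed tracks
    cell_diameter_mean: float  # μm (major axis)
    eccentricity_mean: float
    intensity_mean: float = 200.0

    def __post_init__(self) -> None:
        if not 0 <= self.directed_fraction <= 1:
            raise ValueError("directed_fraction must be in [0, 1]")
        if not 0 <= self.eccentricity_mean < 1:
            raise ValueError("eccentricity_mean must be in [0, 1)")
        if self.mean_speed < 0 or self.speed_dispersion < 0:
            raise ValueError("speed parameters must be non-negative")
        if self.turning_angle_std < 0:
            raise ValueError("turning_angle_std must be ≥ 0")
        if self.cell_diameter_mean <= 0 or self.intensity_mean <= 0:
            raise ValueError("scale parameters must be positive")

    @property
    def median_speed(self) -> float:
        """Median of the log-normal per-frame speed law."""
        if self.mean_speed == 0:
            return 0.0
        return self.mean_speed * math.exp(-0.5 * self.speed_dispersion**2)


def dispersion_for_mean_median(mean: float, median: float) -> float:
    """Log-normal shape giving the requested mean and median simultaneously."""
    if median <= 0 or mean < median:
        raise ValueError("need mean ≥ median > 0")
    return math.sqrt(2.0 * math.log(mean / median))


# Qualitative ordering across populations: PD1 fastest and largest;
# CD20 turns most and has the lowest directed ratio and highest
# eccentricity.  Dispersions calibrated so mean/median speeds hit
# 2.00/1.65, 2.06/1.72 and 2.55/2.11 μm/min.
DEFAULT_PRESETS: dict[str, PhenotypePreset] = {
    "CD20": PhenotypePreset(
        name="CD20", mean_speed=2.00,
        speed_dispersion=dispersion_for_mean_median(2.00, 1.65),
        turning_angle_std=2.0, directed_fraction=0.23,
        cell_diameter_mean=7.0, eccentricity_mean=0.60,
    ),
    "CD3": PhenotypePreset(
        name="CD3", mean_speed=2.06,
        speed_dispersion=dispersion_for_mean_median(2.06, 1.72),
        turning_angle_std=0.8, directed_fraction=0.35,
        cell_diameter_mean=7.0, eccentricity_mean=0.35,
    ),
    "PD1": PhenotypePreset(
        name="PD1", mean_speed=2.55,
        speed_dispersion=dispersion_for_mean_median(2.55, 2.11),
        turning_angle_std=1.2, directed_fraction=0.38,
        cell_diameter_mean=10.0, eccentricity_mean=0.25,
    ),
}


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, calibration and noise of a rendered scene."""

    n_cells_per_phenotype: int = 10
    n_frames: int = 60
    frame_shape: tuple[int, int] = (256, 256)  # (Y, X) pixels
    pixel_size: float = 0.4  # μm / pixel
    frame_interval: float = 20.0  # seconds / frame
    noise_sigma: float = 0.0  # Gaussian read-noise, intensity units
    psf_sigma: float = 0.0  # extra PSF blur in pixels
    fdc_pulse_amplitude: float = 0.5  # μm
    fdc_pulse_period: int = 12  # frames
    coupling_strength: float = 0.0  # lymphocyte-to-FDC velocity coupling
    seed: int = 0
    min_separation_px: float = 20.0  # placement constraint at t = 0
    n_fdc_segments: int = 40

    def __post_init__(self) -> None:
        if self.n_cells_per_phenotype < 0 or self.n_frames < 20:
            raise ValueError("need non-negative cell count and n_frames ≥ 20")
        if min(self.frame_shape) < 64:
            raise ValueError("frame_shape must be at least 64×64")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("calibration must be positive")
        if self.fdc_pulse_amplitude < 0 or self.fdc_pulse_period < 2:
            raise ValueError("invalid FDC pulse parameters")
        if self.noise_sigma < 0 or self.psf_sigma < 0:
            raise ValueError("noise parameters must be ≥ 0")


@dataclass
class FdcNetwork:
    """Rigidly oscillating line segments forming the dendritic channel."""

    centers: np.ndarray  # (S, 2) px, (x, y)
    directions: np.ndarray  # (S, 2) unit orientation of each segment
    half_lengths: np.ndarray  # (S,) px
    osc_dirs: np.ndarray  # (S, 2) unit direction of oscillation
    phases: np.ndarray  # (S,)
    amplitude_px: float
    period: int
    speckle: list[np.ndarray] = field(default_factory=list)  # per-segment amps

    def offset(self, frame: int) -> np.ndarray:
        """(S, 2) rigid displacement of every segment at a frame, px."""
        s = self.amplitude_px * np.sin(
            2 * np.pi * frame / self.period + self.phases
        )
        return s[:, None] * self.osc_dirs

    def sample_points(self, frame: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense points along every segment at a frame.

        Returns (points (P, 2), amplitudes (P,), segment index (P,)).
        """
        off = self.offset(frame)
        pts, amps, seg_idx = [], [], []
        for s in range(len(self.centers)):
            n = len(self.speckle[s])
            ts = np.linspace(-self.half_lengths[s], self.half_lengths[s], n)
            p = self.centers[s] + ts[:, None] * self.directions[s] + off[s]
            pts.append(p)
            amps.append(self.speckle[s])
            seg_idx.append(np.full(n, s))
        return np.concatenate(pts), np.concatenate(amps), np.concatenate(seg_idx)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    tracks: list[Track]
    pixel_labels: dict[str, np.ndarray]  # phenotype → (M, Y, X) bool
    fdc_displacement_field: np.ndarray | None  # (M−1, Y, X, 2) px/frame
    fdc_occupancy: np.ndarray | None = None  # (M, Y, X) bool


# ---------------------------------------------------------------------------
# track simulation


def _lognormal_speeds(rng, mean: float, shape: float, size) -> np.ndarray:
    if mean == 0:
        return np.zeros(size)
    mu = math.log(mean) - 0.5 * shape**2
    if shape == 0:
        return np.full(size, mean)
    return rng.lognormal(mean=mu, sigma=shape, size=size)


def simulate_tracks(
    preset: PhenotypePreset,
    config: SceneConfig,
    n_tracks: int | None = None,
    rng: np.random.Generator | None = None,
    start_positions: np.ndarray | None = None,
    fdc: FdcNetwork | None = None,
) -> list[Track]:
    """Correlated random walks with a heavy-tailed speed law.

    Each track is assigned a regime: directed tracks keep a nearly
    constant heading (std :data:`DIRECTED_TURN_STD`), undirected tracks
    re-orient with the preset's turning_angle_std.  Per-frame step speeds
    are log-normal with population mean ``preset.mean_speed`` so that the
    grand mean over many tracks converges to the configured value.

    When an :class:`FdcNetwork` is supplied and ``coupling_strength`` > 0,
    steps taken within :data:`COUPLING_RADIUS_UM` of a filament inherit
    ``coupling_strength`` times the local filament displacement.
    """
    if n_tracks is None:
        n_tracks = config.n_cells_per_phenotype
    if n_tracks <= 0:
        raise ValueError("n_tracks must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    m = config.n_frames
    dt_min = config.frame_interval / 60.0
    ylim, xlim = config.frame_shape
    if start_positions is None:
        margin = 5.0
        start_positions = np.column_stack(
            [
                rng.uniform(margin, xlim - margin, n_tracks),
                rng.uniform(margin, ylim - margin, n_tracks),
            ]
        )
    regimes = np.where(
        rng.random(n_tracks) < preset.directed_fraction, "directed", "undirected"
    )

    # pre-build filament KD-trees for coupling lookups
    trees = None
    if fdc is not None and config.coupling_strength > 0:
        trees = []
        for f in range(m - 1):
            pts, _, seg_idx = fdc.sample_points(f)
            trees.append((cKDTree(pts), seg_idx, fdc.offset(f + 1) - fdc.offset(f)))

    tracks = []
    for i in range(n_tracks):
        speeds = _lognormal_speeds(rng, preset.mean_speed, preset.speed_dispersion, m - 1)
        turn_std = (
            min(DIRECTED_TURN_STD, preset.turning_angle_std)
            if regimes[i] == "directed"
            else preset.turning_angle_std
        )
        heading = rng.uniform(-np.pi, np.pi)
        turns = rng.normal(0.0, turn_std, m - 1) if turn_std > 0 else np.zeros(m - 1)
        pos = np.empty((m, 2))
        pos[0] = start_positions[i]
        for j in range(m - 1):
            if j > 0:
                heading = np.angle(np.exp(1j * (heading + turns[j])))
            step_um = speeds[j] * dt_min
            step_px = step_um / config.pixel_size
            d = np.array([np.cos(heading), np.sin(heading)]) * step_px
            if trees is not None:
                tree, seg_idx, seg_step = trees[j]
                dist, idx = tree.query(pos[j])
                if dist * config.pixel_size <= COUPLING_RADIUS_UM:
                    d = d + config.coupling_strength * seg_step[seg_idx[idx]]
            pos[j + 1] = pos[j] + d
        tracks.append(
            Track(
                track_id=f"{preset.name}_{i}",
                t=np.arange(m),
                x=pos[:, 0],
                y=pos[:, 1],
                phenotype=preset.name,
                regime=str(regimes[i]),
                pixel_size=config.pixel_size,
                frame_interval=config.frame_interval,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# FDC channel


def analytic_mean_node_speed(
    amplitude_um: float, period_frames: int, frame_interval_s: float
) -> float:
    """Time-mean per-frame node speed of the sinusoidal jitter, μm/min.

    A node at A·sin(2πt/T + φ)·d moves |2A sin(π/T) cos(·)| per frame;
    averaging |cos| over a uniform phase gives the 2/π factor.
    """
    per_frame_um = (4.0 / np.pi) * amplitude_um * math.sin(math.pi / period_frames)
    return per_frame_um * 60.0 / frame_interval_s


def amplitude_for_mean_speed(
    speed_um_min: float, period_frames: int, frame_interval_s: float
) -> float:
    """Invert :func:`analytic_mean_node_speed` for calibrated scenes."""
    per_frame_um = speed_um_min * frame_interval_s / 60.0
    return per_frame_um * np.pi / (4.0 * math.sin(math.pi / period_frames))


def _splat_gaussians(image: np.ndarray, pts: np.ndarray, amps, sigma: float) -> None:
    """Accumulate isotropic Gaussian blobs into ``image`` in place."""
    ylim, xlim = image.shape
    r = max(2, int(math.ceil(4 * sigma)))
    amps = np.broadcast_to(np.asarray(amps, dtype=float), (len(pts),))
    for (x, y), a in zip(pts, amps):
        x0, x1 = int(math.floor(x)) - r, int(math.floor(x)) + r + 1
        y0, y1 = int(math.floor(y)) - r, int(math.floor(y)) + r + 1
        cx0, cx1 = max(0, x0), min(xlim, x1)
        cy0, cy1 = max(0, y0), min(ylim, y1)
        if cx0 >= cx1 or cy0 >= cy1:
            continue
        yy, xx = np.mgrid[cy0:cy1, cx0:cx1]
        image[cy0:cy1, cx0:cx1] += a * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2)
        )


def build_fdc_network(config: SceneConfig, rng: np.random.Generator) -> FdcNetwork:
    """Random segments with per-segment rigid sinusoidal jitter and a
    fixed speckle texture that travels with each segment (so motion is
    observable by optical flow even along the filament axis)."""
    ylim, xlim = config.frame_shape
    s = config.n_fdc_segments
    # rejection-sample segments so no two filaments cross or touch: a
    # crossing produces interference patterns whose apparent motion is not
    # the filament motion, which would corrupt the flow ground truth
    min_gap = 6.0
    kept_pts: list[np.ndarray] = []
    centers_l, theta_l, half_l = [], [], []
    attempts = 0
    while len(centers_l) < s and attempts < 300 * s:
        attempts += 1
        c = np.array([rng.uniform(10, xlim - 10), rng.uniform(10, ylim - 10)])
        th = rng.uniform(0, np.pi)
        hl = rng.uniform(8, 22)
        d = np.array([math.cos(th), math.sin(th)])
        ts = np.linspace(-hl, hl, max(4, int(round(2 * hl / 2.0))))
        pts = c + ts[:, None] * d
        if kept_pts:
            existing = np.concatenate(kept_pts)
            dists = np.linalg.norm(
                pts[:, None, :] - existing[None, :, :], axis=-1
            )
            if dists.min() < min_gap:
                continue
        kept_pts.append(pts)
        centers_l.append(c)
        theta_l.append(th)
        half_l.append(hl)
    centers = np.array(centers_l)
    theta = np.array(theta_l)
    directions = np.column_stack([np.cos(theta), np.sin(theta)])
    half_lengths = np.array(half_l)
    s = len(centers)
    osc_theta = rng.uniform(0, 2 * np.pi, s)
    osc_dirs = np.column_stack([np.cos(osc_theta), np.sin(osc_theta)])
    phases = rng.uniform(0, 2 * np.pi, s)
    # beaded texture: wider blob spacing with strong amplitude contrast
    # gives the flow estimator unambiguous 2D features along the filament
    speckle = []
    for hl in half_lengths:
        n = max(4, int(round(2 * hl / 1.8)))
        base = 0.35 + 1.3 * rng.random(n)
        base[0] *= 2.5  # bright node blobs at the endpoints
        base[-1] *= 2.5
        speckle.append(base)
    return FdcNetwork(
        centers=centers,
        directions=directions,
        half_lengths=half_lengths,
        osc_dirs=osc_dirs,
        phases=phases,
        amplitude_px=config.fdc_pulse_amplitude / config.pixel_size,
        period=config.fdc_pulse_period,
        speckle=speckle,
    )


def simulate_fdc_channel(
    config: SceneConfig,
    rng: np.random.Generator | None = None,
    network: FdcNetwork | None = None,
    intensity: float = 120.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, FdcNetwork]:
    """Render the pulsating network channel and its true displacement field.

    Returns ``(frames (M, Y, X), flow (M−1, Y, X, 2) in px/frame with
    (dx, dy) order, occupancy (M, Y, X) bool, network)``.  Because each
    segment moves rigidly, every occupied pixel's true displacement equals
    its segment's node displacement, so the field mean matches
    :func:`analytic_mean_node_speed`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if network is None:
        network = build_fdc_network(config, rng)
    m = config.n_frames
    ylim, xlim = config.frame_shape
    frames = np.zeros((m, ylim, xlim))
    occupancy = np.zeros((m, ylim, xlim), dtype=bool)
    flow = np.zeros((m - 1, ylim, xlim, 2))
    seg_pts_cache = []
    for f in range(m):
        pts, amps, seg_idx = network.sample_points(f)
        seg_pts_cache.append((pts, seg_idx))
        _splat_gaussians(frames[f], pts, amps * intensity / 2.0, sigma=1.1)
        ix = np.clip(np.round(pts[:, 0]).astype(int), 0, xlim - 1)
        iy = np.clip(np.round(pts[:, 1]).astype(int), 0, ylim - 1)
        occupancy[f, iy, ix] = True
    for f in range(m - 1):
        step = network.offset(f + 1) - network.offset(f)  # (S, 2) px
        pts, seg_idx = seg_pts_cache[f]
        ix = np.clip(np.round(pts[:, 0]).astype(int), 0, xlim - 1)
        iy = np.clip(np.round(pts[:, 1]).astype(int), 0, ylim - 1)
        flow[f, iy, ix] = step[seg_idx]
    return frames, flow, occupancy, network


# ---------------------------------------------------------------------------
# scene rendering


def _place_starts(config: SceneConfig, n: int, rng) -> np.ndarray:
    """Rejection-sample start positions with a minimum pairwise separation."""
    ylim, xlim = config.frame_shape
    margin = 12.0
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError(
                f"cannot place {n} cells with separation "
                f"{config.min_separation_px} px in {config.frame_shape}"
            )
        cand = np.array(
            [rng.uniform(margin, xlim - margin), rng.uniform(margin, ylim - margin)]
        )
        if all(
            np.linalg.norm(cand - p) >= config.min_separation_px for p in placed
        ):
            placed.append(cand)
    return np.array(placed)


def _render_cell_blob(
    image: np.ndarray,
    x: float,
    y: float,
    amp: float,
    sigma_major: float,
    sigma_minor: float,
    orientation: float,
) -> None:
    """Anisotropic Gaussian blob, added in place."""
    ylim, xlim = image.shape
    r = max(3, int(math.ceil(4 * sigma_major)))
    x0, x1 = max(0, int(x) - r), min(xlim, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(ylim, int(y) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - x, yy - y
    c, s = math.cos(orientation), math.sin(orientation)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    image[y0:y1, x0:x1] += amp * np.exp(
        -0.5 * ((u / sigma_major) ** 2 + (v / sigma_minor) ** 2)
    )


def render_scene(
    config: SceneConfig,
    presets: dict[str, PhenotypePreset] | None = None,
    include_fdc: bool = True,
) -> tuple[Movie, GroundTruth]:
    """Full multi-channel movie plus ground truth.

    One channel per phenotype preset, optionally a CD35-like network
    channel.  Cells are anisotropic Gaussian blobs whose FWHM along the
    major axis equals the preset diameter; orientation drifts slowly and
    eccentricity fluctuates around the preset mean.  Cells within the
    coupling radius of a filament inherit a velocity component
    proportional to the local filament velocity.
    """
    if presets is None:
        presets = DEFAULT_PRESETS
    if not presets:
        raise ValueError("need at least one phenotype preset")
    rng = np.random.default_rng(config.seed)
    m = config.n_frames
    ylim, xlim = config.frame_shape

    fdc_frames = fdc_flow = fdc_occ = network = None
    if include_fdc:
        fdc_frames, fdc_flow, fdc_occ, network = simulate_fdc_channel(config, rng=rng)

    channels: dict[str, np.ndarray] = {}
    all_tracks: list[Track] = []
    pixel_labels: dict[str, np.ndarray] = {}
    for name, preset in presets.items():
        n = config.n_cells_per_phenotype
        starts = _place_starts(config, n, rng)
        tracks = simulate_tracks(
            preset, config, n_tracks=n, rng=rng, start_positions=starts, fdc=network
        )
        frames = np.zeros((m, ylim, xlim))
        labels = np.zeros((m, ylim, xlim), dtype=bool)
        # thresholding a Gaussian at half max gives semi-axis σ√(2 ln 2),
        # so FWHM = diameter puts the measured major axis at the preset value
        sigma_major0 = preset.cell_diameter_mean / config.pixel_size / 2.3548
        for tr in tracks:
            orient = rng.uniform(0, np.pi)
            ecc = preset.eccentricity_mean
            for j in range(m):
                orient += rng.normal(0, 0.15)  # slow orientation drift
                ecc = float(
                    np.clip(
                        ecc + rng.normal(0, 0.03) + 0.05 * (preset.eccentricity_mean - ecc),
                        0.0,
                        0.95,
                    )
                )
                sigma_minor = sigma_major0 * math.sqrt(1 - ecc**2)
                _render_cell_blob(
                    frames[j], tr.x[j], tr.y[j], preset.intensity_mean,
                    sigma_major0, sigma_minor, orient,
                )
                rad = int(round(sigma_major0 * 1.5))
                y0 = max(0, int(tr.y[j]) - rad)
                y1 = min(ylim, int(tr.y[j]) + rad + 1)
                x0 = max(0, int(tr.x[j]) - rad)
                x1 = min(xlim, int(tr.x[j]) + rad + 1)
                if y0 < y1 and x0 < x1:
                    yy, xx = np.mgrid[y0:y1, x0:x1]
                    disk = (yy - tr.y[j]) ** 2 + (xx - tr.x[j]) ** 2 <= rad**2
                    labels[j, y0:y1, x0:x1] |= disk
        channels[name] = frames
        pixel_labels[name] = labels
        all_tracks.extend(tracks)

    if include_fdc:
        channels["CD35"] = fdc_frames

    if config.psf_sigma > 0:
        from scipy.ndimage import gaussian_filter

        for name in channels:
            channels[name] = gaussian_filter(
                channels[name], sigma=(0, config.psf_sigma, config.psf_sigma)
            )
    if config.noise_sigma > 0:
        gain = 0.25  # photons per intensity unit for shot noise
        for name in channels:
            shot = rng.poisson(np.clip(channels[name], 0, None) * gain) / gain
            channels[name] = shot + rng.normal(
                0, config.noise_sigma, channels[name].shape
            )
            channels[name] = np.clip(channels[name], 0, None)

    movie = Movie(
        channels=channels,
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
        movie_id=f"sim_seed{config.seed}",
        patient_id="sim",
    )
    truth = GroundTruth(
        tracks=all_tracks,
        pixel_labels=pixel_labels,
        fdc_displacement_field=fdc_flow,
        fdc_occupancy=fdc_occ,
    )
    return movie, truth


def scene_config_from_yaml(path) -> SceneConfig:
    import yaml

    data = yaml.safe_load(open(path))
    if "frame_shape" in data:
        data["frame_shape"] = tuple(data["frame_shape"])
    return SceneConfig(**data)
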