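"""Track container shared by the simulator, the tracker and the feature stage.

Positions are stored in pixels together with the spatial/temporal
calibration so that every downstream consumer can convert to physical
units consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: speed conversion used throughout when no calibration-derived factor is
#: requested: μm/min per (pixel/frame) at 0.4 μm/px and 20 s/frame.
DEFAULT_CONVERSION_FACTOR = 1.23

DEFAULT_PIXEL_SIZE = 0.4  # μm / pixel
DEFAULT_FRAME_INTERVAL = 20.0  # seconds / frame


@dataclass
class Track:
    """A single cell's trajectory: ordered (t, x, y) samples in pixel units.

    Parameters
    ----------
    track_id : str or int
        Unique identifier.
    t : ndarray of int
        Frame indices, strictly increasing.
    x, y : ndarray of float
        Positions in pixels (x = column, y = row).
    phenotype : str
        Marker label (e.g. ``"CD3"``); empty if unknown.
    regime : str or None
        Motion-regime ground truth (``"directed"``/``"undirected"``) when
        produced by the simulator.
    pixel_size : float
        μm per pixel.
    frame_interval : float
        Seconds per frame.
    imputed_mask : ndarray of bool or None
        Per-point flag marking gap-filled positions.
    """

    track_id: object
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    phenotype: str = ""
    regime: str | None = None
    pixel_size: float = DEFAULT_PIXEL_SIZE
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    movie_id: str = ""
    patient_id: str = ""
    imputed_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if self.imputed_mask is None:
            self.imputed_mask = np.zeros(len(self.t), dtype=bool)
        else:
            self.imputed_mask = np.asarray(self.imputed_mask, dtype=bool)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def positions(self) -> np.ndarray:
        """(l, 2) array of (x, y) pixel positions."""
        return np.column_stack([self.x, self.y])

    @property
    def conversion_factor(self) -> float:
        """μm/min per pixel/frame implied by this track's calibration."""
        return self.pixel_size * 60.0 / self.frame_interval

    def to_frame(self) -> pd.DataFrame:
        """One row per point, with both pixel and μm coordinates."""
        return pd.DataFrame(
            {
                "track_id": self.track_id,
                "frame": self.t,
                "t_seconds": self.t * self.frame_interval,
                "x_px": self.x,
                "y_px": self.y,
                "x_um": self.x * self.pixel_size,
                "y_um": self.y * self.pixel_size,
                "phenotype": self.phenotype,
                "regime": self.regime if self.regime is not None else "",
                "imputed": self.imputed_mask,
            }
        )


def tracks_to_csv(tracks: list[Track], path) -> None:
    """Write tracks to the canonical CSV schema."""
    if not tracks:
        raise ValueError("no tracks to write")
    pd.concat([tr.to_frame() for tr in tracks], ignore_index=True).to_csv(
        path, index=False
    )


def tracks_from_csv(
    path,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> list[Track]:
    """Read tracks written by :func:`tracks_to_csv`."""
    df = pd.read_csv(path)
    out = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        regime = None
        if "regime" in grp.columns:
            vals = grp["regime"].astype(str)
            if len(vals) and vals.iloc[0] not in ("", "nan"):
                regime = vals.iloc[0]
        out.append(
            Track(
                track_id=tid,
                t=grp["frame"].to_numpy(),
                x=grp["x_px"].to_numpy(),
                y=grp["y_px"].to_numpy(),
                phenotype=str(grp["phenotype"].iloc[0]) if "phenotype" in grp else "",
                regime=regime,
                pixel_size=pixel_size,
                frame_interval=frame_interval,
                imputed_mask=grp["imputed"].to_numpy()
                if "imputed" in grp
                else None,
            )
        )
    return out
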