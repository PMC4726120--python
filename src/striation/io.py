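"""Reading and writing image stacks, time metadata and result tables.

Input stacks are multi-page grayscale TIFFs (8/12/16-bit or float), one
stack per field of view.  Frame acquisition times are supplied separately
(sidecar CSV/YAML or an explicit list) and are expressed in minutes
relative to micro-irradiation, so the first frame is at ``t <= 0``.
TIFF-embedded timestamps are deliberately ignored: they are not portable
across acquisition-software dialects.

Stacks acquired with several z-planes per time point are reduced to 2D
before analysis; the default policy is a per-pixel maximum-intensity
projection, which preserves the stripe signal under focal drift.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "FrameStack",
    "read_stack",
    "read_times",
    "write_stack",
    "write_times",
    "write_ms_table",
    "read_ms_table",
]


@dataclass
class FrameStack:
    """A timed sequence of 2D intensity frames for one field of view.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Non-negative, finite intensity rasters; all frames share the same
        width and height.  Pixel coordinates are 0-based, row-major, with
        the origin at the top-left corner and y increasing downward.
    times_min : ndarray, shape (T,)
        Acquisition time of each frame in minutes relative to
        micro-irradiation; strictly increasing, first entry at or
        before 0.
    pixel_size_um : float, optional
        Physical pixel size in micrometres (informational only).
    channel_label : str
        Free-text channel description.
    """

    frames: np.ndarray
    times_min: np.ndarray
    pixel_size_um: float | None = None
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.times_min = np.asarray(self.times_min, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (T, H, W) array, got shape {self.frames.shape}"
            )
        if len(self.times_min) != len(self.frames):
            raise ValueError(
                f"{len(self.frames)} frames but {len(self.times_min)} time points"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if self.frames.size and self.frames.min() < 0:
            raise ValueError("frame intensities must be >= 0")
        if len(self.times_min) == 0:
            raise ValueError("stack must contain at least one frame")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times_min must be strictly increasing")
        if self.times_min[0] > 0:
            raise ValueError(
                "first frame must be acquired at or before micro-irradiation "
                f"(t = 0); got t = {self.times_min[0]} min"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of each frame."""
        return self.frames.shape[1:]


def read_times(path: str | Path) -> np.ndarray:
    """Read frame times (minutes) from a sidecar CSV or YAML file.

    CSV files must contain a ``time_min`` column; YAML files either a
    plain list or a mapping with a ``times_min`` key.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"times sidecar not found: {path}")
    if path.suffix.lower() in {".yml", ".yaml"}:
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if isinstance(data, dict):
            data = data["times_min"]
        return np.asarray(data, dtype=float)
    df = pd.read_csv(path)
    if "time_min" not in df.columns:
        raise ValueError(f"column 'time_min' missing from {path}")
    return df["time_min"].to_numpy(dtype=float)


def read_stack(
    path: str | Path,
    times: Sequence[float] | str | Path,
    z_policy: str = "max_projection",
    n_z: int = 1,
    **stack_kwargs,
) -> FrameStack:
    """Read a multi-page TIFF into a :class:`FrameStack`.

    Parameters
    ----------
    path : path
        Multi-page grayscale TIFF.  Pages are ordered T-major: all
        z-planes of the first time point, then the second, and so on.
    times : sequence of float, or path
        Per-frame acquisition times in minutes, or the path of a sidecar
        file understood by :func:`read_times`.
    z_policy : {"max_projection", "single_plane:<k>"}
        How to reduce z-planes to one 2D frame per time point.  Under
        ``max_projection`` each output pixel is the maximum over the
        z-planes of that time point.
    n_z : int
        Number of z-planes per time point (1 for plain time series).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack not found: {path}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"expected a stack of 2D grayscale pages, got shape {pages.shape}")
    pages = pages.astype(np.float64)

    if n_z < 1:
        raise ValueError("n_z must be >= 1")
    if len(pages) % n_z != 0:
        raise ValueError(
            f"page count {len(pages)} not divisible by declared Z = {n_z}"
        )
    if n_z > 1:
        t = len(pages) // n_z
        cube = pages.reshape(t, n_z, *pages.shape[1:])
        if z_policy == "max_projection":
            frames = cube.max(axis=1)
        elif z_policy.startswith("single_plane:"):
            k = int(z_policy.split(":", 1)[1])
            if not 0 <= k < n_z:
                raise ValueError(f"z-plane index {k} outside [0, {n_z})")
            frames = cube[:, k]
        else:
            raise ValueError(f"unknown z_policy: {z_policy!r}")
    else:
        frames = pages

    if isinstance(times, (str, Path)):
        times = read_times(times)
    return FrameStack(frames=frames, times_min=np.asarray(times, float), **stack_kwargs)


def write_stack(stack: FrameStack, path: str | Path, dtype=np.uint16) -> None:
    """Write a stack as a multi-page TIFF, rounding to the given integer dtype."""
    info = np.iinfo(dtype)
    data = np.clip(np.rint(stack.frames), info.min, info.max).astype(dtype)
    tifffile.imwrite(Path(path), data, photometric="minisblack")


def write_times(times_min: Sequence[float], path: str | Path) -> None:
    """Write a frame-times sidecar CSV with columns frame, time_min."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "time_min"])
        for i, t in enumerate(times_min):
            w.writerow([i, repr(float(t))])


_MS_COLUMNS = [
    "field_id",
    "nucleus_id",
    "time_min",
    "ms",
    "j_meas",
    "j_expt",
    "stripe_D",
    "stripe_P",
    "angle_deg",
]


def write_ms_table(records, path: str | Path) -> None:
    """Write per-nucleus, per-timepoint striation records as CSV.

    One row per record with columns ``field_id, nucleus_id, time_min, ms,
    j_meas, j_expt, stripe_D, stripe_P, angle_deg``; values round-trip
    through :func:`read_ms_table` at full float precision.  Flagged
    (undefined) records carry NaN in the ms column.
    """
    rows = []
    for r in records:
        fit = r.fit
        rows.append(
            {
                "field_id": r.field_id,
                "nucleus_id": r.nucleus_id,
                "time_min": r.time_min,
                "ms": r.ms,
                "j_meas": r.j_meas,
                "j_expt": r.j_expt,
                "stripe_D": fit.d_px if fit is not None else np.nan,
                "stripe_P": fit.p_px if fit is not None else np.nan,
                "angle_deg": fit.angle_deg if fit is not None else np.nan,
            }
        )
    df = pd.DataFrame(rows, columns=_MS_COLUMNS)
    df.to_csv(Path(path), index=False)


def read_ms_table(path: str | Path) -> pd.DataFrame:
    """Read a striation table written by :func:`write_ms_table`."""
    return pd.read_csv(Path(path))
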