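"""Domain types and I/O for ultrasound point tracking.

Coordinate convention (used everywhere in this package): a point is an
``(x, y)`` pair of subpixel floats with ``x`` = column and ``y`` = row,
0-based, origin at the top-left of the image.  No operation transposes.

Frame indices are 0-based.  Human-facing label *ordinals* (``labeled frame
number 4``) are 1-based over the sorted labeled frames of a video;
:func:`ordinal_to_frame` maps between the two conventions.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "VideoSequence",
    "PointSet",
    "LabelSet",
    "Trajectory",
    "SegmentBounds",
    "read_labels",
    "write_labels",
    "read_trajectory",
    "write_trajectory",
    "read_video",
    "write_frames",
    "px_to_mm",
    "ordinal_to_frame",
    "DEFAULT_PX_PER_MM",
]

#: Pixel pitch of the imaging setup: 13 px correspond to 1 mm.
DEFAULT_PX_PER_MM = 13.0


def _as_points(coords) -> np.ndarray:
    pts = np.asarray(coords, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(1, -1)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"points must have shape (p, 2), got {pts.shape}")
    if pts.shape[0] < 1:
        raise ValueError("point set must contain at least one point")
    if not np.all(np.isfinite(pts)):
        raise ValueError("point coordinates must be finite")
    return pts


@dataclasses.dataclass
class PointSet:
    """A set of ``p`` subpixel ``(x, y)`` image points."""

    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = _as_points(self.coordinates)

    @property
    def p(self) -> int:
        return self.coordinates.shape[0]

    def __len__(self) -> int:
        return self.p

    def __iter__(self):
        return iter(self.coordinates)

    def __array__(self, dtype=None, copy=None):
        arr = self.coordinates
        if dtype is not None:
            arr = arr.astype(dtype)
        return np.array(arr) if copy else arr


@dataclasses.dataclass
class VideoSequence:
    """An ordered stack of equally shaped grayscale frames.

    ``frames`` is stored as an array of shape ``(n_frames, height, width)``.
    """

    frames: np.ndarray
    frame_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError(
                f"frames must stack to (n, height, width), got shape {frames.shape}"
            )
        if frames.shape[0] < 2:
            raise ValueError("a video needs at least 2 frames")
        if not np.all(np.isfinite(frames)):
            raise ValueError("frame intensities must be finite")
        if np.any(np.asarray(frames, dtype=float) < 0):
            raise ValueError("frame intensities must be non-negative")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i) -> np.ndarray:
        return self.frames[i]


class LabelSet:
    """Ground-truth point coordinates at a sparse set of frames.

    Every labeled frame carries the same number of points ``p`` in a
    consistent order (ascending point id).
    """

    def __init__(self, entries: Mapping[int, "PointSet | np.ndarray"]):
        if not entries:
            raise ValueError("no labeled frames")
        self._entries: dict[int, np.ndarray] = {}
        p = None
        for frame, pts in entries.items():
            frame = int(frame)
            if frame < 0:
                raise ValueError(f"negative frame index {frame}")
            arr = _as_points(np.asarray(pts, dtype=float))
            if p is None:
                p = arr.shape[0]
            elif arr.shape[0] != p:
                raise ValueError(
                    f"inconsistent number of points at frame {frame}: "
                    f"expected {p}, got {arr.shape[0]}"
                )
            self._entries[frame] = arr
        self._frames = sorted(self._entries)
        self._p = p

    @property
    def frames(self) -> list[int]:
        """Sorted labeled frame indices."""
        return list(self._frames)

    @property
    def p(self) -> int:
        return self._p

    def __len__(self) -> int:
        return len(self._frames)

    def __contains__(self, frame: int) -> bool:
        return int(frame) in self._entries

    def __getitem__(self, frame: int) -> np.ndarray:
        return self._entries[int(frame)]

    def items(self):
        for f in self._frames:
            yield f, self._entries[f]

    def validate_against(self, video: VideoSequence) -> None:
        bad = [f for f in self._frames if f >= video.n_frames]
        if bad:
            raise ValueError(f"labeled frames {bad} outside video of length {video.n_frames}")


@dataclasses.dataclass
class Trajectory:
    """Per-point positions over a contiguous frame range.

    ``positions`` has shape ``(n_frames, p, 2)`` in pixels; ``valid`` flags
    whether each point was successfully tracked at each frame.  The range
    covered is ``[start_frame, start_frame + n_frames - 1]`` of the source
    video, so segment trackers can hand out trajectories that do not begin
    at frame 0.
    """

    positions: np.ndarray
    valid: np.ndarray | None = None
    frame_rate_hz: float = 60.0
    start_frame: int = 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 3 or pos.shape[2] != 2:
            raise ValueError(f"positions must have shape (frames, p, 2), got {pos.shape}")
        self.positions = pos
        if self.valid is None:
            self.valid = np.ones(pos.shape[:2], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != pos.shape[:2]:
                raise ValueError("valid mask shape must match positions")
        if not np.all(np.isfinite(pos[self.valid])):
            raise ValueError("positions must be finite wherever valid")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def p(self) -> int:
        return self.positions.shape[1]

    @property
    def end_frame(self) -> int:
        """Last covered frame index (inclusive)."""
        return self.start_frame + self.n_frames - 1

    def local(self, frame: int) -> int:
        """Map a video frame index to an index into ``positions``."""
        i = int(frame) - self.start_frame
        if not 0 <= i < self.n_frames:
            raise IndexError(
                f"frame {frame} outside trajectory range "
                f"[{self.start_frame}, {self.end_frame}]"
            )
        return i

    def at(self, frame: int) -> np.ndarray:
        """Positions ``(p, 2)`` at a video frame index."""
        return self.positions[self.local(frame)]

    def copy(self) -> "Trajectory":
        return Trajectory(
            self.positions.copy(),
            self.valid.copy(),
            self.frame_rate_hz,
            self.start_frame,
        )


@dataclasses.dataclass(frozen=True)
class SegmentBounds:
    """A frame interval ``[t_i, t_e]`` used by segment-wise corrections."""

    t_i: int
    t_e: int

    def __post_init__(self) -> None:
        if self.t_e <= self.t_i:
            raise ValueError(f"segment end {self.t_e} must exceed start {self.t_i}")
        if self.t_i < 0:
            raise ValueError("segment start must be non-negative")

    @property
    def T(self) -> int:
        """Segment length in frames, ``t_e - t_i``."""
        return self.t_e - self.t_i


# ---------------------------------------------------------------------------
# conversions


def px_to_mm(d_px, px_per_mm: float = DEFAULT_PX_PER_MM):
    """Convert a pixel distance to millimetres (13 px = 1 mm by default)."""
    if px_per_mm <= 0:
        raise ValueError("px_per_mm must be positive")
    return np.asarray(d_px, dtype=float) / px_per_mm if np.ndim(d_px) else float(d_px) / px_per_mm


def ordinal_to_frame(labels: LabelSet, ordinal: int) -> int:
    """Map a 1-based labeled-frame ordinal to its 0-based video frame index.

    "Labeled frame number 4" means the 4th labeled frame in time.
    """
    frames = labels.frames
    if not 1 <= ordinal <= len(frames):
        raise ValueError(f"ordinal {ordinal} outside 1..{len(frames)}")
    return frames[ordinal - 1]


# ---------------------------------------------------------------------------
# label / trajectory I/O (long-format CSV)


def read_labels(path) -> LabelSet:
    """Read a labels table (columns ``frame, point_id, x, y``) into a LabelSet."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no labeled frames") from None
    if df.empty:
        raise ValueError(f"{path}: no labeled frames")
    required = {"frame", "point_id", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("frame", "point_id", "x", "y"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"{path}: non-numeric values in column '{col}'")
    entries = {}
    p = None
    for frame, grp in df.groupby("frame"):
        grp = grp.sort_values("point_id")
        pts = grp[["x", "y"]].to_numpy(dtype=float)
        if p is None:
            p = len(pts)
        elif len(pts) != p:
            raise ValueError(
                f"{path}: frame {int(frame)} has {len(pts)} points, expected {p}"
            )
        entries[int(frame)] = pts
    return LabelSet(entries)


def write_labels(labels: LabelSet, path) -> None:
    rows = [
        (frame, pid, x, y)
        for frame, pts in labels.items()
        for pid, (x, y) in enumerate(pts)
    ]
    df = pd.DataFrame(rows, columns=["frame", "point_id", "x", "y"])
    df.to_csv(path, index=False)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as long-format CSV ``frame, point_id, x, y, valid``.

    Round-trips losslessly through :func:`read_trajectory`.
    """
    frames = np.arange(traj.start_frame, traj.start_frame + traj.n_frames)
    rows = []
    for i, frame in enumerate(frames):
        for pid in range(traj.p):
            x, y = traj.positions[i, pid]
            rows.append((frame, pid, x, y, bool(traj.valid[i, pid])))
    df = pd.DataFrame(rows, columns=["frame", "point_id", "x", "y", "valid"])
    df.to_csv(path, index=False)


def read_trajectory(path, frame_rate_hz: float = 60.0) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame", "point_id", "x", "y"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    frames = np.sort(df["frame"].unique())
    if len(frames) and not np.array_equal(frames, np.arange(frames[0], frames[-1] + 1)):
        raise ValueError(f"{path}: trajectory frames must be contiguous")
    pids = np.sort(df["point_id"].unique())
    n, p = len(frames), len(pids)
    positions = np.full((n, p, 2), np.nan)
    valid = np.ones((n, p), dtype=bool)
    fidx = {f: i for i, f in enumerate(frames)}
    pidx = {pid: j for j, pid in enumerate(pids)}
    has_valid = "valid" in df.columns
    for row in df.itertuples(index=False):
        i, j = fidx[row.frame], pidx[row.point_id]
        positions[i, j] = (row.x, row.y)
        if has_valid:
            valid[i, j] = bool(row.valid)
    return Trajectory(positions, valid, frame_rate_hz, start_frame=int(frames[0]))


# ---------------------------------------------------------------------------
# video I/O


def _to_gray(frame: np.ndarray) -> np.ndarray:
    arr = np.asarray(frame)
    if arr.ndim == 3:  # RGB(A) supplied: single-channel mean
        arr = arr[..., :3].mean(axis=-1)
    return arr


def read_video(path, frame_rate_hz: float = 60.0) -> VideoSequence:
    """Load a video from a frame directory, a multi-page TIFF, or a container file.

    RGB input is collapsed to grayscale by channel averaging.
    """
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(
            f for f in path.iterdir()
            if f.suffix.lower() in {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}
        )
        if len(files) < 2:
            raise ValueError(f"{path}: need at least 2 frame images, found {len(files)}")
        frames = np.stack([_to_gray(iio.imread(f)) for f in files])
    elif path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        frames = np.asarray(tifffile.imread(path))
        if frames.ndim == 2:
            raise ValueError(f"{path}: TIFF contains a single page, need >= 2 frames")
        if frames.ndim == 4:
            frames = frames[..., :3].mean(axis=-1)
    else:
        import imageio.v3 as iio

        frames = np.stack([_to_gray(f) for f in iio.imiter(path)])
    return VideoSequence(frames, frame_rate_hz)


def write_frames(video: VideoSequence, out_dir, fmt: str = "png") -> list[Path]:
    """Write a video as a directory of numbered grayscale images."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = video.frames
    if frames.dtype != np.uint8:
        lo, hi = float(frames.min()), float(frames.max())
        scale = 255.0 / (hi - lo) if hi > lo else 0.0
        frames = ((frames - lo) * scale).astype(np.uint8)
    width = len(str(video.n_frames - 1))
    paths = []
    for i, frame in enumerate(frames):
        p = out_dir / f"frame_{i:0{width}d}.{fmt}"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths
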