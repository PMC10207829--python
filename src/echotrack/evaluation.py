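"""Quantitative evaluation protocols for point trackers.

Three protocols are provided:

Mirrored-video drift
    A video's first ``N`` frames are concatenated with their time reverse
    into a palindrome of ``2N - 1`` frames, so the first and last frames
    coincide.  Tracking through the palindrome, any distance between the
    final tracked points and their initial positions is pure drift; an
    ideal non-drifting tracker scores exactly 0.  Repeating over several
    ``N`` yields a drift curve whose slope is the per-frame drift rate.

Labeled-frame accuracy
    Euclidean distance in pixels between tracked points and ground-truth
    labels at each labeled frame, averaged over points and frames (with a
    millimetre conversion at 13 px/mm by default).

Jitter
    Frame-to-frame high-frequency noise of a trajectory: the mean absolute
    value of the coordinate signal after zero-phase high-pass filtering
    (default cutoff 15 Hz), averaged over x and y per point.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal

from .core import (
    DEFAULT_PX_PER_MM,
    LabelSet,
    Trajectory,
    VideoSequence,
    px_to_mm,
)
from .trackers import Tracker, track_forward

__all__ = [
    "DriftCurve",
    "EvaluationReport",
    "DEFAULT_N_VALUES",
    "mirror_video",
    "mirror_trajectory",
    "drift_error",
    "error_at_labels",
    "jitter_metric",
]

#: Copy lengths used by the drift protocol: N = 200, 400, ... 1600.
DEFAULT_N_VALUES = tuple(range(200, 1601, 200))


@dataclasses.dataclass
class DriftCurve:
    """Mean start-vs-end drift for each mirrored copy length ``N``.

    ``frames_tracked[i] = 2 * n_values[i] - 2`` is the number of tracking
    steps through each palindrome; ``rate_px_per_frame`` is the slope of an
    origin-constrained least-squares fit of error against frames tracked.
    """

    n_values: np.ndarray
    errors_px: np.ndarray
    rate_px_per_frame: float

    @property
    def frames_tracked(self) -> np.ndarray:
        return 2 * self.n_values - 2

    def to_dict(self) -> dict:
        return {
            "n_values": self.n_values.tolist(),
            "frames_tracked": self.frames_tracked.tolist(),
            "errors_px": self.errors_px.tolist(),
            "rate_px_per_frame": self.rate_px_per_frame,
        }


@dataclasses.dataclass
class EvaluationReport:
    """Per-labeled-frame tracking errors and their summary.

    ``per_label_errors_px`` maps each labeled frame to the ``(p,)`` array
    of per-point Euclidean distances; ``flagged`` marks distances measured
    against a held (invalid) tracked position.
    """

    per_label_errors_px: dict[int, np.ndarray]
    mean_error_px: float
    mean_error_mm: float
    flagged: dict[int, np.ndarray]
    jitter_px: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "per_label_errors_px": {
                int(f): e.tolist() for f, e in self.per_label_errors_px.items()
            },
            "mean_error_px": self.mean_error_px,
            "mean_error_mm": self.mean_error_mm,
            "flagged": {int(f): m.tolist() for f, m in self.flagged.items()},
            "jitter_px": None if self.jitter_px is None else self.jitter_px.tolist(),
        }


def mirror_video(video: VideoSequence, n: int) -> VideoSequence:
    """First ``n`` frames followed by their reverse: a ``2n - 1``-frame palindrome.

    Frame ``k`` of the output equals frame ``2n - 2 - k``; in particular the
    first and last frames are identical.
    """
    if not 2 <= n <= video.n_frames:
        raise ValueError(f"n must lie in [2, {video.n_frames}], got {n}")
    head = video.frames[:n]
    frames = np.concatenate([head, head[-2::-1]], axis=0)
    return VideoSequence(frames, video.frame_rate_hz)


def mirror_trajectory(traj: Trajectory, n: int) -> Trajectory:
    """Ground-truth counterpart of :func:`mirror_video` for synthetic trackers."""
    if not 2 <= n <= traj.n_frames:
        raise ValueError(f"n must lie in [2, {traj.n_frames}], got {n}")
    head = traj.positions[:n]
    vhead = traj.valid[:n]
    return Trajectory(
        np.concatenate([head, head[-2::-1]], axis=0),
        np.concatenate([vhead, vhead[-2::-1]], axis=0),
        traj.frame_rate_hz,
        traj.start_frame,
    )


def drift_error(
    video: VideoSequence,
    init,
    tracker,
    n_values=DEFAULT_N_VALUES,
) -> DriftCurve:
    """Run the mirrored-video drift protocol for each copy length ``N``.

    ``tracker`` is either a tracker-contract object or a factory callable
    ``factory(mirrored_video) -> tracker`` (needed by trackers whose state
    depends on the video being tracked, e.g. synthetic ground-truth
    trackers).  The error for each ``N`` is the mean over points of the
    Euclidean distance between final tracked positions and ``init``; an
    entry where the tracker invalidates every point is recorded as NaN and
    excluded from the rate fit.
    """
    n_values = np.asarray(sorted(n_values), dtype=int)
    if n_values[-1] > video.n_frames:
        raise ValueError(
            f"max N {n_values[-1]} exceeds video length {video.n_frames}"
        )
    init = np.asarray(init, dtype=float)
    errors = np.zeros(len(n_values))
    for k, n in enumerate(n_values):
        mirrored = mirror_video(video, int(n))
        trk = tracker(mirrored) if not hasattr(tracker, "initialize") else tracker
        traj = track_forward(mirrored, init, 0, mirrored.n_frames - 1, trk)
        final = traj.positions[-1]
        ok = traj.valid[-1]
        if not ok.any():
            errors[k] = np.nan
            continue
        dists = np.linalg.norm(final[ok] - init[ok], axis=1)
        errors[k] = float(dists.mean())
    x = (2 * n_values - 2).astype(float)
    good = np.isfinite(errors)
    if good.any() and np.sum(x[good] ** 2) > 0:
        rate = float(np.sum(x[good] * errors[good]) / np.sum(x[good] ** 2))
    else:
        rate = float("nan")
    return DriftCurve(n_values, errors, rate)


def error_at_labels(
    traj: Trajectory,
    labels: LabelSet,
    px_per_mm: float = DEFAULT_PX_PER_MM,
) -> EvaluationReport:
    """Euclidean tracking error at every labeled frame.

    Invalid tracked points are measured against their held position and
    flagged in the report rather than dropped.
    """
    per_label: dict[int, np.ndarray] = {}
    flagged: dict[int, np.ndarray] = {}
    for frame, pts in labels.items():
        i = traj.local(frame)  # raises if a labeled frame is out of range
        dists = np.linalg.norm(traj.positions[i] - pts, axis=1)
        per_label[frame] = dists
        flagged[frame] = ~traj.valid[i]
    all_errors = np.concatenate(list(per_label.values()))
    mean_px = float(all_errors.mean())
    return EvaluationReport(
        per_label_errors_px=per_label,
        mean_error_px=mean_px,
        mean_error_mm=px_to_mm(mean_px, px_per_mm),
        flagged=flagged,
    )


def jitter_metric(traj: Trajectory, cutoff_hz: float = 15.0) -> np.ndarray:
    """Per-point jitter: mean |high-passed coordinate signal| in pixels.

    The high-pass is a zero-phase (forward-backward) 4th-order Butterworth
    at ``cutoff_hz``; x and y jitter are averaged per point.
    """
    fs = traj.frame_rate_hz
    if cutoff_hz >= fs / 2.0:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist rate {fs / 2} Hz"
        )
    sos = signal.butter(4, cutoff_hz, btype="highpass", fs=fs, output="sos")
    # sosfiltfilt needs more samples than its padding length
    padlen = 3 * (2 * sos.shape[0] + 1)
    if traj.n_frames <= padlen:
        raise ValueError(
            f"trajectory too short for the filter warm-up ({traj.n_frames} <= {padlen})"
        )
    filtered = signal.sosfiltfilt(sos, traj.positions, axis=0)
    return np.abs(filtered).mean(axis=(0, 2))
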