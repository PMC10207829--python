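"""Drift-correction algorithms for frame-to-frame point tracking.

Frame-to-frame trackers accumulate drift: a slow, steady departure of the
tracked point from its feature.  Three corrections exploit sparse labeled
frames to undo it while preserving the high-frequency motion the tracker
captured:

STC (sigmoid tracking correction)
    Between consecutive correction frames, the residual ``d = label -
    tracked`` at the segment's end is spread over the segment by adding a
    parameterised sigmoid ``d / (1 + exp(-B (j - T/2)))`` with ``B =
    2 ln(1/eps - 1) / T``; the added correction is ``eps*d`` at the segment
    start and ``(1-eps)*d`` at its end, so the corrected path misses the
    label by exactly ``eps*|d|`` per coordinate.  The tracker is reset to
    the label before each following segment.

RTC (reversed tracking correction)
    The plain average of a forward-tracked path and a backward-tracked
    path over the same frames, ``(P_f + P_b) / 2``.

RSTC (reversed sigmoid tracking correction)
    A sigmoid-weighted blend of the same two paths, trusting each path
    near its own initialisation: the forward weight is ``1 - eps`` at the
    start frame and ``eps`` at the end frame, and the weights sum to 1 at
    every frame.

``apply_segmentwise_rstc`` chains RSTC over the segments delimited by a
correction schedule (the combined scheme), and ``pseudo_label_schedule``
turns an external trajectory (e.g. a learned tracker's output) into a
label set usable as correction frames.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .core import LabelSet, SegmentBounds, Trajectory, VideoSequence, ordinal_to_frame
from .trackers import Tracker, track_backward, track_forward

__all__ = [
    "SigmoidParams",
    "CorrectionSchedule",
    "fit_sigmoid",
    "sigmoid_value",
    "select_correction_frames",
    "apply_stc",
    "apply_rtc",
    "rstc_weights",
    "apply_rstc",
    "apply_segmentwise_rstc",
    "pseudo_label_schedule",
]

logger = logging.getLogger(__name__)

#: Default residual tolerance: the corrected path reaches within 1% of the
#: drift magnitude of the label.
DEFAULT_EPSILON = 0.01

#: Correction-frame choices (1-based ordinals over 8 labeled frames) for
#: k = 0..4 correction frames.
_ORDINALS_8 = {0: (), 1: (4,), 2: (3, 6), 3: (2, 4, 6), 4: (1, 3, 5, 7)}


def _check_epsilon(epsilon: float) -> None:
    if not 0.0 < epsilon < 0.5:
        raise ValueError(f"epsilon must lie strictly in (0, 0.5), got {epsilon}")


def _steepness(epsilon: float, T: float) -> float:
    """B = 2 ln(1/eps - 1) / T."""
    return 2.0 * math.log(1.0 / epsilon - 1.0) / T


@dataclasses.dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the correction sigmoid ``S(x) = A/(1+e^{-B(x-C)}) + D``.

    A: amplitude (px) — the drift magnitude being corrected, per coordinate.
    B: steepness (1/frames), tied to the residual tolerance via
       ``B = 2 ln(1/epsilon - 1) / T``.
    C: midpoint (frame, segment-relative).
    D: vertical offset (px).
    """

    A: float
    B: float
    C: float
    D: float
    epsilon: float

    def __post_init__(self) -> None:
        _check_epsilon(self.epsilon)

    def __call__(self, x):
        return sigmoid_value(self, x)


def sigmoid_value(params: SigmoidParams, x):
    """Evaluate the parameterised sigmoid at (array of) positions ``x``."""
    x = np.asarray(x, dtype=float)
    out = params.A / (1.0 + np.exp(-params.B * (x - params.C))) + params.D
    return float(out) if out.ndim == 0 else out


def fit_sigmoid(d: float, T: float, epsilon: float = DEFAULT_EPSILON) -> SigmoidParams:
    """Closed-form sigmoid for a drift ``d`` over a segment of ``T`` frames.

    With segment-relative position ``j`` running 0..T, the returned sigmoid
    evaluates to ``eps*d`` at ``j = 0`` and ``(1-eps)*d`` at ``j = T``.
    """
    if T < 2:
        raise ValueError(f"segment length T must be >= 2, got {T}")
    _check_epsilon(epsilon)
    return SigmoidParams(A=float(d), B=_steepness(epsilon, T), C=T / 2.0, D=0.0, epsilon=epsilon)


@dataclasses.dataclass(frozen=True)
class CorrectionSchedule:
    """Strictly increasing labeled frame indices at which the tracker resets."""

    frames: tuple[int, ...]

    def __init__(self, frames):
        frames = tuple(int(f) for f in frames)
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("schedule frames must be strictly increasing")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def validate_against(self, labels: LabelSet) -> None:
        missing = [f for f in self.frames if f not in labels]
        if missing:
            raise ValueError(f"schedule frames {missing} are not labeled")


def select_correction_frames(
    labels: LabelSet, k: int, allow_generic: bool = False
) -> CorrectionSchedule:
    """Choose ``k`` correction frames from a labeled video.

    For the standard design of 8 labeled frames, the choices are the
    fixed evenly distributed ordinals: {} , {4}, {3, 6}, {2, 4, 6} and
    {1, 3, 5, 7} for k = 0..4 (1-based over the 8 labels).  Other label
    counts or k > 4 require ``allow_generic=True``, which falls back to
    rounding k evenly spaced ordinals.
    """
    n = len(labels)
    if n == 8 and 0 <= k <= 4:
        ordinals = _ORDINALS_8[k]
    elif allow_generic:
        if not 0 <= k <= n:
            raise ValueError(f"k={k} outside 0..{n}")
        ordinals = tuple(
            int(round(o)) for o in np.linspace(1, n, k + 2)[1:-1]
        ) if k else ()
        ordinals = tuple(dict.fromkeys(ordinals))  # dedupe, keep order
    else:
        raise ValueError(
            f"standard schedule needs exactly 8 labeled frames and k in 0..4 "
            f"(got {n} labels, k={k}); pass allow_generic=True for even spacing"
        )
    return CorrectionSchedule(ordinal_to_frame(labels, o) for o in ordinals)


# ---------------------------------------------------------------------------
# STC


def apply_stc(
    traj: Trajectory,
    labels: LabelSet,
    schedule: CorrectionSchedule,
    epsilon: float = DEFAULT_EPSILON,
    video: VideoSequence | None = None,
    tracker: Tracker | None = None,
) -> Trajectory:
    """Sigmoid tracking correction with tracker resets at scheduled frames.

    The trajectory must start at a labeled frame.  For each segment between
    consecutive correction frames the tracker is run from the segment's
    start label, the drift ``d = label - tracked`` at the segment end is
    measured, and the closed-form sigmoid is added per point and per
    coordinate; the tracker then restarts from the label.  Frames after
    the last scheduled frame are tracked without correction (flagged in
    ``result.meta['uncorrected_from']``).

    If ``video``/``tracker`` are omitted the input trajectory itself serves
    as the tracked path of every segment (no re-tracking, no resets) —
    useful when only the recorded path is available.
    """
    _check_epsilon(epsilon)
    start, end = traj.start_frame, traj.end_frame
    if start not in labels:
        raise ValueError(f"trajectory start frame {start} is not labeled")
    schedule.validate_against(labels)
    out_of_range = [f for f in schedule.frames if not start <= f <= end]
    if out_of_range:
        raise ValueError(f"schedule frames {out_of_range} outside trajectory range")
    retrack = video is not None and tracker is not None

    # a schedule frame equal to the start initializes rather than corrects
    sched = [f for f in schedule.frames if f > start]
    boundaries = [start] + sched

    out = traj.copy()
    for a, b in zip(boundaries, boundaries[1:]):
        if retrack:
            seg = track_forward(video, labels[a], a, b, tracker)
        else:
            seg = Trajectory(
                traj.positions[traj.local(a) : traj.local(b) + 1],
                traj.valid[traj.local(a) : traj.local(b) + 1],
                traj.frame_rate_hz,
                start_frame=a,
            )
        T = b - a
        d = labels[b] - seg.at(b)  # (p, 2) correction vector
        j = np.arange(T + 1, dtype=float)
        sig = 1.0 / (1.0 + np.exp(-_steepness(epsilon, T) * (j - T / 2.0)))
        corrected = seg.positions + sig[:, None, None] * d[None, :, :]
        lo = out.local(a)
        # a segment's end frame keeps its corrected value (label - eps*d);
        # the following segment re-tracks from the label but writes only
        # from its second frame on
        skip = 0 if a == boundaries[0] else 1
        out.positions[lo + skip : lo + T + 1] = corrected[skip:]
        out.valid[lo + skip : lo + T + 1] = seg.valid[skip:]

    tail_start = boundaries[-1]
    if tail_start < end:
        if retrack:
            tail = track_forward(video, labels[tail_start], tail_start, end, tracker)
            lo = out.local(tail_start)
            # keep the corrected value at the boundary frame itself
            out.positions[lo + 1 :] = tail.positions[1:]
            out.valid[lo + 1 :] = tail.valid[1:]
    out.meta = {"uncorrected_from": tail_start if sched else start}
    return out


# ---------------------------------------------------------------------------
# RTC / RSTC


def _check_pair(p_f: Trajectory, p_b: Trajectory) -> None:
    if (
        p_f.start_frame != p_b.start_frame
        or p_f.n_frames != p_b.n_frames
        or p_f.p != p_b.p
    ):
        raise ValueError(
            "forward and backward trajectories must cover the same frames "
            f"with the same points (got [{p_f.start_frame}, {p_f.end_frame}] x "
            f"{p_f.p} vs [{p_b.start_frame}, {p_b.end_frame}] x {p_b.p})"
        )


def apply_rtc(p_f: Trajectory, p_b: Trajectory) -> Trajectory:
    """Reversed tracking correction: the average path ``(P_f + P_b) / 2``."""
    _check_pair(p_f, p_b)
    return Trajectory(
        (p_f.positions + p_b.positions) / 2.0,
        p_f.valid & p_b.valid,
        p_f.frame_rate_hz,
        p_f.start_frame,
    )


def rstc_weights(
    bounds: SegmentBounds, epsilon: float = DEFAULT_EPSILON
) -> tuple[np.ndarray, np.ndarray]:
    """Forward/backward blend weights over frames ``t_i..t_e`` (inclusive).

    The forward weight decreases from ``1 - eps`` at ``t_i`` to ``eps`` at
    ``t_e``; the backward weight is its complement, so the two always sum
    to 1.
    """
    _check_epsilon(epsilon)
    b = _steepness(epsilon, bounds.T)
    c = (bounds.t_i + bounds.t_e) / 2.0
    x = np.arange(bounds.t_i, bounds.t_e + 1, dtype=float)
    w_f = 1.0 / (1.0 + np.exp(b * (x - c)))
    return w_f, 1.0 - w_f


def apply_rstc(
    p_f: Trajectory,
    p_b: Trajectory,
    bounds: SegmentBounds | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> Trajectory:
    """Reversed sigmoid tracking correction: sigmoid-weighted path blend.

    Each path dominates near its own initialisation — the forward path near
    the start frame, the backward path near the end frame.
    """
    _check_pair(p_f, p_b)
    if bounds is None:
        bounds = SegmentBounds(p_f.start_frame, p_f.end_frame)
    if bounds.t_i != p_f.start_frame or bounds.t_e != p_f.end_frame:
        raise ValueError("bounds must match the trajectories' frame coverage")
    w_f, w_b = rstc_weights(bounds, epsilon)
    blended = (
        w_f[:, None, None] * p_f.positions + w_b[:, None, None] * p_b.positions
    )
    return Trajectory(blended, p_f.valid & p_b.valid, p_f.frame_rate_hz, p_f.start_frame)


def apply_segmentwise_rstc(
    video: VideoSequence,
    labels: LabelSet,
    schedule: CorrectionSchedule,
    tracker: Tracker,
    epsilon: float = DEFAULT_EPSILON,
) -> Trajectory:
    """RSTC applied per segment between labeled boundary frames.

    The video range from the first to the last labeled frame is split at
    the scheduled frames; each segment is tracked forward from its start
    label and backward from its end label, the two paths are RSTC-blended,
    and segments are concatenated with the shared boundary frames pinned to
    the label coordinates exactly.
    """
    _check_epsilon(epsilon)
    schedule.validate_against(labels)
    first, last = labels.frames[0], labels.frames[-1]
    boundaries = sorted({first, last, *schedule.frames})
    if len(boundaries) < 2:
        raise ValueError("need at least two distinct boundary frames")

    n = last - first + 1
    p = labels.p
    positions = np.zeros((n, p, 2))
    valid = np.ones((n, p), dtype=bool)
    for a, b in zip(boundaries, boundaries[1:]):
        p_f = track_forward(video, labels[a], a, b, tracker)
        p_b = track_backward(video, labels[b], a, b, tracker)
        blended = apply_rstc(p_f, p_b, SegmentBounds(a, b), epsilon)
        lo = a - first
        positions[lo : lo + (b - a) + 1] = blended.positions
        valid[lo : lo + (b - a) + 1] = blended.valid
    for f in boundaries:  # boundary frames take the labels exactly
        positions[f - first] = labels[f]
        valid[f - first] = True
    return Trajectory(positions, valid, video.frame_rate_hz, start_frame=first)


def pseudo_label_schedule(external_traj: Trajectory, stride: int) -> LabelSet:
    """Sample an external trajectory every ``stride`` frames into a LabelSet.

    Entries are taken at frames ``{start, start+stride, ...}`` plus the
    final frame, enabling the combined scheme in which another tracker's
    output (rather than human labels) provides the correction frames.
    Frames where any point is invalid are skipped with a warning.
    """
    if stride < 2:
        raise ValueError("stride must be >= 2")
    frames = list(
        range(external_traj.start_frame, external_traj.end_frame + 1, int(stride))
    )
    if frames[-1] != external_traj.end_frame:
        frames.append(external_traj.end_frame)
    entries = {}
    for f in frames:
        i = external_traj.local(f)
        if not np.all(external_traj.valid[i]):
            logger.warning("skipping pseudo-label at frame %d: invalid points", f)
            continue
        entries[f] = external_traj.positions[i].copy()
    if not entries:
        raise ValueError("no valid frames available for pseudo-labels")
    return LabelSet(entries)
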