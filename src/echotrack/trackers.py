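"""Frame-to-frame point trackers.

The central piece is a translational Lucas–Kanade tracker: for each point a
square intensity template is taken from the previous frame and the
displacement ``(u, v)`` minimising the brightness-constancy residual is
found from the 2x2 normal equations

    [ sum fx^2   sum fx fy ] [u]   [ -sum fx ft ]
    [ sum fx fy  sum fy^2  ] [v] = [ -sum fy ft ]

where ``fx, fy`` are spatial gradients of the template and ``ft`` the
temporal difference over the window.  The solve is iterated with the window
re-sampled at the updated position (standard Newton iterations), because a
single linearised solve is only accurate for sub-pixel motion.

All trackers satisfy the tracker contract used by the correction and
evaluation modules::

    tracker.initialize(frame, points, frame_index=0)
    positions, valid = tracker.step(prev_frame, next_frame,
                                    prev_index, next_index)

``positions`` is an ``(p, 2)`` array of (x, y) pixels and ``valid`` a
boolean ``(p,)`` mask; a point that fails tracking keeps its last position
with ``valid = False``.  Image-based trackers ignore the frame indices;
synthetic trackers (see :mod:`echotrack.synthesis`) use them to look up
ground truth.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy import ndimage

from .core import PointSet, Trajectory, VideoSequence

__all__ = [
    "LKConfig",
    "FlowSolution",
    "lk_flow_step",
    "LucasKanadeTracker",
    "BoxTrackerConfig",
    "BoxBackend",
    "box_tracker_step",
    "BoxTracker",
    "NCCBoxBackend",
    "track_forward",
    "track_backward",
    "denoise_frame",
    "DenoiseConfig",
]


@dataclasses.dataclass
class LKConfig:
    """Parameters of the Lucas–Kanade point tracker.

    window_n
        Odd side length of the square template; the normal equations sum
        over its ``window_n**2`` pixels.
    max_displacement_px
        A step whose solved displacement exceeds this is treated as a
        tracking failure (point held, flagged invalid).
    min_eigen_threshold
        Minimum smallest eigenvalue of the per-pixel-normalised normal
        matrix for the solve to be trusted; below it the window is
        texture-deficient (aperture problem) and the point holds position.
        Intensities are normalised to [0, 1] first so this is scale-free.
    pyramid_levels
        Number of coarse-to-fine pyramid levels; 1 = single level.
    max_iterations, convergence_tol
        Newton-iteration budget per level and the displacement-update norm
        below which iteration stops, in pixels.
    """

    window_n: int = 21
    max_displacement_px: float = 20.0
    min_eigen_threshold: float = 1e-4
    pyramid_levels: int = 1
    max_iterations: int = 25
    convergence_tol: float = 0.01

    def __post_init__(self) -> None:
        if self.window_n < 3 or self.window_n % 2 == 0:
            raise ValueError("window_n must be odd and >= 3")
        if self.max_displacement_px <= 0:
            raise ValueError("max_displacement_px must be positive")
        if self.min_eigen_threshold < 0:
            raise ValueError("min_eigen_threshold must be non-negative")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")


@dataclasses.dataclass
class FlowSolution:
    """Solution of one Lucas–Kanade step for one point.

    ``conditioning`` is the smallest eigenvalue of the (per-pixel
    normalised) 2x2 normal matrix; a value at or below the configured
    threshold marks a rank-deficient window.
    """

    u: float
    v: float
    conditioning: float
    valid: bool = True


def _normalize(frame: np.ndarray) -> np.ndarray:
    """Convert a frame to float64 in [0, 1] (scale-free thresholds)."""
    f = np.asarray(frame, dtype=np.float64)
    if f.size and f.max() > 1.0:
        f = f / 255.0 if f.max() <= 255.0 else f / f.max()
    return f


def _sample(frame: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(frame, [ys, xs], order=1, mode="nearest")


def _solve_point(
    prev_f: np.ndarray,
    next_f: np.ndarray,
    x: float,
    y: float,
    cfg: LKConfig,
    init_disp: np.ndarray,
) -> tuple[np.ndarray, float, bool]:
    """Iterated LK solve for one point at one pyramid level.

    Returns (displacement, conditioning, converged_ok).
    """
    n = cfg.window_n
    half = n // 2
    dy, dx = np.mgrid[-half : half + 1, -half : half + 1]
    ys, xs = y + dy.ravel(), x + dx.ravel()

    template = _sample(prev_f, ys, xs)
    # central-difference spatial gradients of the previous frame's window
    fx = (_sample(prev_f, ys, xs + 1) - _sample(prev_f, ys, xs - 1)) / 2.0
    fy = (_sample(prev_f, ys + 1, xs) - _sample(prev_f, ys - 1, xs)) / 2.0

    g = np.array(
        [
            [np.sum(fx * fx), np.sum(fx * fy)],
            [np.sum(fx * fy), np.sum(fy * fy)],
        ]
    )
    cond = float(np.linalg.eigvalsh(g / (n * n))[0])
    if cond <= cfg.min_eigen_threshold:
        return init_disp, cond, False

    g_inv = np.linalg.inv(g)
    disp = init_disp.astype(float).copy()
    for _ in range(cfg.max_iterations):
        ft = _sample(next_f, ys + disp[1], xs + disp[0]) - template
        b = -np.array([np.sum(fx * ft), np.sum(fy * ft)])
        delta = g_inv @ b
        disp += delta
        if np.hypot(*delta) < cfg.convergence_tol:
            break
        if np.hypot(*disp) > 4.0 * cfg.max_displacement_px:
            break  # diverging; caller will flag on the magnitude check
    return disp, cond, True


def _pyramid(frame: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [frame]
    for _ in range(levels - 1):
        smoothed = ndimage.gaussian_filter(pyr[-1], sigma=1.0)
        pyr.append(smoothed[::2, ::2])
    return pyr


def lk_flow_step(
    prev_frame: np.ndarray,
    next_frame: np.ndarray,
    points: "PointSet | np.ndarray",
    cfg: LKConfig | None = None,
) -> tuple[PointSet, list[FlowSolution]]:
    """Track a set of points from ``prev_frame`` to ``next_frame``.

    Points whose template window is rank-deficient (flat), whose position
    lies outside the frame, or whose solved displacement exceeds
    ``cfg.max_displacement_px`` are returned unmoved with
    ``FlowSolution.valid = False``.
    """
    cfg = cfg or LKConfig()
    prev_f = _normalize(prev_frame)
    next_f = _normalize(next_frame)
    if prev_f.shape != next_f.shape:
        raise ValueError("frames must share the same shape")
    h, w = prev_f.shape
    pts = np.array(np.asarray(points, dtype=float), copy=True)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (p, 2)")

    prev_pyr = _pyramid(prev_f, cfg.pyramid_levels)
    next_pyr = _pyramid(next_f, cfg.pyramid_levels)

    out = np.array(pts, copy=True)
    solutions: list[FlowSolution] = []
    for i, (x, y) in enumerate(pts):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            solutions.append(FlowSolution(0.0, 0.0, 0.0, valid=False))
            continue
        disp = np.zeros(2)
        cond = 0.0
        ok = False
        for level in range(cfg.pyramid_levels - 1, -1, -1):
            scale = 2.0**level
            disp, cond, ok = _solve_point(
                prev_pyr[level], next_pyr[level], x / scale, y / scale, cfg, disp
            )
            if level > 0:
                disp = disp * 2.0
            if not ok:
                break
        magnitude = float(np.hypot(*disp))
        if not ok or magnitude > cfg.max_displacement_px or not np.all(np.isfinite(disp)):
            solutions.append(FlowSolution(0.0, 0.0, cond, valid=False))
            continue
        out[i, 0] = x + disp[0]
        out[i, 1] = y + disp[1]
        solutions.append(FlowSolution(float(disp[0]), float(disp[1]), cond, valid=True))
    return PointSet(out), solutions


class Tracker(Protocol):
    """The tracker contract shared by all trackers in this package."""

    def initialize(self, frame: np.ndarray, points, frame_index: int = 0) -> None: ...

    def step(
        self,
        prev_frame: np.ndarray,
        next_frame: np.ndarray,
        prev_index: int | None = None,
        next_index: int | None = None,
    ) -> tuple[np.ndarray, np.ndarray]: ...


class LucasKanadeTracker:
    """Stateful tracker wrapping :func:`lk_flow_step`."""

    def __init__(self, cfg: LKConfig | None = None, denoise: bool = False):
        self.cfg = cfg or LKConfig()
        self.denoise = denoise
        self._points: np.ndarray | None = None
        self._valid: np.ndarray | None = None

    def _prep(self, frame: np.ndarray) -> np.ndarray:
        if self.denoise:
            frame, _ = denoise_frame(frame)
        return frame

    def initialize(self, frame: np.ndarray, points, frame_index: int = 0) -> None:
        pts = np.array(np.asarray(points, dtype=float), copy=True)
        self._points = pts
        self._valid = np.ones(len(pts), dtype=bool)

    def step(self, prev_frame, next_frame, prev_index=None, next_index=None):
        if self._points is None:
            raise RuntimeError("tracker not initialized")
        active = np.flatnonzero(self._valid)
        if active.size:
            moved, sols = lk_flow_step(
                self._prep(prev_frame), self._prep(next_frame),
                self._points[active], self.cfg,
            )
            arr = np.asarray(moved)
            for k, idx in enumerate(active):
                if sols[k].valid:
                    self._points[idx] = arr[k]
                else:
                    self._valid[idx] = False  # hold last position
        return self._points.copy(), self._valid.copy()


# ---------------------------------------------------------------------------
# bounding-box (template-style) trackers


@dataclasses.dataclass
class BoxTrackerConfig:
    """Protocol parameters for template-style bounding-box trackers.

    The tracked quantity is the box centre; after every backend update the
    centre is taken and the box size is forcibly reset to its initial
    ``box_side_px`` so the box cannot distort over time.
    """

    box_side_px: int = 100
    tracker_kind: str = "external"

    def __post_init__(self) -> None:
        if self.box_side_px <= 0:
            raise ValueError("box_side_px must be positive")


class BoxBackend(Protocol):
    """Adapter interface for an external template tracker (CSRT/MOSSE/KCF-style).

    ``box`` is ``(x, y, w, h)`` with (x, y) the top-left corner in pixels.
    """

    def init(self, frame: np.ndarray, box: tuple[float, float, float, float]) -> None: ...

    def update(self, frame: np.ndarray) -> tuple[bool, tuple[float, float, float, float]]: ...


def _centered_box(x: float, y: float, side: float) -> tuple[float, float, float, float]:
    return (x - side / 2.0, y - side / 2.0, float(side), float(side))


def _clip_box(box, shape) -> tuple[tuple[float, float, float, float], bool]:
    h, w = shape
    x0, y0, bw, bh = box
    cx0, cy0 = max(x0, 0.0), max(y0, 0.0)
    cx1, cy1 = min(x0 + bw, float(w)), min(y0 + bh, float(h))
    clipped = (cx0, cy0, max(cx1 - cx0, 0.0), max(cy1 - cy0, 0.0))
    was_clipped = clipped != (x0, y0, bw, bh)
    return clipped, was_clipped


def box_tracker_step(
    prev_frame: np.ndarray,
    next_frame: np.ndarray,
    points,
    cfg: BoxTrackerConfig,
    backends: Sequence[BoxBackend],
) -> tuple[PointSet, np.ndarray]:
    """Advance per-point box backends one frame, recentring and resetting.

    Each backend must have been initialised with a ``box_side_px`` square
    centred on its point.  After the update the centre of the (possibly
    clipped) box becomes the new point and the backend is re-initialised
    with a fresh square of the initial size centred there, enforcing the
    recenter/reset protocol regardless of backend behaviour.
    """
    pts = np.array(np.asarray(points, dtype=float), copy=True)
    if len(backends) != len(pts):
        raise ValueError("one backend per point required")
    valid = np.ones(len(pts), dtype=bool)
    for i, backend in enumerate(backends):
        ok, box = backend.update(next_frame)
        if not ok:
            valid[i] = False  # tracking loss: hold position
            continue
        clipped, was_clipped = _clip_box(box, next_frame.shape)
        if clipped[2] <= 0 or clipped[3] <= 0:
            valid[i] = False
            continue
        cx = clipped[0] + clipped[2] / 2.0
        cy = clipped[1] + clipped[3] / 2.0
        pts[i] = (cx, cy)
        if was_clipped:
            valid[i] = False
        # reset to initial dimensions before the next step
        backend.init(next_frame, _centered_box(cx, cy, cfg.box_side_px))
    return PointSet(pts), valid


class BoxTracker:
    """Tracker-contract wrapper around per-point box backends."""

    def __init__(self, backend_factory: Callable[[], BoxBackend], cfg: BoxTrackerConfig | None = None):
        self.cfg = cfg or BoxTrackerConfig()
        self._factory = backend_factory
        self._backends: list[BoxBackend] = []
        self._points: np.ndarray | None = None
        self._valid: np.ndarray | None = None

    def initialize(self, frame: np.ndarray, points, frame_index: int = 0) -> None:
        self._points = np.array(np.asarray(points, dtype=float), copy=True)
        self._valid = np.ones(len(self._points), dtype=bool)
        self._backends = []
        for x, y in self._points:
            backend = self._factory()
            backend.init(frame, _centered_box(x, y, self.cfg.box_side_px))
            self._backends.append(backend)

    def step(self, prev_frame, next_frame, prev_index=None, next_index=None):
        if self._points is None:
            raise RuntimeError("tracker not initialized")
        moved, ok = box_tracker_step(prev_frame, next_frame, self._points, self.cfg, self._backends)
        arr = np.asarray(moved)
        for i in range(len(self._points)):
            if self._valid[i] and ok[i]:
                self._points[i] = arr[i]
            elif not ok[i]:
                self._valid[i] = False
        return self._points.copy(), self._valid.copy()


class NCCBoxBackend:
    """Normalised cross-correlation template backend (integer-pixel).

    A minimal reference backend obeying :class:`BoxBackend`: the box
    content at ``init`` becomes the template, and ``update`` finds the
    best integer translation within ``search_radius_px``.
    """

    def __init__(self, search_radius_px: int = 10):
        self.search_radius_px = int(search_radius_px)
        self._template: np.ndarray | None = None
        self._box: tuple[float, float, float, float] | None = None

    def init(self, frame, box) -> None:
        f = _normalize(frame)
        (x0, y0, bw, bh), _ = _clip_box(box, f.shape)
        r0, r1 = int(round(y0)), int(round(y0 + bh))
        c0, c1 = int(round(x0)), int(round(x0 + bw))
        self._template = f[r0:r1, c0:c1].copy()
        self._box = (float(c0), float(r0), float(c1 - c0), float(r1 - r0))

    def update(self, frame):
        if self._template is None or self._template.size == 0:
            return False, (0.0, 0.0, 0.0, 0.0)
        f = _normalize(frame)
        x0, y0, bw, bh = self._box
        r = self.search_radius_px
        best, best_shift = -np.inf, (0, 0)
        t = self._template - self._template.mean()
        tn = np.linalg.norm(t)
        if tn == 0:
            return True, self._box  # flat template: no information, hold
        h, w = f.shape
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                rr0, cc0 = int(y0) + dy, int(x0) + dx
                rr1, cc1 = rr0 + int(bh), cc0 + int(bw)
                if rr0 < 0 or cc0 < 0 or rr1 > h or cc1 > w:
                    continue
                patch = f[rr0:rr1, cc0:cc1]
                p = patch - patch.mean()
                pn = np.linalg.norm(p)
                if pn == 0:
                    continue
                score = float(np.sum(t * p) / (tn * pn))
                if score > best:
                    best, best_shift = score, (dx, dy)
        if not np.isfinite(best):
            return False, self._box
        dx, dy = best_shift
        return True, (x0 + dx, y0 + dy, bw, bh)


# ---------------------------------------------------------------------------
# whole-range tracking drivers


def track_forward(
    video: VideoSequence,
    init,
    start: int,
    end: int,
    tracker: Tracker,
) -> Trajectory:
    """Track points forward in time over video frames ``[start, end]``.

    ``init`` are the point coordinates at ``start``.  The returned
    trajectory covers ``end - start + 1`` frames with
    ``positions[0] == init``; a point that fails keeps its last position
    and is invalid from that frame on.
    """
    if not 0 <= start < end < video.n_frames:
        raise ValueError(f"need 0 <= start < end < {video.n_frames}, got [{start}, {end}]")
    pts = np.asarray(init, dtype=float)
    n, p = end - start + 1, len(pts)
    positions = np.zeros((n, p, 2))
    valid = np.ones((n, p), dtype=bool)
    tracker.initialize(video[start], pts, start)
    positions[0] = pts
    for f in range(start, end):
        pts, ok = tracker.step(video[f], video[f + 1], f, f + 1)
        i = f + 1 - start
        positions[i] = pts
        valid[i] = valid[i - 1] & ok
    return Trajectory(positions, valid, video.frame_rate_hz, start_frame=start)


def track_backward(
    video: VideoSequence,
    init,
    start: int,
    end: int,
    tracker: Tracker,
) -> Trajectory:
    """Track points backward in time from ``end`` down to ``start``.

    ``init`` are the coordinates at frame ``end``.  The returned trajectory
    is indexed in ORIGINAL frame order over ``[start, end]`` with
    ``positions[-1] == init``.
    """
    if not 0 <= start < end < video.n_frames:
        raise ValueError(f"need 0 <= start < end < {video.n_frames}, got [{start}, {end}]")
    pts = np.asarray(init, dtype=float)
    n, p = end - start + 1, len(pts)
    positions = np.zeros((n, p, 2))
    valid = np.ones((n, p), dtype=bool)
    tracker.initialize(video[end], pts, end)
    positions[-1] = pts
    for f in range(end, start, -1):
        pts, ok = tracker.step(video[f], video[f - 1], f, f - 1)
        i = f - 1 - start
        positions[i] = pts
        valid[i] = valid[i + 1] & ok
    return Trajectory(positions, valid, video.frame_rate_hz, start_frame=start)


# ---------------------------------------------------------------------------
# despeckling


@dataclasses.dataclass
class DenoiseConfig:
    """Wavelet despeckling settings (off by default in all trackers)."""

    wavelet: str = "db2"
    method: str = "BayesShrink"
    mode: str = "soft"


def denoise_frame(
    frame: np.ndarray, cfg: DenoiseConfig | None = None
) -> tuple[np.ndarray, float]:
    """Wavelet-denoise one frame; returns (denoised, PSNR vs. input in dB).

    Speckle suppression before tracking is optional preprocessing.  A flat
    (constant) frame passes through unchanged with infinite PSNR.
    """
    from skimage.metrics import peak_signal_noise_ratio
    from skimage.restoration import denoise_wavelet

    cfg = cfg or DenoiseConfig()
    f = _normalize(frame)
    if np.ptp(f) == 0:
        return f.copy(), float("inf")
    den = denoise_wavelet(
        f, wavelet=cfg.wavelet, method=cfg.method, mode=cfg.mode, rescale_sigma=True
    )
    mse = float(np.mean((den - f) ** 2))
    psnr = float("inf") if mse == 0 else float(
        peak_signal_noise_ratio(f, den, data_range=1.0)
    )
    return den, psnr
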